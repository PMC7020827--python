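"""Synthetic anesthesia sessions: end-tidal profile -> effect site -> EEG.

The generator emulates a sevoflurane induction / maintenance / emergence
session so the whole pipeline can be exercised without clinical recordings.
The end-tidal profile follows the standard induction protocol shape (3 %
for two minutes, then 7 %, maintenance, washout); the effect-site series is
its first-order transform; and the EEG is a sum of four band-limited
oscillatory components whose amplitudes are logistic functions of the
effect-site concentration — the gamma and beta bands shrink and the delta
band grows as depth increases — plus white measurement noise.  This is the
simplest mechanism that reproduces the qualitative clinical signatures the
index relies on: entropies and high-frequency relative power that fall
monotonically (in expectation) with effect-site concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pkpd import PKParams, effect_site
from .records import ConcentrationSeries, EEGRecord

__all__ = [
    "BandSpec",
    "SessionSpec",
    "SyntheticSession",
    "DEFAULT_CET_PROFILE",
    "make_cet_profile",
    "synthesize_eeg",
    "simulate_session",
    "simulate_cohort",
]

#: default end-tidal breakpoints (time_s, vol %): ramp to 3 % over the first
#: minute, step up toward 7 % for induction, maintenance plateau, washout.
DEFAULT_CET_PROFILE: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (60.0, 3.0),
    (180.0, 7.0),
    (600.0, 7.0),
    (900.0, 0.0),
)


@dataclass(frozen=True)
class BandSpec:
    """One band-limited EEG component.

    The component is a sum of ``n_components`` sinusoids at frequencies drawn
    uniformly in [low, high] with random phases, normalised to unit RMS, then
    scaled by an amplitude that moves logistically from ``amp_awake`` (uV RMS
    at zero drug) to ``amp_deep`` (uV RMS at saturating concentration).  With
    ``low == high`` and ``n_components = 1`` the component is a pure sinusoid.
    """

    low: float
    high: float
    amp_awake: float
    amp_deep: float
    n_components: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.high:
            raise ValueError("need 0 < low <= high")
        if self.amp_awake < 0 or self.amp_deep < 0 or self.n_components < 1:
            raise ValueError("amplitudes must be >= 0 and n_components >= 1")


#: delta grows with depth; alpha persists; beta and gamma are suppressed
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec(0.8, 4.0, amp_awake=4.0, amp_deep=30.0),    # delta
    BandSpec(8.0, 12.0, amp_awake=10.0, amp_deep=6.0),   # alpha
    BandSpec(13.0, 30.0, amp_awake=8.0, amp_deep=2.0),   # beta
    BandSpec(30.0, 47.0, amp_awake=6.0, amp_deep=0.5),   # gamma
)


@dataclass
class SessionSpec:
    """Parameters of one synthetic anesthesia session.

    duration_s, fs
        Session length (s) and EEG sampling rate (Hz, default 100).
    keo
        Effect-compartment rate constant, 1/min.
    cet_profile
        Piecewise-linear (time_s, vol %) breakpoints of the end-tidal
        concentration; defaults to the induction/maintenance/washout shape.
    noise_sd
        Standard deviation of additive white EEG noise, uV.
    c_mid, c_width
        Center (vol %) and width of the logistic amplitude transition — the
        generator's analogue of an EC50 and slope.
    amp_ceiling
        Hard bound (uV) applied to the generated EEG.
    seed
        Seed for the session's random stream (component frequencies, phases,
        noise).
    """

    duration_s: float = 900.0
    fs: float = 100.0
    keo: float = 1.0
    cet_profile: tuple[tuple[float, float], ...] = DEFAULT_CET_PROFILE
    noise_sd: float = 2.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    c_mid: float = 2.0
    c_width: float = 0.6
    amp_ceiling: float = 200.0
    seed: int = 0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if not self.duration_s > 0 or not self.fs > 0:
            raise ValueError("duration_s and fs must be positive")
        if not self.keo > 0:
            raise ValueError("keo must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        pts = np.asarray(self.cet_profile, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("cet_profile must be a sequence of (time_s, vol%) pairs")
        t = pts[:, 0]
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("cet_profile times must be strictly increasing")
        if t[0] < 0 or t[-1] > self.duration_s:
            raise ValueError("cet_profile times must lie within [0, duration_s]")
        if np.any(pts[:, 1] < 0):
            raise ValueError("cet_profile concentrations must be >= 0")


@dataclass
class SyntheticSession:
    """One generated session: EEG plus aligned end-tidal and effect-site series."""

    eeg: EEGRecord
    cet: ConcentrationSeries
    ceff: ConcentrationSeries
    spec: SessionSpec


#: time step (s) of the concentration series written by the generator; the
#: effect-site dynamics (time constant 60 s at keo = 1/min) are fully
#: resolved at 0.1 s and the series interpolates exactly onto EEG time.
CONC_DT = 0.1


def make_cet_profile(spec: SessionSpec) -> ConcentrationSeries:
    """Piecewise-linear end-tidal concentration on the session time base.

    Values before the first / after the last breakpoint hold the boundary
    value; a single breakpoint yields a constant series.
    """
    pts = np.asarray(spec.cet_profile, dtype=float)
    t = np.arange(0.0, spec.duration_s + CONC_DT / 2, CONC_DT)
    c = np.interp(t, pts[:, 0], pts[:, 1])
    return ConcentrationSeries(t=t, c=c, kind="end_tidal")


def _amplitude(band: BandSpec, ceff: np.ndarray, c_mid: float, c_width: float) -> np.ndarray:
    depth = 1.0 / (1.0 + np.exp(-(ceff - c_mid) / c_width))
    return band.amp_awake + (band.amp_deep - band.amp_awake) * depth


def synthesize_eeg(ceff: ConcentrationSeries, spec: SessionSpec) -> EEGRecord:
    """Generate concentration-dependent EEG for one session.

    Each band contributes ``amp(ceff(t))`` (uV RMS) of band-limited
    oscillation; white noise of ``noise_sd`` uV is added and the result is
    clipped at ``amp_ceiling``.  Deterministic given ``spec.seed``.
    """
    if ceff.t.size < 2:
        raise ValueError("effect-site series must cover the session")
    n = round(spec.duration_s * spec.fs)
    t = np.arange(n) / spec.fs
    if t[-1] > ceff.t[-1] + 1e-9:
        raise ValueError("effect-site series does not span the session duration")
    c_t = np.interp(t, ceff.t, ceff.c)

    rng = np.random.default_rng(spec.seed)
    x = np.zeros(n)
    for band in spec.bands:
        freqs = rng.uniform(band.low, band.high, size=band.n_components)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=band.n_components)
        osc = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
        osc *= np.sqrt(2.0 / band.n_components)  # unit RMS in expectation
        x += _amplitude(band, c_t, spec.c_mid, spec.c_width) * osc
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng.standard_normal(n)
    np.clip(x, -spec.amp_ceiling, spec.amp_ceiling, out=x)
    return EEGRecord(samples=x, fs=spec.fs, subject_id=spec.subject_id)


def simulate_session(spec: SessionSpec) -> SyntheticSession:
    """Run the full generative chain for one subject."""
    cet = make_cet_profile(spec)
    ceff = effect_site(cet, PKParams(keo=spec.keo))
    eeg = synthesize_eeg(ceff, spec)
    return SyntheticSession(eeg=eeg, cet=cet, ceff=ceff, spec=spec)


def simulate_cohort(
    n_subjects: int, base_spec: SessionSpec | None = None, seed: int = 0
) -> list[SyntheticSession]:
    """Generate a cohort with inter-subject variability.

    Each subject gets an independent child seed derived from the master seed
    plus multiplicative jitter on keo (+-20 %), on the logistic transition
    center c_mid (+-20 %, the EC50 analogue) and on the noise level (+-25 %),
    emulating between-patient pharmacological and recording variability.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_spec or SessionSpec()
    master = np.random.default_rng(seed)
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    sessions = []
    for i, child in enumerate(children):
        spec_i = replace(
            base,
            keo=base.keo * master.uniform(0.8, 1.2),
            c_mid=base.c_mid * master.uniform(0.8, 1.2),
            noise_sd=base.noise_sd * master.uniform(0.75, 1.25),
            seed=int(child.generate_state(1)[0] % (2**31)),
            subject_id=f"S{i:02d}",
        )
        sessions.append(simulate_session(spec_i))
    return sessions
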