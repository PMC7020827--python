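"""Hybrid EEG feature extraction.

Each 5 s analysis window yields 46 features: 40 half-Hz spectral bins over
30-50 Hz, the two average band powers (30-47 Hz and 47-50 Hz), permutation
entropy, sample entropy, wavelet entropy, and the alpha-ratio.  The column
order is fixed and identical across subjects and runs.

The three entropies quantify signal irregularity, which falls as anesthetic
depth increases; the high-frequency spectral features capture the loss of
beta/gamma power under sevoflurane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import WindowedEEG, smooth_feature_track

__all__ = [
    "SampEnParams",
    "PeEnParams",
    "WaveletEntropyParams",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "sample_entropy",
    "permutation_entropy",
    "wavelet_entropy",
    "band_spectra",
    "alpha_ratio",
    "assemble_features",
    "HybridFeatureExtractor",
]


@dataclass
class SampEnParams:
    """Sample-entropy parameters: template length m, tolerance r (as a
    fraction of the window standard deviation), and window length N.
    Defaults m=2, r=0.2, N=500 (5 s at 100 Hz)."""

    m: int = 2
    r: float = 0.2
    N: int = 500

    def __post_init__(self) -> None:
        if self.m < 1 or self.r <= 0 or self.N <= self.m + 1:
            raise ValueError("need m >= 1, r > 0, N > m+1")


@dataclass
class PeEnParams:
    """Permutation-entropy parameters: ordinal pattern length m, delay tau,
    window length N.  Defaults m=4, tau=1, N=500."""

    m: int = 4
    tau: int = 1
    N: int = 500

    def __post_init__(self) -> None:
        if self.m < 2 or self.tau < 1 or self.N <= (self.m - 1) * self.tau:
            raise ValueError("need m >= 2, tau >= 1, N > (m-1)*tau")


@dataclass
class WaveletEntropyParams:
    """Wavelet-entropy parameters: basis and decomposition depth."""

    wavelet: str = "db4"
    levels: int = 5

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 decomposition levels")


def _feature_names() -> list[str]:
    names = [f"power_{lo:.1f}_{lo + 0.5:.1f}Hz" for lo in np.arange(30.0, 50.0, 0.5)]
    names += ["power_mean_30_47Hz", "power_mean_47_50Hz"]
    names += ["peen", "sampen", "wavelet_entropy", "alpha_ratio"]
    return names


#: the fixed 46-column order of the hybrid feature matrix
FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names())


@dataclass
class FeatureMatrix:
    """Per-window hybrid feature vectors, time-aligned to window centers."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    centers_s: np.ndarray = field(default_factory=lambda: np.array([]))
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError(
                f"feature matrix must have {len(self.names)} columns, got shape {self.values.shape}"
            )

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name) if isinstance(self.names, list) else list(self.names).index(name)
        except ValueError as exc:
            raise KeyError(f"unknown feature {name!r}") from exc
        return self.values[:, j]


# ---------------------------------------------------------------------------
# Entropies
# ---------------------------------------------------------------------------

def sample_entropy(window: np.ndarray, params: SampEnParams | None = None) -> float:
    """Sample entropy -ln(A(m+1,r)/A(m,r)) with Chebyshev distance.

    Templates of length m and m+1 are both drawn from the first N-m starting
    positions so the match counts at the two lengths are directly comparable;
    self-matches are excluded.  The tolerance is r times the window standard
    deviation, making the statistic invariant under positive affine scaling.

    A constant window returns 0 (every template matches at both lengths).
    If no template pair matches at length m+1 the statistic is undefined;
    the conventional finite ceiling -ln(2/((N-m-1)(N-m))) — the value a
    single match would produce — is returned with a warning.
    """
    p = params or SampEnParams()
    x = np.asarray(window, dtype=float)
    if x.size != p.N:
        raise ValueError(f"window length {x.size} != N={p.N}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r_abs = p.r * sd

    n_t = p.N - p.m  # number of templates at both lengths
    D = np.abs(x[:, None] - x[None, :])
    dm = D[:n_t, :n_t].copy()
    for k in range(1, p.m):
        np.maximum(dm, D[k : k + n_t, k : k + n_t], out=dm)
    dm1 = np.maximum(dm, D[p.m : p.m + n_t, p.m : p.m + n_t])

    iu = np.triu_indices(n_t, k=1)  # unordered pairs, self-matches excluded
    B = int(np.count_nonzero(dm[iu] <= r_abs))
    A = int(np.count_nonzero(dm1[iu] <= r_abs))
    if B == 0:
        return 0.0
    if A == 0:
        ceiling = -math.log(2.0 / ((n_t - 1) * n_t))
        warnings.warn(
            "no template matches at length m+1; returning the finite sample-entropy "
            f"ceiling {ceiling:.4g}",
            stacklevel=2,
        )
        return ceiling
    return -math.log(A / B)


def permutation_entropy(window: np.ndarray, params: PeEnParams | None = None) -> float:
    """Normalized permutation entropy -sum Pj ln Pj / ln(m!) in [0, 1].

    Ordinal patterns of m samples spaced tau apart are ranked with a stable
    argsort, so equal values are ordered by occurrence.  A monotone window
    has a single pattern and entropy 0; a window visiting all m! patterns
    equally often scores 1.
    """
    p = params or PeEnParams()
    x = np.asarray(window, dtype=float)
    n_emb = x.size - (p.m - 1) * p.tau
    if n_emb < 1:
        raise ValueError(
            f"window of length {x.size} too short for m={p.m}, tau={p.tau}"
        )
    idx = np.arange(n_emb)[:, None] + np.arange(p.m)[None, :] * p.tau
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns @ (p.m ** np.arange(p.m))
    counts = np.bincount(codes)
    probs = counts[counts > 0] / n_emb
    return float(-(probs * np.log(probs)).sum() / math.log(math.factorial(p.m)))


def wavelet_entropy(window: np.ndarray, params: WaveletEntropyParams | None = None) -> float:
    """Shannon entropy of the relative wavelet energy across scales.

    Energies E_j are sums of squared decomposition coefficients at each
    scale (approximation plus the detail scales); p_j = E_j / E_total and
    S = -sum p_j ln p_j.  All-zero input returns 0 by convention.
    """
    p = params or WaveletEntropyParams()
    x = np.asarray(window, dtype=float)
    if x.size < 2**p.levels:
        raise ValueError(f"window of length {x.size} too short for {p.levels} levels")
    coeffs = pywt.wavedec(x, p.wavelet, level=p.levels)
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    if total == 0:
        return 0.0
    probs = energies[energies > 0] / total
    return float(-(probs * np.log(probs)).sum())


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def _periodogram(window: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    # Hann-tapered single-segment periodogram; 500 samples at 100 Hz give a
    # native resolution of 0.2 Hz.
    return signal.periodogram(window, fs=fs, window="hann", detrend="constant")


def _band_power(f: np.ndarray, P: np.ndarray, lo: float, hi: float) -> float:
    sel = (f >= lo) & (f < hi)
    return float(P[sel].sum())


def band_spectra(window: np.ndarray, fs: float = 100.0) -> np.ndarray:
    """40 half-Hz spectral bins over [30, 50) Hz plus 2 average band powers.

    Each half-Hz bin sums the native periodogram bins whose center falls in
    [f, f+0.5); the two averages are the means of the half-Hz bins inside
    [30, 47) and [47, 50) respectively, so the aggregation identity holds by
    construction.  Returns 42 non-negative values.
    """
    x = np.asarray(window, dtype=float)
    f, P = _periodogram(x, fs)
    edges = np.arange(30.0, 50.5, 0.5)
    halfhz = np.array([_band_power(f, P, lo, hi) for lo, hi in zip(edges[:-1], edges[1:])])
    mean_30_47 = halfhz[: 2 * 17].mean()  # 34 bins below 47 Hz
    mean_47_50 = halfhz[2 * 17 :].mean()  # 6 bins at and above 47 Hz
    return np.concatenate([halfhz, [mean_30_47, mean_47_50]])


def alpha_ratio(window: np.ndarray, fs: float = 100.0, base: float = 10.0) -> float:
    """log(E_30-42.5Hz / E_6-12Hz); base-10 logarithm by default.

    Negative when low-frequency (6-12 Hz) energy dominates, positive when
    the high band dominates.  Zero denominator energy yields NaN with a
    warning.
    """
    x = np.asarray(window, dtype=float)
    f, P = _periodogram(x, fs)
    e_hi = _band_power(f, P, 30.0, 42.5)
    e_lo = _band_power(f, P, 6.0, 12.0)
    if e_lo == 0:
        warnings.warn("zero energy in the 6-12 Hz band; alpha-ratio undefined", stacklevel=2)
        return float("nan")
    return float(np.log(e_hi / e_lo) / np.log(base)) if e_hi > 0 else float("-inf")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_features(
    windows: WindowedEEG,
    sampen: SampEnParams | None = None,
    peen: PeEnParams | None = None,
    wavelet: WaveletEntropyParams | None = None,
    smooth: bool = False,
    smooth_wavelet: str = "db4",
    smooth_level: int = 3,
) -> FeatureMatrix:
    """Compute the 46-column hybrid feature matrix for a windowed record.

    Row i is computed solely from window i; when ``smooth`` is set, each
    feature column is additionally wavelet-denoised along time (one subject's
    track at a time — never across subjects).
    """
    if windows.n_windows < 1:
        raise ValueError("no analysis windows")
    sampen = sampen or SampEnParams(N=windows.window_len)
    peen = peen or PeEnParams(N=windows.window_len)
    wavelet = wavelet or WaveletEntropyParams()

    rows = np.empty((windows.n_windows, len(FEATURE_NAMES)))
    for i, w in enumerate(windows.windows):
        try:
            spec42 = band_spectra(w, windows.fs)
            rows[i, :42] = spec42
            rows[i, 42] = permutation_entropy(w, peen)
            rows[i, 43] = sample_entropy(w, sampen)
            rows[i, 44] = wavelet_entropy(w, wavelet)
            rows[i, 45] = alpha_ratio(w, windows.fs)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed on window {i}: {exc}") from exc

    if smooth and windows.n_windows >= 2**smooth_level:
        for j in range(rows.shape[1]):
            rows[:, j] = smooth_feature_track(rows[:, j], smooth_wavelet, smooth_level)

    return FeatureMatrix(
        values=rows,
        names=FEATURE_NAMES,
        centers_s=windows.centers_s.copy(),
        subject_id=windows.subject_id,
    )


class HybridFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping raw EEG windows to hybrid features.

    ``transform`` takes an (n_windows, window_len) array of EEG segments (in
    microvolts, temporally ordered) and returns the (n_windows, 46) feature
    matrix in the documented column order.  Stateless apart from recorded
    feature names; ``fit`` only validates input.
    """

    def __init__(
        self,
        fs: float = 100.0,
        sampen_m: int = 2,
        sampen_r: float = 0.2,
        peen_m: int = 4,
        peen_tau: int = 1,
        we_wavelet: str = "db4",
        we_levels: int = 5,
        smooth: bool = False,
    ):
        self.fs = fs
        self.sampen_m = sampen_m
        self.sampen_r = sampen_r
        self.peen_m = peen_m
        self.peen_tau = peen_tau
        self.we_wavelet = we_wavelet
        self.we_levels = we_levels
        self.smooth = smooth

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_windows, window_len)")
        self.n_features_in_ = X.shape[1]
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_windows, window_len)")
        n, wlen = X.shape
        windows = WindowedEEG(
            windows=X,
            centers_s=(np.arange(n) * wlen + wlen / 2.0) / self.fs,
            window_len=wlen,
            stride=wlen,
            fs=self.fs,
        )
        fm = assemble_features(
            windows,
            sampen=SampEnParams(m=self.sampen_m, r=self.sampen_r, N=wlen),
            peen=PeEnParams(m=self.peen_m, tau=self.peen_tau, N=wlen),
            wavelet=WaveletEntropyParams(wavelet=self.we_wavelet, levels=self.we_levels),
            smooth=self.smooth,
        )
        return fm.values

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
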