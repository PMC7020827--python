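"""Pharmacokinetic/pharmacodynamic model for sevoflurane.

The measured end-tidal concentration Cet drives a single effect compartment
with first-order kinetics,

    dCeff/dt = keo (Cet - Ceff),

whose solution lags the input with time constant 1/keo.  Ceff is the training
label for the regression network.  The inhibitory sigmoid Emax curve

    Effect = Emax - (Emax - Emin) Ceff^gamma / (EC50^gamma + Ceff^gamma)

maps concentration to a nominal clinical index and is used for visualisation
and synthetic-data generation, not for labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .records import ConcentrationSeries

__all__ = ["PKParams", "PDParams", "effect_site", "emax_effect", "invert_emax", "align_labels"]


@dataclass
class PKParams:
    """First-order effect-compartment kinetics.

    keo : 1/min
        Rate constant for equilibration between end-tidal and effect-site
        concentration.  No fitted population value is published for this
        dataset family; 1.0 min^-1 is a plausible effect-compartment time
        constant and is configurable everywhere it is used.
    """

    keo: float = 1.0

    def __post_init__(self) -> None:
        if not self.keo > 0:
            raise ValueError(f"keo must be positive, got {self.keo}")


@dataclass
class PDParams:
    """Inhibitory sigmoid Emax concentration-response curve.

    emax/emin are the drug-free and saturated index values, ec50 the
    concentration (vol %) producing the half-maximal effect, gamma the slope.
    """

    emax: float = 100.0
    emin: float = 0.0
    ec50: float = 2.0
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not self.emax > self.emin:
            raise ValueError("emax must exceed emin")
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


def effect_site(
    cet: ConcentrationSeries, pk: PKParams, ceff0: float | None = None
) -> ConcentrationSeries:
    """Integrate dCeff/dt = keo (Cet - Ceff) on the input's time base.

    Cet is treated as linear within each time step, for which the ODE has a
    closed-form update (an exponential integrator).  The scheme is
    unconditionally stable and exact for piecewise-linear input, so the
    result matches c (1 - exp(-keo t)) for a concentration step to machine
    precision.  Ceff(0) defaults to Cet(0), i.e. a patient in steady state
    (awake, zero drug) before induction.

    On a uniform time base the linear recurrence is evaluated with a fast
    IIR filter; non-uniform bases fall back to an explicit loop.
    """
    t = cet.t
    c = cet.c
    if t.size < 1:
        raise ValueError("empty concentration series")
    k = pk.keo / 60.0  # per second
    y0 = float(c[0] if ceff0 is None else ceff0)
    if t.size == 1:
        return ConcentrationSeries(t=t.copy(), c=np.array([y0]), kind="effect_site")

    h = np.diff(t)
    b = np.diff(c) / h  # slope of Cet within each step
    a = c[:-1]
    E = np.exp(-k * h)
    # y(t_i + h) = a + b h - b/k + E (y(t_i) - a + b/k)  for Cet = a + b s
    beta = a + b * h - b / k + E * (b / k - a)

    if np.allclose(h, h[0], rtol=0, atol=1e-12 * max(1.0, abs(h[0]))):
        # uniform grid: y[n+1] = E y[n] + beta[n] is an order-1 IIR filter
        e = float(E[0])
        y_rest, _ = lfilter([1.0], [1.0, -e], beta, zi=np.array([e * y0]))
        y = np.concatenate([[y0], y_rest])
    else:
        y = np.empty(t.size)
        y[0] = y0
        for i in range(t.size - 1):
            y[i + 1] = beta[i] + E[i] * y[i]
    # guard against tiny negative round-off on a non-negative input
    y = np.clip(y, 0.0, None)
    return ConcentrationSeries(t=t.copy(), c=y, kind="effect_site")


def emax_effect(ceff, pd_params: PDParams):
    """Inhibitory sigmoid Emax curve; strictly decreasing in Ceff.

    Returns ``emax`` at zero drug, ``(emax+emin)/2`` at EC50, and approaches
    ``emin`` at saturating concentration.
    """
    ceff = np.asarray(ceff, dtype=float)
    if np.any(ceff < 0):
        raise ValueError("effect-site concentration must be non-negative")
    p = pd_params
    frac = ceff**p.gamma / (p.ec50**p.gamma + ceff**p.gamma)
    out = p.emax - (p.emax - p.emin) * frac
    return out if out.ndim else float(out)


def invert_emax(effect, pd_params: PDParams):
    """Concentration producing a given effect strictly inside (emin, emax)."""
    effect = np.asarray(effect, dtype=float)
    p = pd_params
    if np.any(effect <= p.emin) or np.any(effect >= p.emax):
        raise ValueError("effect must lie strictly inside (emin, emax)")
    frac = (p.emax - effect) / (p.emax - p.emin)
    out = p.ec50 * (frac / (1.0 - frac)) ** (1.0 / p.gamma)
    return out if out.ndim else float(out)


def align_labels(feature_matrix, ceff: ConcentrationSeries) -> np.ndarray:
    """Interpolate effect-site concentration at each feature window's center.

    ``feature_matrix`` is any object with a ``centers_s`` attribute (or an
    array of window-center times).  Raises if any center falls outside the
    span of ``ceff``.
    """
    centers = getattr(feature_matrix, "centers_s", feature_matrix)
    centers = np.asarray(centers, dtype=float)
    return ceff.at(centers)
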