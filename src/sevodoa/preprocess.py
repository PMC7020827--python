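"""EEG preprocessing: notch and band-pass filtering, windowing, feature smoothing.

Filters are applied zero-phase (forward-backward) so filtered signals and the
feature tracks derived from them carry no systematic time shift relative to
the concentration labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from .records import EEGRecord

__all__ = [
    "WindowedEEG",
    "notch_filter",
    "bandpass_filter",
    "window",
    "smooth_feature_track",
]

#: fraction of Nyquist at which an upper band edge is clamped.  A Butterworth
#: edge at exactly fs/2 is ill-posed; recordings sampled at 100 Hz with the
#: standard 0.8-50 Hz band hit this, so 50 Hz is pulled just inside Nyquist.
NYQUIST_MARGIN = 0.99


@dataclass
class WindowedEEG:
    """Fixed-length analysis windows cut from one EEG record.

    ``windows`` has shape (n_windows, window_len); ``centers_s`` gives each
    window's center time, used to align labels.
    """

    windows: np.ndarray
    centers_s: np.ndarray
    window_len: int
    stride: int
    fs: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.windows.ndim != 2 or self.windows.shape[1] != self.window_len:
            raise ValueError("windows must be (n_windows, window_len)")
        if self.centers_s.size > 1 and not np.all(np.diff(self.centers_s) > 0):
            raise ValueError("window centers must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def notch_filter(rec: EEGRecord, mains_hz: float = 50.0, q: float = 35.0) -> EEGRecord:
    """Remove mains interference with a zero-phase IIR notch.

    ``q`` controls the notch width (bandwidth = mains_hz / q); the default is
    narrow enough that a 10 Hz passband tone passes within a fraction of a
    percent while the mains tone is attenuated far beyond 20 dB.
    """
    nyq = rec.fs / 2.0
    if not 0 < mains_hz < nyq:
        raise ValueError(f"mains frequency {mains_hz} Hz must lie in (0, {nyq}) Hz")
    b, a = signal.iirnotch(mains_hz, Q=q, fs=rec.fs)
    return rec.with_samples(signal.filtfilt(b, a, rec.samples))


def bandpass_filter(
    rec: EEGRecord,
    low_hz: float = 0.8,
    high_hz: float = 50.0,
    order: int = 6,
) -> EEGRecord:
    """Zero-phase Butterworth band-pass (defaults 0.8-50 Hz, order 6).

    An upper edge at or above Nyquist is clamped to ``NYQUIST_MARGIN * fs/2``
    with a warning; at the standard 100 Hz sampling rate the nominal 50 Hz
    edge therefore becomes 49.5 Hz.
    """
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    nyq = rec.fs / 2.0
    high_eff = high_hz
    if high_hz >= nyq:
        high_eff = NYQUIST_MARGIN * nyq
        warnings.warn(
            f"band-pass upper edge {high_hz} Hz >= Nyquist ({nyq} Hz); "
            f"clamped to {high_eff:.3g} Hz",
            stacklevel=2,
        )
    if high_eff <= low_hz:
        raise ValueError(
            f"upper edge {high_eff:.3g} Hz (after Nyquist clamping) must exceed low_hz"
        )
    sos = signal.butter(order, [low_hz, high_eff], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples))


def window(rec: EEGRecord, window_len: int = 500, stride: int = 500) -> WindowedEEG:
    """Cut the record into fixed-length windows.

    Windows are contiguous slices starting every ``stride`` samples; a
    trailing partial window is discarded, giving
    n = floor((len - window_len)/stride) + 1 windows.
    """
    n = rec.n_samples
    if window_len > n:
        raise ValueError(f"window_len {window_len} exceeds record length {n}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n_windows = (n - window_len) // stride + 1
    starts = np.arange(n_windows) * stride
    idx = starts[:, None] + np.arange(window_len)[None, :]
    centers = rec.t0 + (starts + window_len / 2.0) / rec.fs
    return WindowedEEG(
        windows=rec.samples[idx],
        centers_s=centers,
        window_len=window_len,
        stride=stride,
        fs=rec.fs,
        subject_id=rec.subject_id,
    )


def smooth_feature_track(
    track: np.ndarray, wavelet: str = "db4", level: int = 3
) -> np.ndarray:
    """Wavelet-threshold denoising of a per-window feature time series.

    Decomposes the track to ``level`` scales, soft-thresholds the detail
    coefficients with the universal threshold sigma sqrt(2 ln n) (sigma
    estimated from the finest-scale details via the median absolute
    deviation), and reconstructs.  Smooth tracks pass essentially unchanged:
    the 'smooth' (linear-extrapolation) boundary mode keeps the details of a
    pure ramp at zero, and a constant track is returned exactly.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 1:
        raise ValueError("feature track must be 1-D")
    n = track.size
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    if n < 2**level:
        raise ValueError(f"track of length {n} too short for level {level}")
    coeffs = pywt.wavedec(track, wavelet, mode="smooth", level=level)
    detail_fine = coeffs[-1]
    sigma = np.median(np.abs(detail_fine - np.median(detail_fine))) / 0.6745
    if sigma > 0:
        thresh = sigma * np.sqrt(2.0 * np.log(n))
        coeffs = [coeffs[0]] + [pywt.threshold(d, thresh, mode="soft") for d in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet, mode="smooth")
    return out[:n]
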