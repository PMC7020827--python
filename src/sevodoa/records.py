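"""Core data containers: single-channel EEG records and drug-concentration series.

Everything downstream (filtering, windowing, feature extraction, PK/PD
labelling) operates on these two containers.  EEG is a uniformly sampled
microvolt trace; concentrations are time-stamped sevoflurane values in
volume percent, either measured end-tidal gas (``end_tidal``) or the modelled
effect-site concentration (``effect_site``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecord",
    "ConcentrationSeries",
    "read_eeg_csv",
    "write_eeg_csv",
    "read_eeg_edf",
    "read_concentration_csv",
    "write_concentration_csv",
]


@dataclass
class EEGRecord:
    """Uniformly sampled single-channel EEG.

    Parameters
    ----------
    samples : array of float
        Signal amplitude in microvolts.
    fs : float
        Sampling rate in Hz.
    subject_id : str, optional
        Label carried through the pipeline for cohort bookkeeping.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    subject_id: str | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("EEG samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EEGRecord":
        """Copy of this record with the signal replaced (rate/labels kept)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class ConcentrationSeries:
    """Time-stamped sevoflurane concentration (vol %).

    ``kind`` distinguishes the measured end-tidal gas concentration from the
    first-order effect-site transform used as the regression label.
    """

    t: np.ndarray
    c: np.ndarray
    kind: str = "end_tidal"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.t.ndim != 1 or self.t.size < 1 or self.t.shape != self.c.shape:
            raise ValueError("t and c must be 1-D arrays of equal, non-zero length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time base must be strictly increasing")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.c)):
            raise ValueError("concentration series must be finite")
        if np.any(self.c < 0):
            raise ValueError("concentrations must be non-negative")
        if self.kind not in ("end_tidal", "effect_site"):
            raise ValueError(f"unknown series kind {self.kind!r}")

    def at(self, t_new: np.ndarray) -> np.ndarray:
        """Linear interpolation at ``t_new``; raises outside the time span."""
        t_new = np.asarray(t_new, dtype=float)
        if t_new.size and (t_new.min() < self.t[0] - 1e-9 or t_new.max() > self.t[-1] + 1e-9):
            raise ValueError(
                f"requested times [{t_new.min():g}, {t_new.max():g}] outside the "
                f"series span [{self.t[0]:g}, {self.t[-1]:g}]"
            )
        return np.interp(t_new, self.t, self.c)


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Two columns, header optional: time_s, value.
# ---------------------------------------------------------------------------

def _read_two_columns(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    # A headerless numeric file parses with its first row as column names;
    # recover it by re-reading without a header.
    try:
        float(df.columns[0])
    except (TypeError, ValueError):
        pass
    else:
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def read_eeg_csv(path, fs: float | None = None, subject_id: str | None = None) -> EEGRecord:
    """Read EEG from delimited text with (time_s, uV) columns.

    The sampling rate is inferred from the median time step unless given.
    """
    t, v = _read_two_columns(path)
    if t.size < 2 and fs is None:
        raise ValueError(f"{path}: cannot infer sampling rate from a single sample")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return EEGRecord(samples=v, fs=fs, subject_id=subject_id, t0=float(t[0]))


def write_eeg_csv(rec: EEGRecord, path) -> None:
    pd.DataFrame({"time_s": rec.times, "uV": rec.samples}).to_csv(path, index=False)


def read_concentration_csv(path, kind: str = "end_tidal") -> ConcentrationSeries:
    t, c = _read_two_columns(path)
    return ConcentrationSeries(t=t, c=c, kind=kind)


def write_concentration_csv(series: ConcentrationSeries, path) -> None:
    pd.DataFrame({"time_s": series.t, "vol_pct": series.c}).to_csv(path, index=False)


def read_eeg_edf(path, channel: str | int = 0, subject_id: str | None = None) -> EEGRecord:
    """Read one channel of an EDF file as an :class:`EEGRecord` (requires mne).

    Amplitudes are converted from Volts (mne's internal unit) to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    name = raw.ch_names[channel] if isinstance(channel, int) else channel
    data = raw.get_data(picks=[name])[0] * 1e6
    return EEGRecord(samples=data, fs=float(raw.info["sfreq"]), subject_id=subject_id)
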