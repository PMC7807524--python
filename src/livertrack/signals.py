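"""Motion-trace container, CSV I/O and preprocessing.

A :class:`MotionTrace` is a uniformly sampled 3-axis displacement time series
in millimetres: x = left-right, y = superior-inferior, z = anterior-posterior.
Paired chest-surface (external) and liver (internal) traces from one session
are held in :class:`PairedTraces` after length alignment.

Preprocessing follows the usual pipeline for optically acquired breathing
surrogates: resampling onto a common grid, outlier replacement (Hampel rule),
smoothing plus zero-phase low-pass filtering, and per-axis z-scoring whose
statistics are always taken from training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .metrics import AXES

__all__ = [
    "MotionTrace", "PairedTraces", "StandardizationStats",
    "read_trace_csv", "write_trace_csv", "resample_to_length",
    "remove_outliers", "smooth_and_filter", "standardize", "destandardize",
]

CSV_COLUMNS = ("time_s", "x_mm", "y_mm", "z_mm")


@dataclass(frozen=True)
class MotionTrace:
    """Uniformly sampled 3-axis displacement series.

    Parameters
    ----------
    values : (N, 3) float array, displacements in mm, axis order (x, y, z).
    sampling_rate_hz : samples per second, > 0.
    start_time_s : wall-clock offset of the first sample.
    """

    values: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("values must have shape (N, 3)")
        if v.shape[0] < 2:
            raise ValueError("trace needs at least 2 samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self)) / self.sampling_rate_hz

    def axis(self, name: str) -> np.ndarray:
        return self.values[:, AXES.index(name)]

    def with_values(self, values: np.ndarray) -> "MotionTrace":
        return replace(self, values=values)

    def slice(self, start: int, stop: int) -> "MotionTrace":
        return MotionTrace(self.values[start:stop], self.sampling_rate_hz,
                           self.start_time_s + start / self.sampling_rate_hz)


@dataclass(frozen=True)
class PairedTraces:
    """Length-aligned external (chest surface) + internal (liver) pair."""

    external: MotionTrace
    internal: MotionTrace

    def __post_init__(self):
        if len(self.external) != len(self.internal):
            raise ValueError("external and internal traces differ in length")
        if not np.isclose(self.external.sampling_rate_hz,
                          self.internal.sampling_rate_hz):
            raise ValueError("sampling rates differ")

    def __len__(self) -> int:
        return len(self.external)

    def slice(self, start: int, stop: int) -> "PairedTraces":
        return PairedTraces(self.external.slice(start, stop),
                            self.internal.slice(start, stop))


@dataclass(frozen=True)
class StandardizationStats:
    """Per-axis mean/SD (mm) used for z-scoring; SD must be positive."""

    mean: np.ndarray  # (3,)
    std: np.ndarray   # (3,)

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=float).reshape(3)
        s = np.asarray(self.std, dtype=float).reshape(3)
        if np.any(s <= 0):
            raise ValueError("standard deviation must be > 0 on every axis")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "std", s)


def read_trace_csv(path) -> MotionTrace:
    """Read a trace from CSV with header ``time_s,x_mm,y_mm,z_mm``.

    The sampling rate is inferred as the reciprocal of the median time step;
    row order is preserved.  A non-monotone time column is rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(t)
    if len(t) < 2 or np.any(steps <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    fs = 1.0 / float(np.median(steps))
    values = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return MotionTrace(values, sampling_rate_hz=fs, start_time_s=float(t[0]))


def write_trace_csv(trace: MotionTrace, path) -> None:
    """Write a trace as CSV (full float precision, round-trip exact)."""
    df = pd.DataFrame({
        "time_s": trace.times,
        "x_mm": trace.values[:, 0],
        "y_mm": trace.values[:, 1],
        "z_mm": trace.values[:, 2],
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def resample_to_length(trace: MotionTrace, target_length: int) -> MotionTrace:
    """Linearly resample onto a uniform grid spanning the original time range.

    Endpoints are preserved exactly; used to align the external trace with
    the internal one when the acquisition devices ran at different rates.
    """
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    n = len(trace)
    if target_length == n:
        return trace
    old = np.linspace(0.0, 1.0, n)
    new = np.linspace(0.0, 1.0, target_length)
    values = np.column_stack([np.interp(new, old, trace.values[:, a])
                              for a in range(3)])
    new_fs = (target_length - 1) / (n - 1) * trace.sampling_rate_hz
    return MotionTrace(values, sampling_rate_hz=new_fs,
                       start_time_s=trace.start_time_s)


def remove_outliers(trace: MotionTrace, window: int = 7,
                    n_mad: float = 3.0) -> MotionTrace:
    """Hampel filter: replace spikes by the rolling median.

    A sample deviating from the centred rolling median by more than
    ``n_mad * 1.4826 * MAD`` (MAD = rolling median absolute deviation) is
    replaced by that median.  Replacement, not deletion, keeps the sampling
    uniform, which downstream windowing requires.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window >= len(trace):
        raise ValueError("window must be smaller than the trace")

    def hampel_pass(x: np.ndarray) -> np.ndarray:
        n = len(x)
        half = window // 2
        med = np.empty(n)
        mad = np.empty(n)
        for j in range(n):  # shrunken windows at the edges
            w = x[max(0, j - half): j + half + 1]
            med[j] = np.median(w)
            mad[j] = np.median(np.abs(w - med[j]))
        # zero MAD means the window is locally constant: any deviation
        # from that constant is then an outlier
        dev = np.abs(x - med)
        bad = np.where(mad > 0, dev > n_mad * 1.4826 * mad, dev > 0)
        out = x.copy()
        out[bad] = med[bad]
        return out

    out = trace.values.copy()
    for a in range(3):
        x = out[:, a]
        for _ in range(20):  # iterate to a fixpoint (idempotent output)
            cleaned = hampel_pass(x)
            if np.array_equal(cleaned, x):
                break
            x = cleaned
        out[:, a] = x
    return trace.with_values(out)


def smooth_and_filter(trace: MotionTrace, smooth_window: int = 5,
                      cutoff_hz: float = 2.0) -> MotionTrace:
    """Centred moving average followed by a zero-phase 4th-order low-pass.

    Breathing energy sits below ~1 Hz, so the default 2 Hz cutoff removes
    sensor noise without touching the physiological band; filtfilt keeps the
    phase response flat so no artificial latency is introduced.  Constant
    signals pass unchanged (unit DC gain).
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    nyq = trace.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff_hz must be in (0, {nyq})")
    out = trace.values
    if smooth_window > 1:
        out = np.column_stack([
            pd.Series(out[:, a]).rolling(smooth_window, center=True,
                                         min_periods=1).mean().to_numpy()
            for a in range(3)])
    sos = _sig.butter(4, cutoff_hz, btype="low", output="sos",
                      fs=trace.sampling_rate_hz)
    out = np.column_stack([_sig.sosfiltfilt(sos, out[:, a]) for a in range(3)])
    return trace.with_values(out)


def standardize(trace: MotionTrace,
                stats: StandardizationStats | None = None
                ) -> tuple[MotionTrace, StandardizationStats]:
    """Per-axis z-score.  If ``stats`` is None they are computed from this
    trace; otherwise the given (training-set) statistics are applied."""
    if stats is None:
        mean = trace.values.mean(axis=0)
        std = trace.values.std(axis=0)
        if np.any(std <= 0):
            raise ValueError("constant axis: cannot standardize (zero SD)")
        stats = StandardizationStats(mean=mean, std=std)
    out = (trace.values - stats.mean) / stats.std
    return trace.with_values(out), stats


def destandardize(trace: MotionTrace,
                  stats: StandardizationStats) -> MotionTrace:
    """Exact inverse of :func:`standardize` for the same stats."""
    return trace.with_values(trace.values * stats.std + stats.mean)
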