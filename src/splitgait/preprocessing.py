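"""Marker/CoP signal conditioning and baseline referencing.

Standard gait-lab preprocessing: zero-phase Butterworth low-pass filtering,
cubic-spline filling of short marker occlusions (long occlusions are
excluded rather than filled), 100-point time-normalization of step
segments, and subtraction of the baseline-slow mean from every per-step
parameter series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

__all__ = [
    "Signal",
    "BaselineStats",
    "lowpass_filter",
    "fill_gaps",
    "normalize_step",
    "subtract_baseline",
    "compute_baseline_stats",
]

#: Parameters whose reference magnitude can be near zero in natural units.
NEAR_ZERO_GUARD = 1e-3


@dataclass
class Signal:
    """A uniformly sampled 1-D signal with a missing-data mask.

    ``mask`` is True where the sample is missing (occluded).  Missing
    samples hold NaN in ``values``.
    """

    values: np.ndarray
    fs: float
    mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask length must equal values length")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs


def lowpass_filter(signal: Signal, cutoff_hz: float = 10.0, order: int = 4) -> Signal:
    """Zero-phase Butterworth low-pass filter.

    A filter of the given order is designed and applied forward-backward
    (``filtfilt``), so the effective magnitude response is the square of
    the designed response and the phase is zero.  Each contiguous observed
    run is filtered independently; missing samples stay missing.  DC gain
    is exactly 1.
    """
    nyq = signal.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    b, a = butter(order, cutoff_hz, fs=signal.fs)
    default_padlen = 3 * max(len(a), len(b))
    out = signal.values.copy()
    for start, stop in _observed_runs(signal.mask):
        seg = signal.values[start:stop]
        if len(seg) <= 3:
            continue  # too short to filter; leave as observed
        padlen = min(default_padlen, len(seg) - 1)
        out[start:stop] = filtfilt(b, a, seg, padlen=padlen)
    return Signal(out, signal.fs, signal.mask.copy())


def _observed_runs(mask):
    """Yield (start, stop) index pairs of contiguous observed samples."""
    idx = np.flatnonzero(~mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    yield from zip(starts, stops)


def _missing_runs(mask):
    yield from _observed_runs(~mask)


def fill_gaps(signal: Signal, max_gap_ms: float = 100.0):
    """Fill short occlusion gaps with cubic splines; exclude long ones.

    Gaps up to ``max_gap_ms`` (inclusive) are interpolated with a cubic
    spline through up to 4 flanking observed samples on each side.  Longer
    gaps, and gaps touching the signal boundary, are left missing and
    returned as exclusion intervals (start_s, end_s) covering the missing
    samples.  Observed samples are never altered.

    Returns ``(filled_signal, exclusions)``.
    """
    values = signal.values.copy()
    mask = signal.mask.copy()
    exclusions = []
    n = len(values)
    max_len = max_gap_ms / 1000.0 * signal.fs

    for start, stop in _missing_runs(signal.mask):
        gap_len = stop - start
        at_boundary = start == 0 or stop == n
        if gap_len > max_len + 1e-9 or at_boundary:
            exclusions.append((start / signal.fs, (stop - 1) / signal.fs))
            continue
        left = np.flatnonzero(~signal.mask[:start])[-4:]
        right = start + np.flatnonzero(~signal.mask[stop:])[:4] + (stop - start)
        support = np.concatenate((left, right))
        if len(left) < 2 or len(right) < 2:
            exclusions.append((start / signal.fs, (stop - 1) / signal.fs))
            continue
        spline = CubicSpline(support, signal.values[support])
        gap_idx = np.arange(start, stop)
        values[gap_idx] = spline(gap_idx)
        mask[gap_idx] = False

    return Signal(values, signal.fs, mask), exclusions


def normalize_step(segment) -> np.ndarray:
    """Resample one step segment (between consecutive heel strikes) to 100 points.

    Endpoints are preserved exactly; interior points by cubic-spline
    interpolation on the normalized time axis (linear when the segment is
    too short to support a cubic).
    """
    values = segment.values if isinstance(segment, Signal) else np.asarray(segment, dtype=float)
    if len(values) < 2:
        raise ValueError("segment must have at least 2 samples")
    x_old = np.linspace(0.0, 1.0, len(values))
    x_new = np.linspace(0.0, 1.0, 100)
    if len(values) < 4:
        return np.interp(x_new, x_old, values)
    out = CubicSpline(x_old, values)(x_new)
    out[0], out[-1] = values[0], values[-1]
    return out


@dataclass
class BaselineStats:
    """Baseline-slow means and percent-change reference magnitudes.

    ``means`` maps (parameter, foot) to the mean of valid baseline-slow
    steps; ``reference`` maps parameter to the magnitude used for
    percent-change conversion.  Parameters whose pooled baseline mean is
    below ``NEAR_ZERO_GUARD`` in natural units fall back to the mean
    absolute raw value and are listed in ``flagged``.
    """

    means: dict = field(default_factory=dict)
    reference: dict = field(default_factory=dict)
    flagged: set = field(default_factory=set)


def compute_baseline_stats(step_df, parameters) -> BaselineStats:
    """Compute :class:`BaselineStats` from baseline-slow step records.

    ``step_df`` must contain only (valid) baseline-slow steps, with
    columns ``foot`` plus one column per parameter.
    """
    stats = BaselineStats()
    valid = step_df[step_df["valid"]] if "valid" in step_df else step_df
    for param in parameters:
        for foot, grp in valid.groupby("foot"):
            stats.means[(param, foot)] = float(grp[param].mean())
        pooled = float(valid[param].mean())
        if abs(pooled) >= NEAR_ZERO_GUARD:
            stats.reference[param] = abs(pooled)
        else:
            stats.flagged.add(param)
            stats.reference[param] = float(valid[param].abs().mean())
    return stats


def subtract_baseline(series, baseline: BaselineStats, parameter: str, foot: str):
    """Subtract the baseline-slow mean from a per-step parameter series.

    Applied to every condition, including baseline slow itself.  Exactly
    invertible given the :class:`BaselineStats`.
    """
    key = (parameter, foot)
    if key not in baseline.means:
        raise KeyError(f"no baseline entry for parameter={parameter!r}, foot={foot!r}")
    return np.asarray(series, dtype=float) - baseline.means[key]
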