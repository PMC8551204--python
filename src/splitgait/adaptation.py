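"""Symmetry series and adaptation metrics.

The adaptation analysis works on *symmetry* series: for each gait
parameter, the difference between the fast-foot and slow-foot values
after baseline subtraction, ``s = delta_fast - delta_slow``, one value
per stride (a fast-led step paired with the following slow-led step).

The rate of adaptation is the *number of steps to plateau*: the plateau
is the mean of the last 50 symmetry values, and the reported step is the
first whose next 9 consecutive values all stay within 2 standard
deviations of that plateau.  The magnitude at plateau is the mean of the
9-value detection window, and the aftereffect magnitude is the mean of
the first 10 symmetry values of the after condition.  For pairwise
comparison across parameters, values are converted to percent change
from the baseline-slow mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import BaselineStats, subtract_baseline

__all__ = [
    "SymmetrySeries",
    "PlateauResult",
    "symmetry",
    "build_symmetry_series",
    "steps_to_plateau",
    "plateau_magnitude",
    "aftereffect_magnitude",
    "percent_change",
]

#: Band half-width substituted when the plateau SD is exactly zero, so
#: that exact-equality points count as inside the band.
ZERO_SD_EPS = 1e-12


@dataclass
class SymmetrySeries:
    parameter: str
    condition: str
    values: np.ndarray

    def __len__(self):
        return len(self.values)


@dataclass
class PlateauResult:
    """Steps-to-plateau detection outcome.

    ``steps_to_plateau`` is 1-based; when the detector never finds a
    window that stays inside the band, ``converged`` is False and the
    series length is reported instead (some series only settle at the
    very end of a trial).
    """

    steps_to_plateau: int
    plateau_mean: float
    plateau_sd: float
    magnitude: float
    converged: bool
    last_n: int = 50
    consec: int = 9


def symmetry(delta_fast, delta_slow) -> np.ndarray:
    """Elementwise fast-slow difference of baseline-subtracted series."""
    delta_fast = np.asarray(delta_fast, dtype=float)
    delta_slow = np.asarray(delta_slow, dtype=float)
    if delta_fast.shape != delta_slow.shape:
        raise ValueError("fast and slow series must have equal length after pairing")
    return delta_fast - delta_slow


def build_symmetry_series(step_df: pd.DataFrame, baseline: BaselineStats,
                          parameter: str, condition: str) -> SymmetrySeries:
    """Pair steps into strides and compute the symmetry series.

    Pairing rule: each valid fast-led step is paired with the next valid
    slow-led step; strides broken by invalid steps are dropped.
    """
    sub = step_df[(step_df["condition"] == condition) if "condition" in step_df else slice(None)]
    sub = sub[sub["valid"]] if "valid" in sub else sub
    feet = sub["foot"].to_numpy()
    vals = sub[parameter].to_numpy(dtype=float)
    steps = sub["step"].to_numpy()

    fast_vals, slow_vals = [], []
    i = 0
    while i < len(sub) - 1:
        if feet[i] == "fast" and feet[i + 1] == "slow" and steps[i + 1] == steps[i] + 1:
            fast_vals.append(vals[i])
            slow_vals.append(vals[i + 1])
            i += 2
        else:
            i += 1
    d_fast = subtract_baseline(fast_vals, baseline, parameter, "fast")
    d_slow = subtract_baseline(slow_vals, baseline, parameter, "slow")
    return SymmetrySeries(parameter=parameter, condition=condition,
                          values=symmetry(d_fast, d_slow))


def _series_values(series) -> np.ndarray:
    if isinstance(series, SymmetrySeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def steps_to_plateau(series, last_n: int = 50, k_sd: float = 2.0,
                     consec: int = 9) -> PlateauResult:
    """Detect the first sustained entry into the plateau band.

    The plateau level ``P`` is the mean and ``S`` the sample SD (ddof=1)
    of the last ``last_n`` values; the detection index (1-based) is the
    smallest ``s`` such that values ``s .. s+consec-1`` all satisfy
    ``|y - P| <= k_sd * S``.  Returns ``converged=False`` and the series
    length when no such window exists.
    """
    y = _series_values(series)
    n = len(y)
    if n < last_n + consec:
        raise ValueError(f"series too short ({n} < {last_n + consec})")
    tail = y[-last_n:]
    p = float(tail.mean())
    s_sd = float(tail.std(ddof=1))
    band = k_sd * s_sd if s_sd > 0 else ZERO_SD_EPS
    inside = np.abs(y - p) <= band
    window_ok = np.convolve(inside.astype(int), np.ones(consec, dtype=int), mode="valid") == consec
    hits = np.flatnonzero(window_ok)
    if len(hits) == 0:
        return PlateauResult(steps_to_plateau=n, plateau_mean=p, plateau_sd=s_sd,
                             magnitude=np.nan, converged=False,
                             last_n=last_n, consec=consec)
    s0 = int(hits[0])  # 0-based start of the detection window
    magnitude = float(y[s0:s0 + consec].mean())
    return PlateauResult(steps_to_plateau=s0 + 1, plateau_mean=p, plateau_sd=s_sd,
                         magnitude=magnitude, converged=True,
                         last_n=last_n, consec=consec)


def plateau_magnitude(series, result: PlateauResult, mode: str = "window") -> float:
    """Asymmetry magnitude at the time of plateau.

    ``mode``: ``"window"`` (default) averages the detection window;
    ``"instant"`` takes the value at the detection step; ``"plateau"``
    returns the last-50 mean itself.  Non-converged detections yield NaN.
    """
    if not result.converged:
        return float("nan")
    y = _series_values(series)
    s0 = result.steps_to_plateau - 1
    if mode == "window":
        return float(y[s0:s0 + result.consec].mean())
    if mode == "instant":
        return float(y[s0])
    if mode == "plateau":
        return result.plateau_mean
    raise ValueError(f"unknown mode {mode!r}")


def aftereffect_magnitude(series, first_n: int = 10) -> float:
    """Mean of the first ``first_n`` symmetry values of the after condition."""
    y = _series_values(series)
    if len(y) < first_n:
        raise ValueError(f"series too short ({len(y)} < {first_n})")
    return float(y[:first_n].mean())


def percent_change(delta, reference: BaselineStats | float, parameter: str | None = None):
    """Convert a baseline-subtracted value to percent of the baseline magnitude.

    ``reference`` may be a :class:`BaselineStats` (with ``parameter``
    naming the entry) or a plain positive magnitude.  A zero reference
    (after the near-zero guard) yields NaN.
    """
    if isinstance(reference, BaselineStats):
        if parameter is None:
            raise ValueError("parameter required with BaselineStats reference")
        ref = reference.reference[parameter]
    else:
        ref = float(reference)
    if ref == 0:
        return np.full_like(np.asarray(delta, dtype=float), np.nan) \
            if np.ndim(delta) else float("nan")
    return 100.0 * np.asarray(delta, dtype=float) / ref if np.ndim(delta) \
        else 100.0 * float(delta) / ref
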