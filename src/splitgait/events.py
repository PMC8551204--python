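"""Gait-event detection from marker extrema.

Heel strikes are the local maxima of forward progression of the heel
marker; push-offs are the local maxima of backward progression (local
minima of the AP position) of the toe marker.  On a treadmill the stance
foot travels backward with the belt, so each gait cycle produces exactly
one forward extremum per foot at ground contact and one backward extremum
at terminal contact.

Automated sequence validation replaces the visual inspection used in
practice: heel strikes must alternate between feet, every step needs
exactly one swing-foot push-off inside it, and steps overlapping marker
exclusion intervals are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocessing import Signal

__all__ = [
    "GaitEvents",
    "detect_heel_strikes",
    "detect_pushoffs",
    "assemble_events",
]

# Peak-acceptance defaults.  The shortest plausible step at 0.7-1.4 m/s is
# ~0.5 s and swing excursions are tens of cm, so these suppress noise-born
# extrema without touching genuine events.  Configurable per call.
MIN_SEPARATION_S = 0.4
MIN_PROMINENCE_M = 0.01


@dataclass
class GaitEvents:
    """Validated event sequence.

    ``strikes`` / ``pushoffs``: per-event tables (foot, sample, time_s,
    flagged).  ``steps``: one row per inter-strike interval with columns
    leading_foot, start_s, po_s (swing-foot push-off), end_s, valid,
    reason.  ``n_violations`` counts alternation violations.
    """

    strikes: pd.DataFrame
    pushoffs: pd.DataFrame
    steps: pd.DataFrame
    n_violations: int = 0


def _detect_extrema(values, fs, sign, min_separation_s, min_prominence_m, exclusions):
    x = sign * np.asarray(values, dtype=float)
    x = np.where(np.isnan(x), -np.inf, x)  # missing samples can't be peaks
    peaks, props = find_peaks(
        x,
        distance=max(1, round(min_separation_s * fs)),
        prominence=min_prominence_m,
        plateau_size=(1, None),
    )
    # ties (flat maxima) resolve to the first sample of the plateau
    samples = props["left_edges"]
    times = samples / fs
    flagged = np.zeros(len(samples), dtype=bool)
    for lo, hi in exclusions:
        flagged |= (times >= lo) & (times <= hi)
    return pd.DataFrame({"sample": samples, "time_s": times, "flagged": flagged})


def detect_heel_strikes(heel_ap: Signal, min_separation_s: float = MIN_SEPARATION_S,
                        min_prominence_m: float = MIN_PROMINENCE_M,
                        exclusions=()) -> pd.DataFrame:
    """Detect heel strikes as local maxima of the AP heel trajectory.

    Events inside ``exclusions`` (time intervals from gap handling) are
    flagged, not removed.  Monotone or empty signals yield no events.
    """
    return _detect_extrema(heel_ap.values, heel_ap.fs, +1.0,
                           min_separation_s, min_prominence_m, exclusions)


def detect_pushoffs(toe_ap: Signal, min_separation_s: float = MIN_SEPARATION_S,
                    min_prominence_m: float = MIN_PROMINENCE_M,
                    exclusions=()) -> pd.DataFrame:
    """Detect push-offs as local maxima of backward progression of the toe."""
    return _detect_extrema(toe_ap.values, toe_ap.fs, -1.0,
                           min_separation_s, min_prominence_m, exclusions)


def assemble_events(hs_left, hs_right, po_left, po_right, exclusions=()) -> GaitEvents:
    """Merge per-foot events into a validated alternating step sequence.

    Heel-strike tables are merged and sorted; consecutive same-foot
    strikes are alternation violations, and both steps enclosing a
    violation are excluded.  Each step is assigned the push-off of its
    swing foot (the foot striking at the step's end); steps overlapping an
    exclusion interval, lacking a unique push-off, or containing flagged
    events are marked invalid with a reason code.
    """
    strikes = _stack_events(hs_left, hs_right)
    pushoffs = _stack_events(po_left, po_right)
    if len(strikes) < 2:
        raise ValueError("need at least 2 heel strikes to assemble steps")

    feet = strikes["foot"].to_numpy()
    times = strikes["time_s"].to_numpy()
    violation_at = np.flatnonzero(feet[1:] == feet[:-1])  # index of first of pair
    n_violations = len(violation_at)

    rows = []
    for i in range(len(strikes) - 1):
        leading = feet[i]
        swing = feet[i + 1]
        start, end = times[i], times[i + 1]
        valid, reason = True, ""
        # a violation at strike pair (i, i+1) invalidates the two steps
        # that use the suspect duplicate strike: steps i and i+1
        if swing == leading or i in violation_at or (i - 1) in violation_at:
            valid, reason = False, "alternation_violation"
        po_s = np.nan
        if valid:
            cand = pushoffs[(pushoffs["foot"] == swing)
                            & (pushoffs["time_s"] > start)
                            & (pushoffs["time_s"] < end)]
            if len(cand) != 1:
                valid, reason = False, "pushoff_missing" if len(cand) == 0 else "pushoff_multiple"
            else:
                po_s = float(cand["time_s"].iloc[0])
                if bool(cand["flagged"].iloc[0]) or bool(strikes["flagged"].iloc[i]) \
                        or bool(strikes["flagged"].iloc[i + 1]):
                    valid, reason = False, "event_in_gap"
        if valid:
            for lo, hi in exclusions:
                if start <= hi and end >= lo:
                    valid, reason = False, "gap_overlap"
                    break
        rows.append({"leading_foot": leading, "start_s": start, "po_s": po_s,
                     "end_s": end, "valid": valid, "reason": reason})

    return GaitEvents(strikes=strikes, pushoffs=pushoffs,
                      steps=pd.DataFrame(rows), n_violations=n_violations)


def _stack_events(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    left = left.assign(foot="left")
    right = right.assign(foot="right")
    merged = pd.concat([left, right], ignore_index=True)
    return merged.sort_values("time_s", kind="stable").reset_index(drop=True)
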