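"""Per-step gait parameters.

Seven parameters are computed for every step, grouped as in the analysis
they support:

* spatial: step length (AP), step width (ML);
* temporal: single stance time, double stance time;
* CoM-referenced (ML balance): CoM position at heel strike, the integral
  of the CoP-CoM displacement over single stance, and the swing-heel
  displacement from the CoM at heel strike.

Conventions
-----------
ML = x, positive toward the left (fast) belt; AP = y, positive forward.
The left foot is labeled *fast* and the right foot *slow* (the belts they
ride during the split condition).  A step record is keyed by the leading
foot's heel strike at ``t_k`` and covers the interval to the next strike:
the at-strike quantities (step length/width, CoM, step-CoM) are evaluated
at ``t_k`` where the stance foot is the *trailing* foot, while the
interval quantities (stance times, CoP-CoM integral) belong to single
stance on the *leading* foot inside ``[t_k, t_{k+1})``.

CoM-referenced quantities are reported with positive = toward the stance
foot: reported = lab-frame value x (+1 if the stance foot is the left/fast
foot, else -1), making fast- and slow-side series directly comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FOOT_OF_SIDE",
    "PARAMETERS",
    "step_length",
    "step_width",
    "single_stance_time",
    "double_stance_time",
    "com_ml_at_heelstrike",
    "int_cop_com",
    "step_com",
    "toward_stance_sign",
    "extract_all",
]

FOOT_OF_SIDE = {"left": "fast", "right": "slow"}
SIDE_OF_FOOT = {"fast": "left", "slow": "right"}

PARAMETERS = (
    "step_length",
    "step_width",
    "single_stance_time",
    "double_stance_time",
    "com",
    "int_cop_com",
    "step_com",
)


def toward_stance_sign(stance_side: str) -> float:
    """Sign mapping lab-frame ML (+ = left) to 'positive toward the stance foot'."""
    return 1.0 if stance_side == "left" else -1.0


def step_length(trailing_heel_ap: float, leading_heel_ap: float) -> float:
    """Signed AP distance from trailing to leading heel at the leading strike."""
    return leading_heel_ap - trailing_heel_ap


def step_width(trailing_heel_ml: float, leading_heel_ml: float) -> float:
    """Absolute ML distance between the heels at the leading strike."""
    return abs(leading_heel_ml - trailing_heel_ml)


def single_stance_time(swing_pushoff_t: float, swing_heelstrike_t: float) -> float:
    """Time between the swing foot's push-off and its heel strike."""
    dt = swing_heelstrike_t - swing_pushoff_t
    if dt < 0:
        raise ValueError("push-off must precede the swing foot's heel strike")
    return dt


def double_stance_time(stance_heelstrike_t: float, swing_pushoff_t: float) -> float:
    """Time between the stance foot's heel strike and the swing foot's push-off."""
    dt = swing_pushoff_t - stance_heelstrike_t
    if dt < 0:
        raise ValueError("heel strike must precede the other foot's push-off")
    return dt


def com_ml_at_heelstrike(hip_left_ml: float, hip_right_ml: float) -> float:
    """CoM proxy: midpoint of the posterior hip markers (lab frame)."""
    return 0.5 * (hip_left_ml + hip_right_ml)


def int_cop_com(cop_ml, com_ml, t) -> float:
    """Trapezoidal integral of (CoP - CoM) ML displacement over single stance.

    ``cop_ml``/``com_ml`` are sampled on the common time base ``t``
    covering the single-stance interval; the result is in m*s of lab-frame
    displacement (caller applies the toward-stance sign remap).  Real time
    is used rather than the normalized cycle: stance durations differ
    between belts and the duration itself carries the effect of interest.
    """
    cop_ml = np.asarray(cop_ml, dtype=float)
    if np.any(np.isnan(cop_ml)):
        raise ValueError("CoP contains unloaded-belt samples inside single stance")
    return float(np.trapezoid(cop_ml - np.asarray(com_ml, dtype=float), np.asarray(t)))


def step_com(swing_heel_ml: float, com_ml: float) -> float:
    """Lab-frame ML displacement of the swing heel from the CoM at heel strike."""
    return swing_heel_ml - com_ml


def _at(signal_values, idx):
    return float(signal_values[idx])


def extract_all(trial, gait_events, markers=None) -> pd.DataFrame:
    """Compute all seven parameters for every step of one trial.

    Parameters
    ----------
    trial:
        A :class:`~splitgait.synthetic_data.TrialRecording` (or any object
        with the same attributes).
    gait_events:
        Validated :class:`~splitgait.events.GaitEvents`.
    markers:
        Optional preprocessed marker signals, ``{name: {axis: ndarray}}``
        with names heel_l/heel_r/toe_l/toe_r/hip_l/hip_r and axes ml/ap.
        Defaults to the raw trial markers.

    Returns a step table with one row per step, invalid steps retained
    with a reason code.  Raises ``ValueError`` when no step is valid.
    """
    steps = gait_events.steps
    if len(steps) == 0:
        raise ValueError("empty event list")
    if markers is None:
        markers = trial.markers
    fs = trial.fs_marker
    t_cop = trial.t_cop

    heel = {"left": markers["heel_l"], "right": markers["heel_r"]}
    hip_l, hip_r = markers["hip_l"], markers["hip_r"]
    cop = {"left": trial.cop_left_ml, "right": trial.cop_right_ml}
    load = {"left": trial.load_left, "right": trial.load_right}
    com_full = 0.5 * (hip_l["ml"] + hip_r["ml"])

    rows = []
    for k, st in steps.iterrows():
        leading_side = st["leading_foot"]  # 'left' | 'right'
        trailing_side = "right" if leading_side == "left" else "left"
        rec = {
            "step": k,
            "foot": FOOT_OF_SIDE[leading_side],
            "time_s": st["start_s"],
            "valid": bool(st["valid"]),
            "reason": st["reason"],
        }
        for p in PARAMETERS:
            rec[p] = np.nan
        if not st["valid"]:
            rows.append(rec)
            continue

        i_hs = int(round(st["start_s"] * fs))
        i_po = int(round(st["po_s"] * fs))
        i_end = int(round(st["end_s"] * fs))
        try:
            lead_ap = _at(heel[leading_side]["ap"], i_hs)
            trail_ap = _at(heel[trailing_side]["ap"], i_hs)
            lead_ml = _at(heel[leading_side]["ml"], i_hs)
            trail_ml = _at(heel[trailing_side]["ml"], i_hs)
            hl = _at(hip_l["ml"], i_hs)
            hr = _at(hip_r["ml"], i_hs)
        except IndexError:
            rec["valid"], rec["reason"] = False, "marker_out_of_range"
            rows.append(rec)
            continue
        needed = (lead_ap, trail_ap, lead_ml, trail_ml, hl, hr)
        if any(np.isnan(v) for v in needed):
            rec["valid"], rec["reason"] = False, "marker_missing"
            rows.append(rec)
            continue

        com_lab = com_ml_at_heelstrike(hl, hr)
        # at the strike instant the stance foot is the trailing foot
        sgn_at_strike = toward_stance_sign(trailing_side)
        rec["step_length"] = step_length(trail_ap, lead_ap)
        rec["step_width"] = step_width(trail_ml, lead_ml)
        rec["com"] = sgn_at_strike * com_lab
        rec["step_com"] = sgn_at_strike * step_com(lead_ml, com_lab)

        try:
            rec["double_stance_time"] = double_stance_time(st["start_s"], st["po_s"])
            rec["single_stance_time"] = single_stance_time(st["po_s"], st["end_s"])
        except ValueError:
            rec["valid"], rec["reason"] = False, "negative_interval"
            rows.append(rec)
            continue

        # single stance on the leading foot: integrate CoP-CoM there
        j0 = int(np.searchsorted(t_cop, st["po_s"]))
        j1 = int(np.searchsorted(t_cop, st["end_s"], side="right"))
        seg_t = t_cop[j0:j1]
        seg_cop = cop[leading_side][j0:j1]
        if not np.all(load[leading_side][j0:j1]):
            rec["valid"], rec["reason"] = False, "belt_unloaded"
            rows.append(rec)
            continue
        seg_com = np.interp(seg_t, trial.t_marker, com_full)
        if np.any(np.isnan(seg_com)):
            rec["valid"], rec["reason"] = False, "marker_missing"
            rows.append(rec)
            continue
        try:
            integral = int_cop_com(seg_cop, seg_com, seg_t)
        except ValueError:
            rec["valid"], rec["reason"] = False, "belt_unloaded"
            rows.append(rec)
            continue
        rec["int_cop_com"] = toward_stance_sign(leading_side) * integral
        rows.append(rec)

    out = pd.DataFrame(rows)
    if not out["valid"].any():
        raise ValueError("no valid steps extracted")
    return out
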