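"""Synthetic split-belt treadmill data generator.

Produces, in order of increasing realism:

1. *Step truth* — per-step ground-truth values of the seven gait
   parameters for every condition of a walking protocol, following an
   exponential adaptation law during the split condition (approach to a
   plateau with time constant ``tau`` in steps) and an opposite-sign
   decaying aftereffect when the belts are tied again.
2. *Trial recordings* — continuous marker and per-belt CoP signals that
   realize the step truth: heel-strike/push-off signatures appear as
   forward/backward AP marker extrema at the programmed times, the
   posterior-hip midpoint carries the programmed CoM, and the CoP lies
   under the loaded foot during single stance.  With zero added noise the
   downstream pipeline recovers the truth to numerical precision.
3. *Cohorts* — younger/older subject groups with per-subject random
   effects, where younger subjects carry a sustained split-condition
   asymmetry in the CoM-referenced parameters and older subjects do not.

Coordinate convention (used package-wide): ML = x, positive toward the
left (fast) belt; AP = y, positive forward; origin at the treadmill
center.  The left foot is the *fast* foot, the right foot the *slow* one.

Kinematic consistency: foot placements and the CoM trace are the
generative primitives in ML, so ``step_com`` ground truth is derived via
the identity placement = CoM + (heel - CoM) rather than programmed
independently, and ``int_cop_com`` truth is the programmed stance
CoP-CoM displacement times the realized single-stance duration.  All
event times are snapped to the marker sampling grid so that truth and
signal agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import SIDE_OF_FOOT

__all__ = [
    "Condition",
    "Protocol",
    "ParamLaw",
    "StepTruth",
    "TrialRecording",
    "SignalParams",
    "GroupParams",
    "CohortSubject",
    "default_protocol",
    "default_laws",
    "exponential_series",
    "generate_step_truth",
    "synthesize_trial",
    "generate_cohort",
]

BELT_SPEEDS = (0.7, 1.4)
SLOW, FAST = 0.7, 1.4

_OTHER_FOOT = {"fast": "slow", "slow": "fast"}


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    name: str
    duration_s: float
    left_speed: float
    right_speed: float
    acceleration: float = 0.5  # m/s^2, treadmill belt acceleration

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("condition duration must be positive")
        if self.left_speed not in BELT_SPEEDS or self.right_speed not in BELT_SPEEDS:
            raise ValueError(f"belt speeds must be in {BELT_SPEEDS}")
        if self.name == "split" and not (self.left_speed == FAST and self.right_speed == SLOW):
            raise ValueError("split condition must run left=1.4, right=0.7 m/s")


@dataclass(frozen=True)
class Protocol:
    conditions: tuple

    def __getitem__(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self):
        return [c.name for c in self.conditions]


def default_protocol(baseline_s: float = 120.0, split_s: float = 600.0,
                     after_s: float = 300.0) -> Protocol:
    """Analysis conditions of the split-belt adaptation protocol.

    Two-minute tied baselines at 0.7 and 1.4 m/s, a ten-minute split
    trial (left belt fast), and an after trial with both belts slow.
    """
    return Protocol(conditions=(
        Condition("baseline_slow", baseline_s, SLOW, SLOW),
        Condition("baseline_fast", baseline_s, FAST, FAST),
        Condition("split", split_s, FAST, SLOW),
        Condition("after", after_s, SLOW, SLOW),
    ))


# ---------------------------------------------------------------------------
# Adaptation laws and step truth
# ---------------------------------------------------------------------------

def exponential_series(n: int, start: float, plateau: float, tau: float) -> np.ndarray:
    """Noise-free adaptation law y_k = plateau + (start - plateau) * exp(-k/tau)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    k = np.arange(n)
    return plateau + (start - plateau) * np.exp(-k / tau)


@dataclass(frozen=True)
class ParamLaw:
    """Adaptation law of one parameter for one foot.

    ``base`` holds the stationary mean per baseline condition
    (keys ``baseline_slow`` / ``baseline_fast``; a second slow baseline
    reuses the first).  During split the series decays from
    ``split_start`` to ``split_plateau`` with time constant ``split_tau``
    (in steps of that foot); during after it decays from ``after_start``
    back to the slow-baseline mean with ``after_tau``.  ``noise_sd`` is
    the step-to-step SD added everywhere.
    """

    base: dict
    split_start: float
    split_plateau: float
    split_tau: float
    after_start: float
    after_tau: float
    noise_sd: float

    def __post_init__(self):
        if self.split_tau <= 0 or self.after_tau <= 0:
            raise ValueError("adaptation time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    def series(self, condition: str, n: int, rng) -> np.ndarray:
        if condition.startswith("baseline"):
            key = "baseline_fast" if condition == "baseline_fast" else "baseline_slow"
            mean = np.full(n, self.base[key])
        elif condition == "split":
            mean = exponential_series(n, self.split_start, self.split_plateau, self.split_tau)
        elif condition == "after":
            mean = exponential_series(n, self.after_start, self.base["baseline_slow"], self.after_tau)
        else:
            raise ValueError(f"unknown condition {condition!r}")
        if self.noise_sd > 0:
            mean = mean + rng.normal(0.0, self.noise_sd, size=n)
        return mean


def _law(base_slow, base_fast, split_start, split_plateau, tau, noise_sd,
         after_kappa=0.6, after_tau=8.0):
    """Build a ParamLaw; the aftereffect starts opposite the split change."""
    after_start = base_slow - after_kappa * (split_plateau - base_slow)
    return ParamLaw(
        base={"baseline_slow": base_slow, "baseline_fast": base_fast},
        split_start=split_start, split_plateau=split_plateau, split_tau=tau,
        after_start=after_start, after_tau=after_tau, noise_sd=noise_sd,
    )


#: Parameters that are generated directly; step_com and the two derived
#: timing aggregates come from these plus the kinematic identities.
GENERATED = ("step_length", "step_width", "single_stance_time",
             "double_stance_time", "com", "cop_disp")


def default_laws(com_asym: float = 0.0, cop_disp_asym: float = 0.0) -> dict:
    """Default adaptation laws per parameter per foot.

    ``com_asym`` / ``cop_disp_asym`` inject a sustained split-condition
    asymmetry into the CoM-referenced parameters (positive = CoM shifted
    toward the slow foot), zero for a symmetric walker.  Magnitudes are
    in natural units (m); timing in s.  Baselines follow the tied-belt
    conditions (step duration 0.68 s slow / 0.50 s fast, step width
    0.145 / 0.135 m); split step durations are 0.51 s for fast-led and
    0.61 s for slow-led steps.
    """
    laws = {}
    # spatial
    laws["step_length"] = {
        "fast": _law(0.476, 0.70, 0.45, 0.56, 40.0, 0.015),
        "slow": _law(0.476, 0.70, 0.66, 0.58, 40.0, 0.015),
    }
    laws["step_width"] = {
        f: _law(0.145, 0.135, 0.165, 0.150, 15.0, 0.008) for f in ("fast", "slow")
    }
    # temporal (single stance hovers near the respective baseline; double
    # stance starts asymmetric and converges)
    laws["single_stance_time"] = {
        "fast": _law(0.50, 0.38, 0.39, 0.39, 12.0, 0.012),
        "slow": _law(0.50, 0.38, 0.47, 0.47, 12.0, 0.012),
    }
    laws["double_stance_time"] = {
        "fast": _law(0.18, 0.12, 0.16, 0.13, 35.0, 0.008),
        "slow": _law(0.18, 0.12, 0.10, 0.13, 35.0, 0.008),
    }
    # CoM-referenced (values in the 'positive toward the stance foot' frame)
    laws["com"] = {
        "fast": _law(0.010, 0.000, 0.010, 0.010 - com_asym / 2, 10.0, 0.004),
        "slow": _law(0.010, 0.000, 0.010, 0.010 + com_asym / 2, 10.0, 0.004),
    }
    # stance-phase CoP-CoM displacement (m); int_cop_com = disp * stance time
    laws["cop_disp"] = {
        "fast": _law(0.020, 0.012, 0.016, 0.016 - cop_disp_asym / 2, 12.0, 0.003),
        "slow": _law(0.020, 0.012, 0.016, 0.016 + cop_disp_asym / 2, 12.0, 0.003),
    }
    return laws


@dataclass
class StepTruth:
    """Ground-truth per-step parameter table plus the generating laws.

    ``table`` columns: condition, step, foot, leading_side, t_strike,
    duration, the seven analysis parameters, and bookkeeping columns
    (cop_disp, placement_ml, com_lab).  ``fs_grid`` is the marker rate
    that all event times are snapped to.
    """

    table: pd.DataFrame
    laws: dict
    protocol: Protocol
    fs_grid: float = 120.0
    lead_in_s: float = 1.0

    def condition_steps(self, name: str) -> pd.DataFrame:
        return self.table[self.table["condition"] == name].reset_index(drop=True)


def _snap(x, fs):
    return np.round(np.asarray(x) * fs) / fs


def generate_step_truth(protocol: Protocol, adaptation_params: dict | None = None,
                        seed: int = 0, fs_grid: float = 120.0,
                        min_step_s: float = 0.2) -> StepTruth:
    """Generate the per-step ground truth for every protocol condition.

    ``adaptation_params`` maps parameter -> foot -> :class:`ParamLaw`
    (see :func:`default_laws`).  Feet alternate, starting with the fast
    (left) foot; all durations are snapped to the ``fs_grid`` sampling
    grid.  Raises ``ValueError`` for non-positive time constants or
    durations (checked by :class:`ParamLaw` / :class:`Condition`).
    """
    laws = adaptation_params if adaptation_params is not None else default_laws()
    rng = np.random.default_rng(seed)
    frames = []
    for cond in protocol.conditions:
        nominal = np.mean([
            laws["single_stance_time"][f].series(cond.name, 1, np.random.default_rng(0))[0]
            + laws["double_stance_time"][f].series(cond.name, 1, np.random.default_rng(0))[0]
            for f in ("fast", "slow")
        ])
        n = int(cond.duration_s // nominal)
        if n < 2:
            raise ValueError(f"condition {cond.name!r} too short for 2 steps")
        feet = np.array([("fast", "slow")[k % 2] for k in range(n)])

        draws = {}
        for param in GENERATED:
            vals = np.empty(n)
            for f in ("fast", "slow"):
                idx = np.flatnonzero(feet == f)
                vals[idx] = laws[param][f].series(cond.name, len(idx), rng)
            draws[param] = vals

        ss = _snap(np.maximum(draws["single_stance_time"], 2.0 / fs_grid), fs_grid)
        ds = _snap(np.maximum(draws["double_stance_time"], 2.0 / fs_grid), fs_grid)
        duration = ss + ds
        if np.any(duration <= min_step_s):
            raise ValueError("generated step duration at or below the plausible minimum")

        # ML geometry: placements alternate symmetrically about the treadmill
        # center (half the drawn step width per side), which keeps the walker
        # centered the way real treadmill gait does; the *realized* step width
        # |p_k - p_{k-1}| is what the truth table records.
        sigma_lead = np.where(feet == "fast", 1.0, -1.0)  # left = +
        half = draws["step_width"] / 2.0
        placements = sigma_lead * half
        prev_half = np.concatenate(([half[0]], half[:-1]))
        sw = half + prev_half  # realized width; equals the draw when constant
        # at the strike the stance foot is the trailing one
        sigma_stance = -sigma_lead
        com_rep = draws["com"]
        com_lab = np.where(sigma_stance > 0, com_rep, -com_rep)
        step_com_rep = np.where(sigma_stance > 0, 1.0, -1.0) * (placements - com_lab)

        t_strike = np.empty(n)
        t_strike[0] = 1.0  # lead-in, snapped grid value
        t_strike[1:] = 1.0 + np.cumsum(duration[:-1])

        frames.append(pd.DataFrame({
            "condition": cond.name,
            "step": np.arange(n),
            "foot": feet,
            "leading_side": [SIDE_OF_FOOT[f] for f in feet],
            "t_strike": t_strike,
            "duration": duration,
            "step_length": draws["step_length"],
            "step_width": sw,
            "single_stance_time": ss,
            "double_stance_time": ds,
            "com": com_rep,
            "int_cop_com": draws["cop_disp"] * ss,
            "step_com": step_com_rep,
            "cop_disp": draws["cop_disp"],
            "placement_ml": placements,
            "com_lab": com_lab,
        }))
    table = pd.DataFrame(pd.concat(frames, ignore_index=True))
    return StepTruth(table=table, laws=laws, protocol=protocol, fs_grid=fs_grid)


# ---------------------------------------------------------------------------
# Continuous signal synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalParams:
    """Knobs of the continuous-signal synthesis.

    Marker noise defaults to 1 mm RMS (optical capture jitter); dropouts
    are (marker, start_s, duration_s) occlusion intervals masked in the
    output.  ``hip_halfwidth`` separates the two posterior hip markers
    about the CoM; ``foot_length`` offsets the toe from the heel in AP.
    """

    fs_marker: float = 120.0
    fs_cop: float = 1200.0
    marker_noise_sd: float = 0.001
    cop_noise_sd: float = 0.001
    hip_halfwidth: float = 0.08
    foot_length: float = 0.20
    tail_s: float = 0.5
    contact_smooth_s: float = 0.05  # parabolic-cap half-width at AP extrema
    dropouts: tuple = ()


@dataclass
class TrialRecording:
    """Marker and CoP signals for one subject x condition."""

    subject: str
    group: str
    condition: str
    belt_speed_left: float
    belt_speed_right: float
    fs_marker: float
    t_marker: np.ndarray
    markers: dict  # name -> {"ml": ndarray, "ap": ndarray}
    marker_mask: dict  # name -> bool ndarray (True = missing)
    fs_cop: float
    t_cop: np.ndarray
    cop_left_ml: np.ndarray
    cop_right_ml: np.ndarray
    load_left: np.ndarray
    load_right: np.ndarray
    truth_events: dict  # generator bookkeeping, for validation only

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV layout: time_s plus one column per marker-axis."""
        data = {"time_s": self.t_marker}
        for name, axes in self.markers.items():
            for axis, vals in axes.items():
                data[f"{name}_{axis}"] = vals
        return pd.DataFrame(data)


def _hermite(t, t0, t1, y0, y1, m0, m1):
    """Cubic Hermite segment evaluated at t (array)."""
    T = t1 - t0
    s = (t - t0) / T
    s2, s3 = s * s, s * s * s
    return ((2 * s3 - 3 * s2 + 1) * y0 + (s3 - 2 * s2 + s) * T * m0
            + (-2 * s3 + 3 * s2) * y1 + (s3 - s2) * T * m1)


class _PiecewiseBuilder:
    """Fills a sampled trace segment by segment; boundaries lie on the grid."""

    def __init__(self, t_grid):
        self.t = t_grid
        self.y = np.full(len(t_grid), np.nan)

    def _slice(self, t0, t1, include_end=False):
        i0 = int(np.searchsorted(self.t, t0 - 1e-9))
        i1 = int(np.searchsorted(self.t, t1 - 1e-9))
        if include_end:
            i1 = min(i1 + 1, len(self.t))
        return slice(i0, i1)

    def linear(self, t0, t1, y0, slope, include_end=False):
        sl = self._slice(t0, t1, include_end)
        self.y[sl] = y0 + slope * (self.t[sl] - t0)

    def hermite(self, t0, t1, y0, y1, m0, m1, include_end=False):
        sl = self._slice(t0, t1, include_end)
        self.y[sl] = _hermite(self.t[sl], t0, t1, y0, y1, m0, m1)

    def parabola(self, t0, t1, tc, vertex, coef, include_end=False):
        sl = self._slice(t0, t1, include_end)
        self.y[sl] = vertex + coef * (self.t[sl] - tc) ** 2


def synthesize_trial(truth: StepTruth, condition: str,
                     signal_params: SignalParams | None = None,
                     seed: int = 0, subject: str = "S01",
                     group: str = "younger") -> TrialRecording:
    """Render one condition of a :class:`StepTruth` as continuous signals.

    Heel AP traces move backward with the belt during stance and swing
    forward along a cubic arc whose endpoint slopes equal the belt speed,
    so each programmed heel strike is a locally symmetric forward maximum
    (robust to zero-phase filtering); toe AP minima mark push-offs the
    same way.  The posterior-hip midpoint is piecewise linear through the
    programmed CoM values at the strikes, and the stance-belt CoP equals
    that CoM plus the programmed displacement, constant over each single
    stance.
    """
    sp = signal_params or SignalParams()
    steps = truth.condition_steps(condition)
    if len(steps) < 2:
        raise ValueError("need at least 2 steps per condition")
    if np.any(steps["duration"].to_numpy() < 2.0 / sp.fs_marker):
        raise ValueError("step duration shorter than 2 samples")
    cond = truth.protocol[condition]
    rng = np.random.default_rng(seed)
    v_of = {"left": cond.left_speed, "right": cond.right_speed}

    n = len(steps)
    lead_side = steps["leading_side"].to_numpy()
    t_strike = steps["t_strike"].to_numpy()
    ds = steps["double_stance_time"].to_numpy()
    ss = steps["single_stance_time"].to_numpy()
    sl_truth = steps["step_length"].to_numpy()
    place = steps["placement_ml"].to_numpy()
    com_lab = steps["com_lab"].to_numpy()
    disp = steps["cop_disp"].to_numpy()
    t_end_strike = t_strike[-1] + float(steps["duration"].iloc[-1])
    total_s = t_end_strike + sp.tail_s
    po_t = t_strike + ds  # push-off of the swing foot inside each step

    t_m = np.arange(round(total_s * sp.fs_marker) + 1) / sp.fs_marker
    t_c = np.arange(round(total_s * sp.fs_cop) + 1) / sp.fs_cop

    # contact smoothing: around each AP extremum the marker follows a C1
    # parabolic cap (half-width W) whose endpoint slopes equal the belt
    # speed, emulating the finite deceleration of a real foot at contact;
    # the extremum stays exactly at the programmed sample
    W = _snap(sp.contact_smooth_s, sp.fs_marker)

    # --- AP strike positions from the step-length recursion ----------------
    # trailing heel at t_k sits on its post-cap stance line:
    # x(t) = a_{k-1} + v*W/2 - v * (t - t_{k-1})
    a = np.empty(n + 1)
    a[0] = 0.3
    for k in range(1, n):
        v_tr = v_of[lead_side[k - 1]]
        a[k] = sl_truth[k] + a[k - 1] + v_tr * W / 2 - v_tr * (t_strike[k] - t_strike[k - 1])
    a[n] = a[n - 1] - v_of[lead_side[n - 1]] * (t_end_strike - t_strike[n - 1]) + (
        sl_truth[n - 1] if n < 2 else sl_truth[n - 2])  # plausible final strike
    strike_sides = list(lead_side) + [_other_side(lead_side[-1])]
    strike_times = np.append(t_strike, t_end_strike)
    place_full = np.append(place, place[-2] if n >= 2 else -place[-1])
    com_nodes = np.append(com_lab, com_lab[-1])

    # per-foot event schedules (strike index lists into strike_times)
    events = {"left": {"strikes": [], "pushoffs": []},
              "right": {"strikes": [], "pushoffs": []}}
    for i, side in enumerate(strike_sides):
        events[side]["strikes"].append(i)
    for k in range(n):
        events[_other_side(lead_side[k])]["pushoffs"].append(po_t[k])

    swing_pre = _snap(0.35, sp.fs_marker)
    markers = {}
    po_by_side = {}
    for side in ("left", "right"):
        v = v_of[side]
        s_idx = events[side]["strikes"]
        s_t = strike_times[s_idx]
        s_ap = a[s_idx]
        s_ml = place_full[s_idx]
        po = sorted(events[side]["pushoffs"])
        heel_ap = _PiecewiseBuilder(t_m)
        toe_ap = _PiecewiseBuilder(t_m)
        heel_ml = _PiecewiseBuilder(t_m)

        first_strike = s_t[0]
        pre_po = [p for p in po if p < first_strike]
        if pre_po:
            # trailing foot: its pre-trial stance must realize the first
            # step's programmed step length (AP) and step width (ML)
            p0 = pre_po[0]
            b_pre = (a[0] - sl_truth[0]) - v * (p0 - t_strike[0])
            ml_pre = -place[0]
        else:
            # first striker: give it a swing ending at its first strike
            p0 = _snap(first_strike - swing_pre, sp.fs_marker)
            po = [p0] + po
            b_pre = s_ap[0] - 0.5
            ml_pre = s_ml[0]
        # before the first strike: stance line, push-off cap, swing
        heel_ap.linear(0.0, p0 - W, b_pre + v * W + v * (p0 - W), -v)
        heel_ap.parabola(p0 - W, p0 + W, p0, b_pre + v * W / 2, v / (2 * W))
        heel_ap.hermite(p0 + W, first_strike - W, b_pre + v * W,
                        s_ap[0] - v * W / 2, v, v)
        heel_ap.parabola(first_strike - W, first_strike + W, first_strike,
                         s_ap[0], -v / (2 * W))
        toe_ap.linear(0.0, p0 - W, b_pre + sp.foot_length + v * W + v * (p0 - W), -v)
        toe_ap.parabola(p0 - W, p0 + W, p0, b_pre + sp.foot_length + v * W / 2,
                        v / (2 * W))
        toe_ap.hermite(p0 + W, first_strike, b_pre + sp.foot_length + v * W,
                       s_ap[0] + sp.foot_length, v, v)
        heel_ml.linear(0.0, p0, ml_pre, 0.0)
        heel_ml.hermite(p0, first_strike, ml_pre, s_ml[0], 0.0, 0.0)
        po_by_side[side] = np.asarray(po)

        po_after = {t0: [p for p in po if p > t0] for t0 in s_t}
        for i in range(len(s_t)):
            t0 = s_t[i]
            if i + 1 < len(s_t) and po_after[t0]:
                p_i = po_after[t0][0]
                t1 = s_t[i + 1]
                # heel: post-cap stance line, smooth at its own push-off is
                # not needed (no extremum there), cap at the next strike
                b_i = s_ap[i] + v * W / 2 - v * (p_i - t0)
                heel_ap.linear(t0 + W, p_i, s_ap[i] - v * W / 2, -v)
                heel_ap.hermite(p_i, t1 - W, b_i, s_ap[i + 1] - v * W / 2, -v, v)
                heel_ap.parabola(t1 - W, t1 + W, t1, s_ap[i + 1], -v / (2 * W))
                # toe: stance line from the strike, parabolic minimum at
                # push-off, swing to the next strike position
                B_i = s_ap[i] + sp.foot_length - v * (p_i - t0)
                toe_ap.linear(t0, p_i - W, s_ap[i] + sp.foot_length, -v)
                toe_ap.parabola(p_i - W, p_i + W, p_i, B_i + v * W / 2, v / (2 * W))
                toe_ap.hermite(p_i + W, t1, B_i + v * W,
                               s_ap[i + 1] + sp.foot_length, v, v)
                heel_ml.linear(t0, p_i, s_ml[i], 0.0)
                heel_ml.hermite(p_i, t1, s_ml[i], s_ml[i + 1], 0.0, 0.0)
            else:
                # final stance: backward with the belt until the trial ends
                heel_ap.linear(t0 + W, total_s, s_ap[i] - v * W / 2, -v,
                               include_end=True)
                toe_ap.linear(t0, total_s, s_ap[i] + sp.foot_length, -v,
                              include_end=True)
                heel_ml.linear(t0, total_s, s_ml[i], 0.0, include_end=True)
                break
        suffix = "l" if side == "left" else "r"
        markers[f"heel_{suffix}"] = {"ml": heel_ml.y, "ap": heel_ap.y}
        markers[f"toe_{suffix}"] = {"ml": heel_ml.y.copy(), "ap": toe_ap.y}

    # --- CoM / hips ---------------------------------------------------------
    com_m = np.interp(t_m, strike_times, com_nodes)
    markers["hip_l"] = {"ml": com_m + sp.hip_halfwidth,
                        "ap": np.full_like(t_m, -0.15)}
    markers["hip_r"] = {"ml": com_m - sp.hip_halfwidth,
                        "ap": np.full_like(t_m, -0.15)}

    # --- CoP ----------------------------------------------------------------
    com_c = np.interp(t_c, strike_times, com_nodes)
    rel = _PiecewiseBuilder(t_c)
    sigma_stance = np.where(lead_side == "left", 1.0, -1.0)
    rel.linear(0.0, t_strike[0], 0.0, 0.0)
    prev_val = 0.0
    for k in range(n):
        # double stance: CoP transfers linearly toward the new stance foot
        val = sigma_stance[k] * disp[k]
        rel.linear(t_strike[k], po_t[k], prev_val, (val - prev_val) / (po_t[k] - t_strike[k]))
        end = t_strike[k + 1] if k + 1 < n else t_end_strike
        rel.linear(po_t[k], end, val, 0.0)
        prev_val = val
    rel.linear(t_end_strike, total_s, prev_val, 0.0, include_end=True)
    cop_total = com_c + rel.y

    load = {s: np.ones(len(t_c), dtype=bool) for s in ("left", "right")}
    for k in range(n):
        swing = _other_side(lead_side[k])
        end = t_strike[k + 1] if k + 1 < n else t_end_strike
        j0 = int(np.searchsorted(t_c, po_t[k] + 1e-9))
        j1 = int(np.searchsorted(t_c, end - 1e-9))
        load[swing][j0:j1] = False
    cop = {}
    for s in ("left", "right"):
        arr = cop_total.copy()
        if sp.cop_noise_sd > 0:
            arr = arr + rng.normal(0.0, sp.cop_noise_sd, size=len(arr))
        arr[~load[s]] = np.nan
        cop[s] = arr

    # --- noise and dropouts -------------------------------------------------
    marker_mask = {}
    for name, axes in markers.items():
        if sp.marker_noise_sd > 0:
            for axis in axes:
                axes[axis] = axes[axis] + rng.normal(0.0, sp.marker_noise_sd, size=len(t_m))
        marker_mask[name] = np.zeros(len(t_m), dtype=bool)
    for name, start_s, dur_s in sp.dropouts:
        i0 = int(np.searchsorted(t_m, start_s - 1e-9))
        i1 = int(np.searchsorted(t_m, start_s + dur_s - 1e-9))
        marker_mask[name][i0:i1] = True
        for axis in markers[name]:
            markers[name][axis][i0:i1] = np.nan

    truth_events = {
        "strike_times": strike_times,
        "strike_sides": strike_sides,
        "pushoff_times": po_by_side,
        "steps": steps,
    }

    return TrialRecording(
        subject=subject, group=group, condition=condition,
        belt_speed_left=cond.left_speed, belt_speed_right=cond.right_speed,
        fs_marker=sp.fs_marker, t_marker=t_m, markers=markers,
        marker_mask=marker_mask, fs_cop=sp.fs_cop, t_cop=t_c,
        cop_left_ml=cop["left"], cop_right_ml=cop["right"],
        load_left=load["left"], load_right=load["right"],
        truth_events=truth_events,
    )


def _other_side(side: str) -> str:
    return "right" if side == "left" else "left"


def save_trial(trial: TrialRecording, outdir) -> None:
    """Write one trial as plain-text CSV/YAML (markers, CoP, metadata)."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = trial.condition
    trial.to_frame().to_csv(outdir / f"{tag}_markers.csv", index=False)
    pd.DataFrame({
        "time_s": trial.t_cop,
        "cop_left_ml": trial.cop_left_ml,
        "cop_right_ml": trial.cop_right_ml,
        "load_left": trial.load_left.astype(int),
        "load_right": trial.load_right.astype(int),
    }).to_csv(outdir / f"{tag}_cop.csv", index=False)
    meta = {"subject": trial.subject, "group": trial.group,
            "condition": trial.condition, "fs_marker": float(trial.fs_marker),
            "fs_cop": float(trial.fs_cop),
            "belt_speed_left": float(trial.belt_speed_left),
            "belt_speed_right": float(trial.belt_speed_right)}
    (outdir / f"{tag}_meta.yaml").write_text(yaml.safe_dump(meta))


def load_trial(indir, condition: str) -> TrialRecording:
    """Read a trial written by :func:`save_trial` (bookkeeping not restored)."""
    import pathlib

    import yaml

    indir = pathlib.Path(indir)
    meta = yaml.safe_load((indir / f"{condition}_meta.yaml").read_text())
    mk = pd.read_csv(indir / f"{condition}_markers.csv")
    cp = pd.read_csv(indir / f"{condition}_cop.csv")
    markers, mask = {}, {}
    names = sorted({c.rsplit("_", 1)[0] for c in mk.columns if c != "time_s"})
    for name in names:
        markers[name] = {ax: mk[f"{name}_{ax}"].to_numpy() for ax in ("ml", "ap")}
        mask[name] = np.isnan(markers[name]["ml"]) | np.isnan(markers[name]["ap"])
    return TrialRecording(
        subject=meta["subject"], group=meta["group"], condition=condition,
        belt_speed_left=meta["belt_speed_left"], belt_speed_right=meta["belt_speed_right"],
        fs_marker=meta["fs_marker"], t_marker=mk["time_s"].to_numpy(),
        markers=markers, marker_mask=mask, fs_cop=meta["fs_cop"],
        t_cop=cp["time_s"].to_numpy(),
        cop_left_ml=cp["cop_left_ml"].to_numpy(),
        cop_right_ml=cp["cop_right_ml"].to_numpy(),
        load_left=cp["load_left"].to_numpy().astype(bool),
        load_right=cp["load_right"].to_numpy().astype(bool),
        truth_events=None,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Group-level effect structure.

    ``com_asym`` / ``cop_disp_asym``: sustained split-condition asymmetry
    of the CoM-referenced parameters per group (m); younger adults shift
    the CoM toward the slow foot, older adults stay symmetric.
    ``subject_sd``: between-subject SD of the injected asymmetries;
    ``shared_frac``: fraction of the subject deviation shared between the
    two CoM-referenced channels (a subject-level random intercept).
    """

    com_asym: dict = field(default_factory=lambda: {"younger": 0.020, "older": 0.0})
    cop_disp_asym: dict = field(default_factory=lambda: {"younger": 0.008, "older": 0.0})
    subject_sd: dict = field(default_factory=lambda: {"com": 0.005, "cop_disp": 0.002})
    shared_frac: float = 0.5


def scale_noise_to_cv(laws: dict, cv: float) -> dict:
    """Return laws with step-to-step noise set to ``cv`` times the
    slow-baseline magnitude of each channel.

    Useful for calibration studies: after percent-change conversion the
    per-parameter responses then share a common relative variance, which
    is the homoscedasticity the pooled mixed model assumes.
    """
    out = {}
    for param, per_foot in laws.items():
        out[param] = {}
        for foot, law in per_foot.items():
            sd = cv * abs(law.base["baseline_slow"])
            out[param][foot] = replace(law, noise_sd=sd)
    return out


@dataclass
class CohortSubject:
    subject: str
    group: str
    truth: StepTruth
    recordings: dict = field(default_factory=dict)


def generate_cohort(n_young: int, n_old: int, group_params: GroupParams | None = None,
                    seed: int = 0, protocol: Protocol | None = None,
                    with_signals: bool = False,
                    signal_params: SignalParams | None = None,
                    law_builder=default_laws) -> list:
    """Generate a two-group cohort of synthetic subjects.

    Each subject gets its own adaptation laws: the group's CoM-referenced
    asymmetry plus subject random effects (partially shared across the
    two CoM channels), and the common step-length/timing adaptation
    structure.  With ``with_signals=True`` every condition is also
    rendered to a :class:`TrialRecording`.
    """
    if n_young < 0 or n_old < 0:
        raise ValueError("subject counts must be non-negative")
    gp = group_params or GroupParams()
    if not 0.0 <= gp.shared_frac <= 1.0:
        raise ValueError("shared_frac must lie in [0, 1]")
    proto = protocol or default_protocol()
    rng = np.random.default_rng(seed)
    subjects = []
    groups = ["younger"] * n_young + ["older"] * n_old
    for i, group in enumerate(groups):
        z = rng.normal()
        mix = (gp.shared_frac * z
               + math.sqrt(1.0 - gp.shared_frac**2) * rng.normal(size=2))
        com_asym = gp.com_asym[group] + gp.subject_sd["com"] * mix[0]
        disp_asym = gp.cop_disp_asym[group] + gp.subject_sd["cop_disp"] * mix[1]
        laws = law_builder(com_asym=com_asym, cop_disp_asym=disp_asym)
        truth_seed = int(rng.integers(0, 2**31 - 1))
        truth = generate_step_truth(proto, laws, seed=truth_seed)
        subj = CohortSubject(subject=f"{'Y' if group == 'younger' else 'O'}{i:03d}",
                             group=group, truth=truth)
        if with_signals:
            for cond in proto.names:
                subj.recordings[cond] = synthesize_trial(
                    truth, cond, signal_params,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    subject=subj.subject, group=group)
        subjects.append(subj)
    return subjects
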