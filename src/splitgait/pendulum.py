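"""Frontal-plane single-link inverted-pendulum walker.

The model captures medial-lateral (ML) balance during treadmill walking: the
body is a point mass atop a mass-less leg pivoting about the center of
pressure (CoP).  Linearized about upright, the ML center-of-mass (CoM)
position ``u`` obeys

    u''(t) = omega**2 * (u(t) - q(t)),        omega = sqrt(g / l),

where ``q(t)`` is the CoP.  Gravity always accelerates the CoM *away* from
the stance foot, producing the rhythmic lateral oscillation of gait.  Steps
are instantaneous: after a fixed step duration the leg switches to a new
contact point.  Foot placement follows an extrapolated-CoM rule: the new
foot lands a constant offset ``b`` beyond the extrapolated CoM

    p_new = u + v / omega + sigma * b,

with ``sigma = +1`` when stepping onto the left (fast-belt) foot and ``-1``
for the right (slow-belt) foot (ML axis positive toward the left belt).
Optionally the CoP migrates under the stance foot at a constant signed rate
``c`` (ankle-roll compensation), modeling an active lateral control mode.

Conventions
-----------
A *step of side s* is the pendulum phase that **ends with the placement of
foot s**, i.e. single stance on the contralateral foot.  Step durations are
named accordingly: in split-belt walking the fast step (terminated by the
fast-foot strike) lasts longer than the slow step, while the *stance* time
of the fast foot is the shorter one.  The placement offset ``b_s`` applies
at the placement of foot ``s``.

With ``c = 0`` the stride map is dead-beat: immediately after placing foot
``s`` the extrapolated CoM sits exactly ``-sigma_s * b_s`` from the new
foot, independent of history, so the walker reaches its limit cycle in a
single step and the steady-state step width has the closed form
``b_prev * exp(omega*T) + b_new``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PendulumConfig",
    "PendulumTrajectory",
    "TrajectorySummary",
    "DivergenceError",
    "OptimizationError",
    "analytic_step",
    "simulate",
    "trajectory_summary",
    "optimize_tied",
    "optimize_split_young",
    "optimize_split_old",
    "single_offset_residuals",
]

GRAVITY = 9.81  # m/s^2
DEFAULT_LENGTH = 1.0  # m, effective pendulum length

SIDES = ("fast", "slow")  # fast = left belt, slow = right belt
_SIGMA = {"fast": 1.0, "slow": -1.0}

#: |CoM| beyond which a simulation is declared divergent (treadmill half
#: width is ~0.5 m; 1 m is far outside any recoverable state).
DIVERGENCE_LIMIT = 1.0


class DivergenceError(RuntimeError):
    """Raised when the simulated CoM leaves the plausible workspace."""


class OptimizationError(RuntimeError):
    """Raised when a control-parameter optimization fails to meet its goal."""


@dataclass(frozen=True)
class PendulumConfig:
    """Constants and control parameters for one walker.

    Parameters
    ----------
    omega:
        Pendulum rate constant ``sqrt(g / l)`` in 1/s.
    durations:
        Step duration per side in s; ``durations["fast"]`` is the duration
        of the phase ending with the fast-foot placement.
    offsets:
        Foot-placement offset ``b`` per side in m, applied at that foot's
        placement.
    cop_rate:
        Signed CoP migration rate ``c`` in m/s, applied in the lab frame
        during every stance phase starting from the placement point.
    initial_state:
        CoM (position m, velocity m/s) at simulation start.
    initial_foot:
        ML position of the initial stance foot (m).
    first_stance_side:
        Side of the initial stance foot; the first placement is the other
        side.
    burn_in_strides:
        Strides discarded before summary statistics.
    """

    omega: float = math.sqrt(GRAVITY / DEFAULT_LENGTH)
    durations: dict = field(default_factory=lambda: {"fast": 0.68, "slow": 0.68})
    offsets: dict = field(default_factory=lambda: {"fast": 0.01, "slow": 0.01})
    cop_rate: float = 0.0
    initial_state: tuple = (0.0, 0.0)
    initial_foot: float = 0.0
    first_stance_side: str = "slow"
    burn_in_strides: int = 20

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        for s in SIDES:
            if self.durations[s] <= 0:
                raise ValueError(f"step duration for side {s!r} must be positive")
        if self.burn_in_strides < 0:
            raise ValueError("burn_in_strides must be >= 0")
        if self.first_stance_side not in SIDES:
            raise ValueError(f"unknown side {self.first_stance_side!r}")


@dataclass
class PendulumTrajectory:
    """Result of :func:`simulate`.

    Per-step arrays are indexed by placement: entry ``k`` describes the
    phase that ends with placement ``k``.
    """

    config: PendulumConfig
    placement_sides: list  # side of the foot placed at the end of each phase
    placements: np.ndarray  # ML position of each placement (m)
    step_widths: np.ndarray  # |p_k - p_{k-1}| (m)
    boundary_states: np.ndarray  # (n_steps + 1, 2) CoM state at phase edges
    stance_feet: np.ndarray  # stance-foot position during each phase (m)
    phase_durations: np.ndarray  # (n_steps,) s
    com_integrals: np.ndarray  # exact integral of u(t) over each phase (m*s)
    times: np.ndarray  # dense sample times (s)
    com: np.ndarray  # dense CoM trace (m)
    cop: np.ndarray  # dense CoP trace (m)

    @property
    def n_steps(self) -> int:
        return len(self.placements)


@dataclass(frozen=True)
class TrajectorySummary:
    mean_step_width: float  # m, over post-burn-in steps
    drift_per_stride: float  # m per two-step stride cycle
    com_midline_offset: float  # time-averaged CoM minus foot midline (m)


def _other(side: str) -> str:
    return "slow" if side == "fast" else "fast"


def analytic_step(u0, v0, omega, duration, cop_rate=0.0):
    """Closed-form single-stance solution of the linearized pendulum.

    The CoP starts at the origin and moves at ``cop_rate``; ``u0``/``v0``
    are the CoM position and velocity relative to the initial CoP.  In the
    moving frame ``w = u - cop_rate * t`` the dynamics are the pure
    hyperbolic flow ``w'' = omega**2 * w``, giving

        u(T) = c*T + u0*cosh(wT) + ((v0 - c)/w)*sinh(wT)
        v(T) =  c  + u0*w*sinh(wT) + (v0 - c)*cosh(wT)

    Returns ``(u(T), v(T))``.
    """
    wt = omega * duration
    ch, sh = math.cosh(wt), math.sinh(wt)
    dv = v0 - cop_rate
    u_t = cop_rate * duration + u0 * ch + dv / omega * sh
    v_t = cop_rate + u0 * omega * sh + dv * ch
    return u_t, v_t


def _phase_com_integral(w0, dv, omega, duration, p0, cop_rate):
    """Exact integral of u(t) over one stance phase.

    u(t) = p0 + c*t + w0*cosh(w t) + (dv/w)*sinh(w t) with w0 = u0 - p0,
    dv = v0 - c.
    """
    wt = omega * duration
    return (
        p0 * duration
        + 0.5 * cop_rate * duration**2
        + w0 / omega * math.sinh(wt)
        + dv / omega**2 * (math.cosh(wt) - 1.0)
    )


def simulate(config: PendulumConfig, n_steps: int, dense_dt: float = 0.005) -> PendulumTrajectory:
    """Simulate ``n_steps`` consecutive foot placements.

    Each phase integrates the closed-form stance solution from the current
    state, then places the swing foot at the extrapolated CoM plus the
    side's offset.  Raises :class:`DivergenceError` if the CoM magnitude
    exceeds ``DIVERGENCE_LIMIT``.
    """
    if n_steps < 2 * config.burn_in_strides + 2:
        raise ValueError("n_steps must cover burn-in plus at least one stride")
    omega, c = config.omega, config.cop_rate
    u, v = config.initial_state
    p = config.initial_foot
    stance = config.first_stance_side

    sides, placements, widths = [], [], []
    boundary = [(u, v)]
    stance_feet = np.empty(n_steps)
    phase_T = np.empty(n_steps)
    com_int = np.empty(n_steps)
    t_dense, com_dense, cop_dense = [], [], []
    t0 = 0.0

    for k in range(n_steps):
        new_side = _other(stance)
        T = config.durations[new_side]
        w0, dv = u - p, v - c
        # dense sampling of this phase (closed form, for plotting/inspection)
        ts = np.arange(0.0, T, dense_dt)
        wt = omega * ts
        t_dense.append(t0 + ts)
        com_dense.append(p + c * ts + w0 * np.cosh(wt) + dv / omega * np.sinh(wt))
        cop_dense.append(p + c * ts)

        com_int[k] = _phase_com_integral(w0, dv, omega, T, p, c)
        stance_feet[k] = p
        phase_T[k] = T

        du, dvv = analytic_step(u - p, v, omega, T, cop_rate=c)
        u, v = p + du, dvv
        if abs(u) > DIVERGENCE_LIMIT:
            raise DivergenceError(
                f"CoM diverged (|u|={abs(u):.3f} m) at step {k} with "
                f"offsets={config.offsets}, cop_rate={c}, durations={config.durations}"
            )
        p_new = u + v / omega + _SIGMA[new_side] * config.offsets[new_side]
        widths.append(abs(p_new - p))
        placements.append(p_new)
        sides.append(new_side)
        p = p_new
        stance = new_side
        boundary.append((u, v))
        t0 += T

    return PendulumTrajectory(
        config=config,
        placement_sides=sides,
        placements=np.asarray(placements),
        step_widths=np.asarray(widths),
        boundary_states=np.asarray(boundary),
        stance_feet=stance_feet,
        phase_durations=phase_T,
        com_integrals=com_int,
        times=np.concatenate(t_dense),
        com=np.concatenate(com_dense),
        cop=np.concatenate(cop_dense),
    )


def trajectory_summary(traj: PendulumTrajectory) -> TrajectorySummary:
    """Summary statistics over post-burn-in strides.

    Drift is the mean CoM displacement per two-step stride cycle, measured
    at phase boundaries; the midline is the midpoint between the mean left
    and mean right foot placements.
    """
    start = 2 * traj.config.burn_in_strides
    if traj.n_steps - start < 4:
        raise ValueError("need at least 2 post-burn-in strides")
    # trim to a whole number of strides
    n_post = (traj.n_steps - start) // 2 * 2
    sl = slice(start, start + n_post)

    widths = traj.step_widths[sl]
    u_bounds = traj.boundary_states[start : start + n_post + 1 : 2, 0]
    drift = float(np.mean(np.diff(u_bounds)))

    com_mean = float(np.sum(traj.com_integrals[sl]) / np.sum(traj.phase_durations[sl]))
    p = traj.placements[sl]
    sides = np.asarray(traj.placement_sides[sl])
    midline = 0.5 * (p[sides == "fast"].mean() + p[sides == "slow"].mean())
    return TrajectorySummary(
        mean_step_width=float(widths.mean()),
        drift_per_stride=drift,
        com_midline_offset=com_mean - float(midline),
    )


# ---------------------------------------------------------------------------
# Constrained optimization of control parameters
# ---------------------------------------------------------------------------

_N_MEASURE_STRIDES = 20
_SW_TOL = 1e-4  # m, convergence requirement on mean step width
_DRIFT_TOL = 1e-5  # m/stride, zero-drift constraint


def _run_summary(config: PendulumConfig) -> TrajectorySummary:
    n = 2 * (config.burn_in_strides + _N_MEASURE_STRIDES)
    traj = simulate(config, n)
    return trajectory_summary(traj)


def _safe_residuals(config, sw_target, with_drift):
    try:
        s = _run_summary(config)
    except DivergenceError:
        return [10.0, 10.0] if with_drift else [10.0]
    res = [s.mean_step_width - sw_target]
    if with_drift:
        res.append(s.drift_per_stride)
    return res


def optimize_tied(T, sw_target, config: PendulumConfig | None = None):
    """Find the placement offset ``b`` giving a target step width at tied belts.

    Both sides share duration ``T`` and offset ``b``; by symmetry the gait
    is periodic with zero drift, so only the step-width goal is optimized.
    Deterministic gradient-based solve from the fixed initial guess
    b = 0.01 m.  Returns ``b``; raises :class:`OptimizationError` if the
    converged residual exceeds 1e-4 m.
    """
    if sw_target < 0:
        raise ValueError("sw_target must be >= 0")
    base = config or PendulumConfig()
    base = replace(base, durations={"fast": T, "slow": T}, cop_rate=0.0)

    def residual(x):
        cfg = replace(base, offsets={"fast": x[0], "slow": x[0]})
        return _safe_residuals(cfg, sw_target, with_drift=False)

    sol = least_squares(residual, x0=[0.01], bounds=([0.0], [0.2]), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    b = float(sol.x[0])
    resid = abs(residual([b])[0])
    if resid > _SW_TOL:
        raise OptimizationError(f"tied optimization residual {resid:.2e} m exceeds {_SW_TOL} m")
    return b


def optimize_split_young(T_fast, T_slow, sw_target, config: PendulumConfig | None = None):
    """Split-belt solution with per-leg placement offsets (the 'young' strategy).

    ``T_fast``/``T_slow`` are the durations of the fast and slow steps
    (phases ending at the fast- and slow-foot placements).  Solves for
    ``(b_fast, b_slow)`` such that the mean step width matches
    ``sw_target`` and the net lateral drift per stride vanishes: the
    walker stays centered on the treadmill purely through asymmetric foot
    placement, at the cost of a CoM shift relative to the foot midline.
    """
    base = config or PendulumConfig()
    base = replace(base, durations={"fast": T_fast, "slow": T_slow}, cop_rate=0.0)

    def residual(x):
        cfg = replace(base, offsets={"fast": x[0], "slow": x[1]})
        return _safe_residuals(cfg, sw_target, with_drift=True)

    sol = least_squares(
        residual, x0=[0.01, 0.01], bounds=([0.0, 0.0], [0.2, 0.2]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    b_fast, b_slow = (float(v) for v in sol.x)
    r = residual([b_fast, b_slow])
    if abs(r[0]) > _SW_TOL or abs(r[1]) > _DRIFT_TOL:
        raise OptimizationError(f"split-young optimization infeasible; residuals {r}")
    return b_fast, b_slow


def optimize_split_old(T_fast, T_slow, sw_target, config: PendulumConfig | None = None,
                       fix_cop_rate: float | None = None):
    """Split-belt solution with one shared offset plus CoP-shift rate ('old').

    Solves for ``(b, c)`` such that mean step width matches ``sw_target``
    and net drift per stride vanishes: foot placement stays symmetric
    relative to the extrapolated CoM and the asymmetric gravitational
    impulse is compensated by actively rolling the CoP at rate ``c``
    during stance.  With ``fix_cop_rate=0.0`` the compensation channel is
    frozen and the problem is infeasible for unequal durations
    (:class:`OptimizationError`).
    """
    base = config or PendulumConfig()
    base = replace(base, durations={"fast": T_fast, "slow": T_slow})

    if fix_cop_rate is not None:
        def residual(x):
            cfg = replace(base, offsets={"fast": x[0], "slow": x[0]}, cop_rate=fix_cop_rate)
            return _safe_residuals(cfg, sw_target, with_drift=True)

        sol = least_squares(residual, x0=[0.01], bounds=([0.0], [0.2]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        r = residual([float(sol.x[0])])
        if abs(r[0]) > _SW_TOL or abs(r[1]) > _DRIFT_TOL:
            raise OptimizationError(
                f"single-offset optimization with frozen CoP rate infeasible; residuals {r}"
            )
        return float(sol.x[0]), fix_cop_rate

    def residual(x):
        cfg = replace(base, offsets={"fast": x[0], "slow": x[0]}, cop_rate=x[1])
        return _safe_residuals(cfg, sw_target, with_drift=True)

    sol = least_squares(
        residual, x0=[0.01, 0.0], bounds=([0.0, -0.5], [0.2, 0.5]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    b, c = (float(v) for v in sol.x)
    r = residual([b, c])
    if abs(r[0]) > _SW_TOL or abs(r[1]) > _DRIFT_TOL:
        raise OptimizationError(f"split-old optimization infeasible; residuals {r}")
    return b, c


def single_offset_residuals(T_fast, T_slow, sw_target, b_grid,
                            config: PendulumConfig | None = None):
    """Constraint residual of the single-offset, no-CoP-shift strategy.

    For each ``b`` in ``b_grid`` (shared by both sides, ``c = 0``), returns
    the Euclidean norm of (mean step width - target, drift per stride).
    A residual bounded away from zero across the grid demonstrates that
    symmetric foot placement alone cannot both hit the step-width goal and
    keep the walker centered when step durations differ.
    """
    base = config or PendulumConfig()
    base = replace(base, durations={"fast": T_fast, "slow": T_slow}, cop_rate=0.0)
    out = np.empty(len(b_grid))
    for i, b in enumerate(b_grid):
        cfg = replace(base, offsets={"fast": float(b), "slow": float(b)})
        r = _safe_residuals(cfg, sw_target, with_drift=True)
        out[i] = math.hypot(*r)
    return out
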