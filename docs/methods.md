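# Methods

## Coordinate and naming conventions

ML = x, positive toward the left belt; AP = y, positive forward; origin
at the treadmill center. The left foot rides the 1.4 m/s belt during the
split condition and is called *fast*; the right foot (0.7 m/s) is
*slow*, and the labels are kept in every condition. A step record is
keyed by the leading foot's heel strike at `t_k` and covers the interval
to the next strike: step length/width and the CoM-referenced positions
are evaluated at `t_k` (where the stance foot is the trailing foot),
while stance times and ∫CoP−CoM belong to single stance on the leading
foot inside `[t_k, t_{k+1})`. CoM-referenced quantities are reported
with **positive = toward the stance foot**: `reported = lab × (+1 if the
stance foot is left else −1)`. The sign map is an involution, so
round-trips through it are exact.

## Preprocessing

Markers are filtered with a 4th-order Butterworth low-pass at 10 Hz
applied forward–backward (`filtfilt`), giving zero phase and the
*squared* magnitude response of the designed filter; tests therefore
check attenuation against `|H(f)|²` of the digital design (at 30 Hz on a
120 Hz grid the bilinear-transform warping makes the digital response
~6× stronger than the analog formula). Occlusion gaps up to 100 ms
(inclusive) are filled by a cubic spline through up to four observed
samples on each side; longer or boundary gaps become exclusion
intervals, and any step overlapping one is dropped. Baseline statistics
(per parameter per foot) come from the first slow-baseline trial only;
the Δ reference magnitude for percent-change conversion is the absolute
pooled baseline mean, falling back to the mean absolute value when that
mean is below 1e−3 in natural units (the percent scale is undefined at a
zero reference — this matters for the CoM-referenced parameters, whose
baselines are near zero; see Limitations).

## Event detection

Heel strikes and push-offs are AP-marker extrema. Peak acceptance
requires 0.4 s minimum separation (the shortest plausible step at these
speeds is ~0.5 s) and 1 cm prominence; flat maxima resolve to the first
plateau sample. Sequence validation replaces manual inspection:
consecutive same-foot strikes invalidate the two steps using the
duplicate event, each step must contain exactly one swing-foot push-off,
and ∫CoP−CoM requires the stance belt to be loaded throughout single
stance.

## Adaptation metrics

Symmetry pairs each valid fast-led step with the following valid
slow-led step, one value per stride. *Steps to plateau* uses the mean P
and sample SD S (ddof = 1) of the last 50 symmetry values; the reported
step (1-based) is the first whose 9-step window stays within 2S of P.
When S = 0 the band is widened to 1e−12 so exact-equality points count
as inside; when no window qualifies, the series length is returned with
`converged=False` rather than raising (some parameters settle only at
the trial end). Plateau magnitude defaults to the detection-window mean;
the instantaneous value and P itself are available as alternative modes.
The aftereffect is the mean of the first 10 after-condition symmetry
values. Note that for *noise-free* exponential series the plateau band
itself decays with the time constant, so the detection index saturates
near the series end; the intuitive "slower adaptation ⇒ later plateau"
monotonicity holds once a stationary noise floor pins the band, and that
is the regime the property test uses.

## Mixed-effects group comparison

Each response (steps to plateau, plateau magnitude, aftereffect, in %Δ)
is modeled as `response ~ group · gait_parameter + (1|subject)`, REML
via statsmodels `MixedLM` with sum-to-zero coding (so coefficient blocks
give type-III tests), followed by a direct Nelder–Mead polish of the
closed-form random-intercept REML profile, which also rescues optimizer
failures. Kenward–Roger denominator dfs are approximated by
Satterthwaite throughout: for a contrast `l`,
`df = 2 g² / (∇g' A ∇g)` with `g(θ) = l'C(θ)l` differenced numerically
and `A` the inverse observed information of the REML likelihood;
multi-row contrasts combine per-direction dfs by the Fai–Cornelius
eigen-decomposition rule (as in lmerTest). For this balanced
one-intercept design the two approximations are near-identical, and the
computed dfs reproduce the classical split-plot values (N−2 for group,
(N−2)(p−1) for the within-subject effects). Degenerate fits are handled
explicitly: zero subject variance reduces inference to OLS residual
df, and (near-)zero residual variance switches to exact OLS (estimates
are the cell means, intervals collapse). Posthoc least-squares means
carry Satterthwaite-df 95 % CIs; group differences are flagged when the
two intervals do not overlap.

## Pendulum model

The frontal-plane model is a linearized single-link inverted pendulum
with a mass-less leg: `ü = ω²(u − q(t))`, ω = √(g/ℓ) with defaults
g = 9.81 m/s², ℓ = 1.0 m (both configurable; the recovered control
parameters scale with ω, so only their orderings and the achieved step
widths are meaningful across choices of ℓ). Steps are instantaneous
transfers after a fixed duration; a *step of side s* is the phase ending
with the placement of foot s, so the reported split durations
(fast step 0.61 s, slow step 0.51 s) put the *shorter* stance on the
fast foot, consistent with the experimental observation that the fast
foot spends less time in stance. Placement follows the extrapolated-CoM
rule `p = u + v/ω + σ·b` (σ = +1 stepping onto the left/fast side). The
optional CoP shift moves the CoP at a constant signed lab-frame rate `c`
from the placement point during every stance.

With `c = 0` the stride map is dead-beat — after one placement the
extrapolated CoM sits exactly `−σb` from the new foot — giving closed
forms used as independent test oracles: tied step width
`b(1 + e^{ωT})`, and the zero-drift condition
`b_fast(e^{ωT_fast} − 1) = b_slow(e^{ωT_slow} − 1)`, which forces
`b_fast > b_slow` for the longer fast step. Optimizations use
deterministic least-squares (trust-region, fixed initial guesses
b = 0.01 m, c = 0) on residuals (mean step width − goal, drift/stride)
measured from simulation with 20 burn-in + 20 measured strides;
convergence demands |width error| ≤ 1e−4 m and |drift| ≤ 1e−5 m/stride.
The single-offset/no-shift variant is infeasible for unequal durations
(drift ∝ b(e^{ωT_f} − e^{ωT_s})); the feasibility probe reports the norm
of both residuals over a grid of b, which stays above 1e−3.

## Synthetic-data generator

The generator emulates the analysis protocol (2-min tied baselines at
0.7 and 1.4 m/s, 10-min split, 5-min after — the after duration is a
package default, configurable) with belt acceleration metadata of
0.5 m/s². Six channels are programmed directly per foot — step length,
step width, single and double stance time, CoM position, and the stance
CoP−CoM displacement — each following `y_k = plateau + (start −
plateau)e^{−k/τ} + ε` during split and an opposite-sign decay during
after. Derived quantities follow kinematic identities rather than
independent programs: step duration = single + double stance time
(snapped to the 120 Hz grid so truth and signals agree exactly),
∫CoP−CoM = displacement × realized single-stance time, and Step−CoM =
placement − CoM. Foot placements alternate symmetrically about the
treadmill center at half the drawn step width, which keeps the walker
centered (chaining noisy widths would random-walk the feet away from a
stationary CoM — a geometry real treadmill walking forbids).

Signals: heel AP moves backward with the belt during stance and swings
forward along a cubic arc; around every programmed extremum the
trajectory follows a C¹ parabolic cap (half-width 50 ms) whose endpoint
slopes equal the belt speed, emulating finite foot deceleration at
contact. The cap keeps the extremum exactly at the programmed sample —
symmetric, so zero-phase filtering does not move it — and bounds the
value bias that filtering a sharp corner would otherwise introduce
(~1 cm at 1.4 m/s without smoothing, <0.1 mm of the effect sizes with
it). The hip midpoint is piecewise linear through the programmed CoM
values; the stance-belt CoP equals that CoM plus the programmed
displacement, constant over single stance and transferred linearly
during double support; the unloaded belt reads NaN. Marker noise
defaults to 1 mm RMS i.i.d. per sample. Cohorts draw per-subject
asymmetries for the CoM-referenced channels (group mean 0.020 m CoM /
0.008 m displacement for younger, 0 for older; subject SD 0.005/0.002 m,
partially shared between the two channels), so the young-only effect is
4× the between-subject SD; all other channels are identical across
groups. Adaptation time constants (10–40 steps depending on channel) are
package defaults, not empirical claims.

What the generator does **not** emulate: soft-tissue artifact and
autocorrelated marker noise, belt-speed fluctuations, handrail use,
double-support force sharing (per-belt CoP during double stance is not
used by the pipeline), foot rotation, and any pelvis-marker/CoM
discrepancy. Passing recovery tests therefore demonstrate correctness of
the pipeline's computations, not robustness to every artifact of real
capture.

## Simulation scales

Default test runs use desk-scale protocols (30–120 s conditions, 59+
strides of split so the last-50 + 9-step plateau rule applies per
stride), cohorts of 1–4 subjects with rendered signals, n = 31/21
truth-level cohorts for posthoc recovery, and 1000-replicate null
simulations at n = 6 + 6 for calibration; the pendulum uses 20 burn-in +
20 measured strides everywhere.

## Limitations

- **Calibration of the pooled F-test on derived outcomes.** The
  group×parameter interaction test assumes homoscedastic, independent
  residuals across the seven parameter levels. Percent-change conversion
  already violates this grossly (near-zero CoM-referenced baselines
  inflate their % variance by orders of magnitude), and even with noise
  proportional to each channel's baseline the kinematic identities do:
  ∫CoP−CoM is a product of two noisy channels (double relative variance,
  correlated with the stance-time response), and step-width symmetry
  partially telescopes because adjacent widths share a foot placement
  (~1/20 the variance). Measured type-I error of the full-chain
  interaction test on null cohorts is ~0.077 (equal-relative-noise null)
  to ~0.16 (default-noise null) at nominal 0.05; the corresponding
  acceptance test is left failing by design, with the table-level
  calibration of the statistical machinery itself (i.i.d. responses)
  verified separately at nominal level. Group-level conclusions from
  CI non-overlap on strongly separated parameters are unaffected in the
  recovery simulations, but borderline interaction p-values on real
  derived gait outcomes should be treated as anticonservative.
- The pendulum's ℓ (hence ω) is a convention; recovered b and c values
  are reported relative to it.
- steps-to-plateau on percent scales inherits the near-zero-reference
  instability; the raw-step mode is the default for that response.
- The event detector's hyperparameters (0.4 s separation, 1 cm
  prominence) are engineering defaults standing in for the manual
  inspection used in practice.
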