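# Methods

This note documents the models, parameter choices and numerical
decisions behind `pursuitkit`, in the spirit of a statistical software
methods appendix.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Stimulus generation

### Path shapes

Every path is defined by its tangential angle θ as a function of arc
length and realized as the cumulative sum of unit steps
(cos θᵢ, sin θᵢ), in screen coordinates (pixels, origin top-left, y
down; a positive angle turns downward).  Curvature is estimated as the
absolute angle increment per arc step, κᵢ = |Δθᵢ|/Δs.

* **Lines** use constant θ: 0° (horizontal), ±45° (tilted).
* **Zigzags** map a triangle wave with `periods` cycles through the
  normalized tunable sigmoid f(x, k) = (x − kx)/(k − 2k|x| + 1),
  k ∈ (−1, 1), scaled to `amplitude_deg`.  The sigmoid's k controls
  corner sharpness: k = 0 gives straight sweeps with linear blends,
  k → 1 approaches instant direction flips.  Defaults: 4 periods,
  60° amplitude, k = 0.7.
* **Spirals** wind with θ ∝ √(arc length), the tangent-angle growth of
  an Archimedean spiral traversed outward.  An `inner_frac` of 0.02
  starts slightly off-center so the innermost curvature is finite.
  Default: 3 turns.

The shipped battery fixes each trajectory's **extent** (total arc
length) so that extent / speed reproduces the intended durations —
lines 427 px at 100 px/s (4.27 s); zigzags 1050 / 1046.25 / 894 px at
100 / 225 / 300 px/s (10.50 / 4.65 / 2.98 s); spirals 2246 / 2355.75 /
2025 px (22.46 / 10.47 / 6.75 s).  The zigzag tiers (and spiral tiers)
share one shape rescaled to slightly different arc lengths; their
implied extents differ across speed tiers, so a per-tier extent, not a
shared one, is the honest parameterization.

### Motion profiles

* **Minimum jerk** (horizontal line): the rest-to-rest quintic
  s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, the unique polynomial minimizing
  integrated squared jerk with zero endpoint velocity and
  acceleration.  Peak/mean speed = 1.875 analytically.
* **Constant speed** (tilted lines).
* **Speed–curvature power law** (zigzags, spirals): v(s) = g κ(s)^(−β)
  with β = 1/3 by default (the classical two-thirds power law); the
  gain g is chosen in closed form so the realized mean speed equals
  the nominal average speed, hence duration = arc length / speed
  exactly.  Curvature below 10⁻⁶ px⁻¹ is clamped to that floor, so an
  (almost) straight path degrades to constant speed rather than
  unbounded velocity; a fully straight path logs the fallback.

Frames are placed at tᵢ = i/60 s, i = 0 … round(60 T) − 1, and target
positions are linear interpolations along the 1-px-step polyline; the
arc-length shortfall of the last frame is below one frame
displacement.

### Pixel pitch

All px ↔ mm conversions use 155 mm / 800 px = 0.19375 mm/px.  The
cm/s speed column sometimes quoted for such batteries (100 px/s =
"0.20 cm/s") is dimensionally inconsistent with this pitch (100 px/s =
1.94 cm/s); px/s values are treated as authoritative throughout.

## Acquisition protocol

The reset rule emulates the game directive: a reset fires when the
touch–target distance exceeds 9 mm continuously for 1.7 s (102 frames
at 60 Hz); the dwell clock restarts after a reset and clears whenever
the distance re-enters the threshold.  Two underspecified points are
settled as configurable defaults: an inactive-touch frame counts as
"too far" (the finger is off the screen), and distances are measured
on unfiltered positions, because the rule ran in real time on the
device whereas the 8 Hz filter is an offline analysis step.  Resets
are recorded as events; traces are never truncated.

Timestamps with device jitter (SD ≈ 1.7 ms is typical for this class
of hardware) are regularized to a uniform 60 Hz clock without
resampling positions; original timestamps are retained.

## Offset metrics

Touch x and y are filtered independently with a zero-phase
(forward–backward) Butterworth low-pass, 8 Hz cut-off, 4th order,
applied per contiguous active segment; segments too short to pad are
passed through raw and flagged.  No outlier removal is performed —
slips and jerky corrections are signal, not artifact.  Touch movement
direction comes from central differences of the filtered positions;
frames slower than 2 mm/s are flagged invalid (the direction of a
near-stationary finger is sensor noise).  Target direction is the
analytic path tangent interpolated at the frame's arc position, never
a finite difference of rendered frames.

The per-trajectory aggregate is the arithmetic mean over valid frames
(median available for sensitivity analyses); directional offsets are
unsigned in [0, 180]°.  Inactive frames are excluded, not
interpolated.  A trajectory with zero valid frames yields a missing
summary that propagates as missing data into the cohort table.

## The synthetic cohort generator

The pursuit model is a first-order lagged tracker:

    touch[i] = touch[i−1] + gain · (target(t − lag) − touch[i−1]) + η[i]

plus an optional tremor sinusoid and brief touch drops.  The process
noise η is **signal-dependent**: its SD is `noise_sd_mm` at a 100 px/s
reference target speed and scales proportionally with local target
speed (clipped to 0.25–4×), the standard property of motor output
noise.  This matters for construct separation: with purely isotropic
noise the direction error would shrink as 1/speed and the
participant's directional-skill trait would vanish on the fast
trajectories; with signal-dependent noise, directional error is a
speed-invariant trait while spatial error still scales with
speed × lag.  The model is a fixture generator with the right
covariance structure, not a claim about child motor control.

Cohort defaults mirror a small clinical repeated-measures design: 12
participants, ages uniform on 5–16 y, 4 sessions each advancing by
0.25 y.  Age acts through two maps (value = a₀ + a₁·age + a₂·age²,
clipped):

* lag_s = 0.70 − 0.050·age + 0.0015·age² (≈ 0.49 s at age 5, 0.28 s at
  16) — the dominant age effect, expressed mainly in the *spatial*
  offset;
* noise_sd_mm = 1.7 − 0.07·age (≈ 1.35 → 0.58 mm) — a milder age
  effect on the *directional* channel.

Participant-level random intercepts: SD 0.04 s on lag, 0.40 mm on
noise (individual skill heterogeneity beyond age — without it the
directional offsets carry too little between-participant variance to
identify the score model in a 12-participant design), and SD 1.5
points on the score.  The external score is generated from the
*realized* mean directional offsets of the two slow complex
trajectories:

    score = 34 − 0.25·dir_spiralA − 0.12·dir_zigzagA + u + ε,  ε ~ N(0, 1)

calibrated once so scores land on a plausible discrete-test points
range (roughly 5–27).  Gain is fixed at 0.18, tremor at 0.3 mm / 5 Hz,
touch-drop probability 0.002/frame.  A skip hook can mark the fastest
trajectories as not attempted, mirroring incomplete sessions.

What the generator does **not** emulate: saccade-locked catch-up
movements, direction-specific biases, fatigue or learning across
sessions, non-Gaussian score noise, floor/ceiling effects of a
discrete score.  Passing recovery tests therefore shows that the
analysis layer is correct and well-calibrated for data with this
covariance structure — not that real children behave like the model.

## Statistical layer

The random-intercept LMM is fitted by profiling: for a variance ratio
λ = σ²ᵤ/σ²ₑ each group block of V is σ²ₑ(I + λJ) with closed-form
inverse and determinant, so GLS and the (RE)ML criterion cost O(n) per
candidate λ, and a bounded 1-D optimization (with an explicit λ = 0
boundary check) completes the fit.  This specialized solver exists
because the pipeline needs Satterthwaite denominator degrees of
freedom and thousands of refits in bootstrap/recovery loops; its
estimates are cross-checked in the test suite against statsmodels
MixedLM (agreement to ≤ 10⁻⁴) and, for the Satterthwaite df, against
R's lme4/lmerTest (agreement to ≤ 0.2 df) and the classical balanced
one-way design where the df are exactly g − 2.

Satterthwaite df for a contrast L: ν = 2(LCL′)²/Var(LCL′), with C the
fixed-effects covariance, the gradient of LCL′ taken analytically in
(σ²ᵤ, σ²ₑ), and the variance-component covariance from the inverse
expected REML information ½tr(P ∂V P ∂V).

Conventions: ML is used whenever models with different fixed effects
are compared (part R²); REML for final variance-component reports;
every report prints its estimation method and df method.  Marginal /
conditional R² use the variance of the fixed-effect predictions over
the observed design.  Part R² of a focal set is the drop in marginal
(resp. conditional) R² when the focal predictors are removed with
controls retained; CIs by seeded parametric bootstrap (default 1000
draws; analyses here run with fewer or none, stated per output).  Age
and age² enter centered to tame collinearity; part R² is invariant to
this (tested).  No multiple-testing correction is applied across the
per-trajectory scans; p-values are reported raw.  Missing summaries
are handled by listwise deletion per model.  Effect sizes follow
d = 2r/√(1 − r²) computed from unrounded r; where r derives from a
mixed model it is √R²ₘ.

A note on exact replication: duplicating every observation is *not* a
no-op for a mixed model (GLS weights depend on group size), so the
toolkit does not promise that invariance; the test suite asserts the
weaker property (small perturbation, identical to statsmodels'
behavior).

## Validation studies and problem sizes

`validation.coverage_study` simulates fresh default-design cohorts
(only the two score trajectories, for speed), refits the score LMM and
records whether the Satterthwaite-t 95% CI covers each true weight;
the package runs 200 replicates in the test suite and acceptance
script.  `validation.dominance_study` simulates full nine-trajectory
cohorts and records, per replicate, on how many trajectories the
directional offset beats the spatial in score part R² and the spatial
beats the directional in age R²; 100 replicates in the test suite, 60
in the acceptance script — sizes chosen to make the medians stable
while keeping a full run in the low minutes on a single core.

## Known limitations

* The battery's shape parameters (sigmoid tuning, period counts, turn
  counts) are this package's own design; only extents, speeds and the
  derived durations are pinned to the published battery timing.
* The Satterthwaite machinery covers the random-intercept model only;
  random slopes are out of scope.
* Bootstrap CIs for part R² are percentile CIs without bias
  correction.
* The CLI's plotting is a minimal predicted-vs-actual / residual pair,
  intended for smoke checks rather than publication figures.
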