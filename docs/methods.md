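# Methods

This note documents the models, algorithms, and design choices behind the
package, in the spirit of a statistical software vignette. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate frame and data model

All positions are in mm in a right-handed frame with X lateral (leftward
negative), Y vertical (up positive), and Z pointing from the start position
toward the target; time is in seconds at a nominal 70 Hz. The unit of
analysis is a (trial, parameter) observation in a long table; a trial
contributes up to ten observations.

## Signal processing

**Filtering.** Positions are low-pass filtered with a 2nd-order Butterworth
at 10 Hz applied forward and backward (`filtfilt`, reflective padding):
effective 4th-order attenuation with zero phase, so detected event times are
not lagged. The dual pass squares the single-pass magnitude response; DC is
preserved exactly. Tests verify the realized discrete-filter gain against
the analytic frequency response at 2 and 20 Hz.

**Differentiation.** Tangential speed is the Euclidean norm of the
central-difference derivative of filtered position (one-sided at the ends);
"deceleration" is the signed derivative of that speed. Only position is
filtered; speed is differentiated from the filtered signal rather than
re-filtered, because a second smoothing pass would bias peak speed downward
at 70 Hz.

**Event detection.** Onset is the first sample whose speed strictly exceeds
5 mm/s and remains above it for at least ceil(0.5 s × fs) consecutive
samples (35 at 70 Hz). The kick is the first sustained (3-sample) crossing
of the same threshold by the ball-marker speed; without a usable ball trace
the fallback is the sample of minimum finger–target distance, and failing
that the speed peak. Offset is the first sample at or after the kick where
finger speed drops below 5 mm/s; if that never happens the last sample is
used with a logged warning. Note that zero-phase filtering spreads the
ball's abrupt motion onset backward by a few samples, so detected kick times
run slightly early; onset/offset, which gate every parameter, are unaffected
because the fingertip speed is smooth there.

**Parameters.** MH is the maximum filtered Y within [onset, offset]; MV the
maximum speed; MDec the absolute minimum of the speed derivative *after* the
speed peak (deceleration phase only); MT the onset-to-offset duration in ms.
Lateral deviation is computed in the horizontal (X–Z) plane as the signed
perpendicular distance from the line through start and target, negative
leftward, so the vertical arc cannot contaminate it; MDevLeft/MDevRight are
the signed extrema (a side never visited scores 0, with the index of the
sample closest to that side). Event times are normalized as
(index − onset)/(offset − onset).

**Start and target.** The start position is the mean filtered fingertip
position over the pre-onset rest; the default target is the ball's rest
position averaged over the same interval and projected to the start height.
Because the ball sits only ~10 mm from the start, a line fitted through two
nearby noisy points is angularly unstable; when the apparatus geometry is
known (as in any calibrated motion-capture session, and always in
simulation) the goal position should be supplied via
`KinematicsOptions.target_mm`, which the pipeline does by default
(0, 0, 500 mm).

## Scoring and cleaning

MPI = ET + ACA + SCA with each sub-score in 0–20. ET is by definition
already reverse-coded (20 s minus the enumeration time), so no further
reversal is applied; the published participant table is consistent with this
plain sum on every row, which the acceptance tests reproduce exactly.

z-score cleaning standardizes each parameter against its pooled whole-sample
mean and SD (ddof = 1) and marks single (trial, parameter) observations with
|z| > 3 as excluded, leaving the trial's other parameters in the analysis —
the choice that retains the most data and matches per-parameter modelling.
Zero-variance parameters are skipped with a warning. The cleaning report
gives the exclusion rate under both defensible denominators: per observation
and per trial (trials with at least one exclusion).

## Mixed models

For response y of participant i on trial j:

    y_ij ~ family(η_ij, φ),   η_ij = x_ij'β + u_i,   u_i ~ N(0, σ_u²)

with treatment-coded fixed effects for Group (reference: preschool),
Stimulus (reference: the 2-dot condition) and their interaction, so the
Group coefficient is the school-minus-preschool difference at the reference
stimulus on the link scale.

Families: gaussian (identity link, residual SD), Student-t (identity link;
scale and degrees of freedom ν jointly estimated with ν bounded in
[2.5, 100] — the lower bound keeps the variance finite, the upper bound is
effectively gaussian), and Gamma (log link, shape parametrization with
mean = exp(η)).

**Estimation** is marginal maximum likelihood (not REML). The scalar random
intercept is integrated out per participant by adaptive Gauss–Hermite
quadrature: a safeguarded Newton search (trust region, step halving) finds
each participant's mode of the joint log-density in u, the local curvature
scales and centres the Gauss–Hermite grid (default 11 nodes; one node
recovers the Laplace approximation, and for the gaussian family any node
count is exact). The outer optimization is L-BFGS-B over
(β, log σ_u, log-dispersion) from deterministic starts (GLM estimates on the
link scale, σ_u at 10% of the link-scale response SD), followed by up to
three Newton polish steps using the numerical Hessian — the quasi-Newton
loop alone can stall ~1e-4 from the optimum, which would break the exact
balanced-design identities the tests rely on. Quadrature invariance (9 vs 25
nodes) is tested at 1e-3 relative.

**Inference** is Wald throughout: SEs from the inverse observed information
(central-difference numerical Hessian at the optimum), z = b/SE, two-sided
normal p — no Satterthwaite or Kenward–Roger small-sample correction. The
convergence flag requires optimizer success plus a projected-gradient norm
below 1e-5 relative to |log-likelihood| (components pressing against an
active bound, e.g. ν at 100 for effectively gaussian data, are ignored).

**Contrasts.** Estimated marginal means are fixed-effect linear combinations
at each Group × Stimulus cell on the link scale; a contrast takes an ordered
pair within a group, with a delta-method SE and Bonferroni adjustment over a
declared family size m (default 2: the two comparisons against the reference
stimulus within one group). No global sign convention is imposed — the
estimate is EMM(first) − EMM(second) for whatever pair the caller declares.

**R².** Marginal and conditional R² by latent-scale variance decomposition:
var(Xβ) over observations, plus σ_u², plus the family's residual variance on
the link scale — σ² (gaussian), s²ν/(ν−2) (t), trigamma(shape) (log-link
Gamma).

**Diagnostics.** DHARMa-style simulation-based residuals: n_sim (default
250) response vectors are simulated from the fitted model with fresh random
intercepts; each observation's scaled residual is its randomized empirical
CDF position among its simulations, uniform on [0, 1] under a correct model.
A one-sample KS test summarizes uniformity and a variance ratio
(observed/simulated) flags dispersion problems.

**Correlations.** Pearson correlations at trial level, pooled over groups,
pairwise-complete after exclusions; two-sided p from the exact t transform;
Bonferroni over all 45 parameter pairs. Within-group or participant-level
aggregation is deliberately not the default (the data that motivated the
package do not state which was used; the pooled trial level is the most
granular choice).

## Synthetic data generator

The generator's defaults encode the study design: 7 preschool + 14
school-age participants, three go conditions × 10 trials at 70 Hz, plus an
optional no-go placeholder condition that never enters the analysis.
Injected effects default to the study's headline magnitudes: +6.58 mm on MH
for the school group, −2.24 mm extra leftward deviation for preschool
children in the 2-dot condition, and per-condition multiplicative MV factors
(baseline ≈ 1.105 × the 2-dot level, i.e. a 0.10 log-difference).
Per-parameter means and pooled SDs follow the published per-condition
summaries, with the pooled SD split 50/50 between the participant and trial
levels — the split is not identified by published summaries and is an
explicit, documented assumption.

A trial is rest (≥ 1 s) + movement + rest tail. The movement follows a
minimum-jerk progress s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ along Z (amplitude A),
with a vertical arc h·sin(π·s) and lateral bow d·sin(π·s). Parametrizing
the arcs by *path progress* rather than raw normalized time keeps the
velocity zero at both movement boundaries (a sin(πτ) arc would jump to
hπ/MT instantly at onset) while leaving the injected extremes exactly
d and y₀ + h. Peak transport speed is 1.875·A/MT, the minimum-jerk closed
form, which serves as an analytic oracle.

Three realism constraints matter:

- **Noise model.** White 0.2 mm noise at 70 Hz would produce filtered
  rest-phase speeds above the 5 mm/s onset threshold almost half the time.
  Optical reconstruction error is dominated by slowly varying components, so
  marker noise is white Gaussian noise coloured below ~1.5 Hz and rescaled
  to exactly 0.2 mm per axis (the variance gain of the colouring filter is
  computed from its frequency response, not estimated per trial). Rest-phase
  speeds then stay below threshold for >99% of samples, which a test
  verifies through the actual filter + differentiation pipeline.
- **Movement duration.** An onset rule requiring 500 ms above threshold
  cannot detect movements whose above-threshold phase is shorter; trajectory
  realizations therefore draw movement durations around a 0.85 s median
  (clipped at 0.62 s), while the direct parameter-table generator reproduces
  the published MT distribution (mean ≈ 458 ms) untouched. The tension
  between the published mean MT and the 500 ms persistence rule is inherited
  from the measurement protocol being emulated, not introduced here.
- **Unimodality.** The tangential speed of an arc-modulated minimum-jerk
  transport develops two *exactly tied* symmetric maxima once
  π·√(h² + d²)/A exceeds ≈ 0.65, making "time of peak speed" ill-defined.
  The generator guarantees a single dominant peak by raising the transport
  speed so that the ratio stays ≤ 0.55.

Ground truth for each trial (onset/offset/kick samples and all ten
parameters) is evaluated on the noise-free analytic profile at 20×
oversampling, with event samples mapped by ceiling (first sample satisfying
the condition). Recovery tests compare extraction only against this ground
truth, never against re-derived constants. Same seed ⇒ byte-identical
output; all randomness descends from one `SeedSequence`.

The direct parameter-table generator draws the ten parameters straight from
the mixed-model generating equations (participant intercept + cell mean +
family noise: gaussian/t on the natural scale, Gamma on the log scale,
[0, 1]-truncated normal for the normalized times), which is how the
statistical layer is exercised at scale without the kinematics in the loop.

What the generator does **not** emulate: marker occlusion and gap-filling,
no-go inhibition behaviour, biomechanical (joint-level) realism, movement
segmentation failures, or any dependence of noise on movement speed. Passing
recovery tests therefore demonstrate correctness of the pipeline under its
own stated measurement model, not robustness to every pathology of real
optical capture.

## Problem sizes used in the checks

The recovery suite extracts 200 seeded synthetic trials; mixed-model
recovery and type-I calibration each use 100 seeded replicates of the full
study design (21 participants × 3 conditions × 10 trials), and residual
calibration uses 50 replicates with 250 simulations each. These sizes give
Monte-Carlo error comfortably below the asserted margins while keeping the
default test run fast.

## Known limitations

- The Student-t df is box-bounded; for near-gaussian data it sits at the
  upper bound and the observed information is nearly singular in that
  direction (the projected-gradient convergence check accounts for this).
- Wald p-values are asymptotic; with 21 participants the random-intercept SD
  itself is estimated with substantial uncertainty, and no profile-likelihood
  or bootstrap intervals are provided.
- The kick event inherits a small acausal bias from zero-phase filtering of
  the ball trace (a few samples early); onset/offset do not.
- Lateral deviation assumes a single start–target line per trial; curved
  intended paths would be misattributed to deviation.
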