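# fingerkick

Kinematic analysis of children's finger-kick reaching movements, from raw
3-D motion-capture marker trajectories to mixed-model inference.

In the underlying task, preschool and school-age children kick a small ball
toward a goal with their index finger after seeing a non-symbolic numerical
stimulus (a 2-dot or 8-dot array, or a neutral baseline picture). The
scientific question is whether numerical magnitude biases the movement — for
example, whether small numerosities pull the trajectory leftward, as
predicted by a left-to-right mental number line. The package turns each
trial's fingertip and ball marker time series (70 Hz) into ten kinematic
parameters, applies observation-level quality control, and tests
Group × Stimulus effects with random-intercept generalized linear mixed
models.

## What it computes

**Kinematic parameters per trial** (after zero-phase 10 Hz Butterworth
filtering and central-difference differentiation, with movement onset
defined as tangential speed exceeding 5 mm/s sustained for 500 ms and offset
as the return below 5 mm/s after the ball is kicked):

- `MH` — maximum vertical (Y) position of the fingertip, mm
- `MDevRight`, `MDevLeft` — extrema of the signed horizontal-plane
  perpendicular deviation from the start–target line (left negative), mm
- `MV` — maximum tangential speed, mm/s
- `MDec` — peak deceleration after the speed maximum (absolute value), mm/s²
- `MT` — movement duration, ms
- `TMV`, `TMDec`, `TMDevRight`, `TMDevLeft` — the times of those events as
  fractions of MT in [0, 1]

**Scoring and QC**: the Mathematical Proficiency Index
MPI = ET + ACA + SCA (three 0–20 timed sub-scores: enumeration, additions,
subtractions; range 0–60), developmental group assignment, and per-parameter
z-scoring with |z| > 3 SD observation exclusion.

**Inference**: for each parameter y of participant i, trial j,

    y_ij ~ family(η_ij),   η_ij = x_ij'β + u_i,   u_i ~ N(0, σ_u²)

with treatment-coded Group × Stimulus fixed effects (reference: preschool,
2-dot condition) and a scalar random intercept per participant, estimated by
marginal maximum likelihood with adaptive Gauss–Hermite quadrature.
Families: gaussian and Student-t (identity link; t scale and df jointly
estimated) and Gamma (log link). Wald z inference, estimated-marginal-mean
contrasts with Bonferroni adjustment, marginal/conditional R² by latent-scale
variance decomposition, simulation-based (DHARMa-style) residual
diagnostics, and a Bonferroni-corrected Pearson correlation matrix.

**Synthetic data**: a seeded generator produces full experiments —
minimum-jerk transports with vertical arc and lateral bow, correlated
marker noise (0.2 mm), a stationary-then-kicked ball — together with
analytic ground truth for every event and parameter, plus a direct
parameter-table generator for testing the statistical layer at scale.

## Worked example

```bash
fingerkick run --outdir out --seed 42
```

runs simulate → extract → qc → fit → report on the default study design
(7 preschool + 14 school-age participants, 3 go conditions × 10 trials) and
prints, via `out/report.md`:

```
- trials simulated: 630
- trials extracted: 630
- observations in: 6300, excluded: 99 (1.57% of observations)

Model: MH (student_t)
| term           | b      | SE    | z     | p      |
| (Intercept)    | 70.071 | 1.270 | 55.19 | <0.001 |
| group[school]  |  6.163 | 1.555 |  3.96 | <0.001 |
...
random-intercept SD: 3.183; R² marginal 0.301, conditional 0.629
```

The generator injected a 6.58 mm school-vs-preschool difference in maximum
trajectory height; the fitted coefficient 6.16 ± 1.56 recovers it within one
standard error. The exclusion rate (1.57%) stays below the 5% QC budget, and
the simulation-based residual diagnostics for the t-family fit are
uniform (KS p = 0.51), as they should be when the fitting family matches the
generating one.

The same stages are available programmatically (`fingerkick.simulate`,
`fingerkick.kinematics.extract_parameters`, `fingerkick.scoring.zscore_clean`,
`fingerkick.inference.fit_mixed_model`, ...) and as individual CLI
subcommands (`simulate`, `extract`, `qc`, `fit`, `correlate`).

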