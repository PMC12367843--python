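# Methods

## Geometric model

An aneurysm is idealized as a spherical dome of radius
`R_dome = sqrt(h*w)/2` (geometric mean of the measured height and width,
halved) sitting on an elliptical neck with perpendicular axes `d1 >= d2`.
The dome wall is assumed to be parent-vessel wall stretched during growth
with conserved material, so the dome thickness is the vessel thickness scaled
by the neck-to-dome surface-area ratio:

    t_A = SA_neck / SA_dome * t_V
        = [pi (d1/2)(d2/2)] / [4 pi R_dome^2] * t_V
        = d1 d2 / (4 h w) * t_V.

The vessel wall thickness comes from a linear correlation of the
wall-thickness-to-lumen-diameter ratio against vessel radius, fitted
elsewhere to intra-operative measurements of cerebral arteries:

    t_V = (slope * r + intercept) * 2r,   slope = -0.0297 /mm, intercept = 0.1187.

Both coefficients are configurable (`VesselWallModel`). The linear ratio
crosses zero at `r = intercept/|slope| ≈ 3.997 mm`; at or beyond that radius
the model predicts a non-positive wall and the code raises a domain error.
We deliberately error rather than clamp: a clamped `t_V = 0` would silently
zero WTR and corrupt every downstream statistic.

The central score is `WTR = t_A / R_dome` (dimensionless, typically
`~1e-3..1e-2`); lower WTR associates with rupture. Comparators: aspect ratio
`AR = h/sqrt(d1 d2)`, bottleneck factor `BF = w/sqrt(d1 d2)`, size ratio
`SR = max(h,w)/2r`. AR, BF, SR and the sphericity statistic `|h-w|/(h+w)`
are scale-free; WTR is not, because `t_V` is nonlinear in `r` (the test suite
asserts both).

Assumptions worth keeping in mind: single-lobed, near-spherical domes only
(the screen `|h-w|/(h+w) < 0.2`, strict inequality, enforces this); uniform
wall thickness; wall material conserved from the parent vessel without
remodeling. None of these hold exactly in vivo.

### Post-rupture height correction

Measured heights of ruptured aneurysms overestimate the pre-rupture height by
14.9% on average, so the corrected analysis substitutes `h' = h/1.149` for
ruptured records only (unruptured heights are never corrected). This yields
WTR', AR', SR'. BF involves neither height nor radius changes and has no
primed variant. SR' uses the literal substitution `max(h', w)/2r`; since the
correction can only lower `h`, SR' <= SR with equality whenever width
dominates. The `sphericity` field of a corrected result is computed from the
same `h'` as its other indices; the inclusion screen always runs on raw
measurements.

## Statistical layer

- **AUC** is the midrank Mann–Whitney estimate (ties count 1/2), identical to
  the trapezoidal area under the empirical ROC; an exhaustive pairwise oracle
  checks it in the tests. All indices are oriented internally so that higher
  score = ruptured (WTR-family scores are negated), making AUC > 0.5
  comparable across indices.
- **AUC 95% CI**: DeLong structural-components variance by default; a seeded
  stratified bootstrap (2000 resamples) is available for sensitivity
  analysis. Intervals are clipped to [0, 1].
- **Operating points**: the pipeline reports the Youden-optimal cutoff
  (candidates are midpoints between adjacent distinct scores plus one cutoff
  beyond each extreme; ties break toward higher sensitivity, then the smaller
  cutoff) and can evaluate any user-supplied cutoff, so externally reported
  cutoffs can be assessed directly.
- **Positive likelihood ratio** `sens/(1-spec)` with the Simel log-method
  95% CI, variance `(1-sens)/tp + spec/fp`; a zero cell triggers a flagged
  0.5 continuity correction. Perfect specificity returns `inf` rather than
  raising.
- **Logistic regression** is fitted by Fisher-scoring IRLS on a standardized
  predictor (coefficients and covariance are transformed back), convergence
  at max |coefficient change| < 1e-8, at most 100 iterations. For a single
  predictor, perfect separation is exactly a disjoint support split and is
  detected up front; coefficient divergence (|beta| > 1e3) is a backstop.
  Wald p-value on the slope. The fit agrees with an independent
  maximum-likelihood implementation to 1e-6 in the tests.
- **Critical value**: `x* = (logit(p) - b0)/b1`, by default `p = 0.5`, the
  index value with a 50% fitted probability of presenting ruptured. The
  comparison against the theoretical threshold `6.1e-3` uses
  `|computed - reference|/|computed| * 100` (denominator = the
  cohort-calculated value).
- **Odds ratio per increment** is reported as a magnitude,
  `exp(|b1| * delta)` (default delta 0.001): the conventional "OR per 0.001
  increase" phrasing, sign-agnostic because the direction is already carried
  by the slope.
- Group comparisons: Welch t (Satterthwaite df) for continuous variables,
  Pearson chi-squared without continuity correction for categorical ones,
  missing covariates excluded pairwise. No multiplicity adjustment
  (alpha = 0.05 throughout).

The worked thickness example `t_A = WTR' * R_dome` at `R_dome = 7 mm`
propagates the critical ratio at its 2-significant-figure reporting
precision (`6.2e-3 -> 43.4 um`); the unrounded value gives 43.2 µm.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any particular
patient population:

- `h`, neck geometric-mean diameter, and `r` are independent log-normals with
  default medians 6 / 4 / 1.3 mm and geometric SDs 1.35 / 1.25 / 1.2 —
  plausible scales for cerebral aneurysms that place the WTR distribution
  (median ≈ 7.7e-3) in the regime of the fitted rupture models and keep `r`
  far below the 3.997 mm validity bound (out-of-bound draws are redrawn).
- `w = h (1 + u)`, `u ~ U(-0.18, 0.18)`, so every record passes the
  sphericity screen by construction.
- The neck splits into `d1 = g*e`, `d2 = g/e` with eccentricity
  `e ~ U(1, 1.3)`.
- Rupture labels: `P(rupture) = 1/(1 + exp(-(b0 + b1*WTR)))` with default
  link `(0.577, -72.8)`.
- If `apply_rupture_inflation` (default on), ruptured records' heights are
  multiplied by 1.149 *after* label assignment, emulating post-rupture
  measurement; applying the `h'` correction recovers the pre-inflation height
  exactly (round-trip tested to 1e-12).
- Sites (BT/Acom/Pcom at 51/15/14 parts), imaging modality, smoking (80%) and
  hypertension (79%) are drawn independently of morphometry.

Two sampling schemes: `generate_cohort` draws until fixed group sizes
(default 52 unruptured / 28 ruptured) are met — a case-control design, under
which the logistic intercept absorbs the usual sampling offset; and
`generate_prospective_cohort`, a fixed number of Bernoulli-labelled records,
under which intercept and critical value are directly identifiable.
Parameter-recovery, coverage and null-behaviour experiments therefore use the
prospective scheme. All draws flow from one `numpy` generator stream seeded
by a single integer, so cohorts are bit-reproducible;
`generate_confusion_cohort` builds deterministic score sets realizing exact
confusion counts.

What passing tests on these cohorts do **not** show: real measurement noise,
inter-rater variability, correlated risk factors, modality-specific biases,
non-spherical geometry, or the true joint distribution of clinical
morphometry. They show that the formulas, the inference machinery and the
pipeline plumbing are correct under a known data-generating process.

## Problem sizes and stochastic checks

Link recovery uses ten prospective cohorts of n = 5000: the single-cohort
recovered critical WTR has a relative sampling SD near 6% under the default
morphometry (the rupture signal is deliberately weak, AUC ≈ 0.77-0.79), so
the recovery assertion targets the 10-cohort mean (SE ≈ 1.8%) at the 5%
band. Wald coverage for the slope is estimated over 200 cohorts of n = 500;
null behaviour (flat link) uses n = 2000. All simulation seeds are fixed in
the tests and derived from `--seed` in `scripts/acceptance.py`.

## I/O and numerical conventions

All lengths are mm in files and in memory; wall thicknesses are converted to
µm only in reports. CSVs are written at full precision (`%.17g`) and read
with round-trip float parsing, so write→read is bit-lossless; `summary.json`
rounds to 3 significant figures for human consumption. Output ordering is
deterministic, so repeated runs produce byte-identical files. `d1/d2` are
canonicalized (major axis first) at read time; all formulas are symmetric in
them.

## Known limitations

- The wall-thickness chain (`t_V` correlation → conservation argument) is an
  approximation, not a measurement; WTR inherits its biases.
- Only BT/Acom/Pcom sites and near-spherical, single-lobed geometry are
  supported; no hemodynamics, no multivariable models, no survival analysis.
- The theoretical threshold `6.1e-3` is imported as a named constant; its
  mechanical derivation is outside this package's scope.
- Ties between two candidate parent vessels of equal radius resolve to the
  first-listed vessel (a documented reader convention).
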