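# Methods

## The model

`thalesarray` analyses two-nutrient intake data collected under the Geometric
Framework for nutrition. An experiment confines animals to *nutritional
rails* — rays from the origin of (nutrient A, nutrient B) space whose
direction is a diet's fixed nutrient ratio — and, in a companion *choice*
treatment, lets animals defend their *intake target* T, the coordinate they
regulate toward when free to choose.

A long-hypothesised rule of compromise for animals on imbalanced rails is
closest-distance optimisation (CDO): eat until the Euclidean distance to T
is minimised, i.e. stop at the perpendicular foot of T on the rail. All such
feet lie on the circle whose diameter is the origin–target segment, so by
Thales' theorem the inscribed angle β at an observed intake point B — the
angle between the directions B→origin and B→T — equals 90° exactly under
CDO. The package therefore reduces the question "which rule of compromise
does this array follow?" to the distribution of the statistic

    β(B) = arccos( (−B)·(T−B) / (|B|·|T−B|) ),   reported in degrees,

and its deviation β − 90. The sign is interpretable: β > 90 places B inside
the Thales circle (the animal stopped short of the CDO foot,
under-consumption); β < 90 places it outside (a tolerated surplus). The
cosine is clamped to [−1, 1] before the arccosine; a point collinear
strictly between origin and target returns the limiting 180°, a collinear
point beyond the target returns 0°; points coinciding with origin or target
(within 1e-12 of the construction scale) are degenerate and rejected, and
row-level degeneracies are dropped with a warning and counted rather than
silently ignored. The construction is two-dimensional by nature (Thales'
theorem does not extend to higher dimensions); higher-dimensional designs
must be sliced into nutrient pairs before analysis.

The intake target is the arithmetic mean of the species' choice-treatment
coordinates (no trimming — robust location estimates are deliberately out of
scope), or an explicit coordinate supplied by the user. Angles of choice
rows never enter inference by default: their geometry is near-degenerate at
the target. Uncertainty in the estimated target is *not* propagated into the
per-point angles; each angle is computed against the fixed average target.

## Estimation and tests

Per-rail deviations are estimated with a cell-means linear model
(deviation ~ rail factor, no intercept) so that each coefficient is the rail
mean; confidence intervals are estimate ± t(df_resid, 0.975)·SE with the
residual variance pooled across rails. A rail whose CI covers 0 is flagged
consistent with CDO. Pooling matches the single-linear-model `confint`
workflow standard in this literature; independent per-rail t-intervals are
available (`pooled=False`) for heteroscedastic arrays. No multiple-testing
correction is applied by default (the field reports raw CIs); Holm-adjusted
p-values are available behind `holm=True`.

The rail effect is a one-way ANOVA F on the per-point deviations. Between
two species, array *shape* is compared by the species × rail interaction in
a sequential (fit-order, main effects first) two-way ANOVA restricted to the
rails both species share; with balanced designs this coincides with the
other sums-of-squares types. The factor coding is under the caller's
control: `angle_records(..., include_choice=True)` admits the choice
treatment as an extra factor level for reproducing published analyses whose
numerator degrees of freedom imply one more level than the rail count.

The linear-model machinery is delegated to statsmodels (OLS, `anova_lm`) and
scipy (`f_oneway`); the test suite cross-checks it against hand-written
closed-form oracles (pooled-variance t-intervals, sums-of-squares F) to
1e-8.

## Synthetic arrays

`generate_cdo_array` places `n_per_rail` points at each rail's CDO foot;
`generate_archetype_array` implements the classic alternative rules:

- `equal_distance` — equal *total* intake on every rail: points on the arc
  of radius r (default |T|) centred on the origin. Since |AB| = |AC| the
  profile is analytic, β = 90° − α/2 with α the rail-to-target angle:
  negative deviations everywhere, largest at the most imbalanced rails,
  vanishing toward the target's own ratio — the surplus-tolerant
  "parabola" typical of generalist feeders. (A circle of fixed radius
  around the *target* produces the opposite ordering — β farthest below 90
  at the rails *nearest* the target ratio — and therefore cannot generate
  that profile; it is still available as `target_distance` with a
  selectable inner/outer branch.)
- `square` / `inverted_square` — nutrient A (resp. B) held at its target
  coordinate on every rail that can reach it.
- `linear` — total intake A+B held at the target's total.
- `concave` — CDO feet shrunk toward the origin by 1 − shrink·(α/α_max)²:
  under-consumption growing with imbalance, a specialist-like concave
  array.

Noise is added per coordinate after construction. The three families use
their natural dispersion parameters — Gaussian sd, Poisson λ, gamma shape
(unit rate) — and are centred by subtracting the theoretical mean (λ and
shape respectively), so growing the scale grows dispersion without
translating the array; `centered=False` keeps raw draws for fidelity
experiments with uncentred error models. Generated coordinates may go
negative under large noise and are deliberately not censored: negativity is
rejected at the I/O validation layer for empirical data, and censoring
simulated draws would bias the angle distribution. What the generators do
*not* emulate: correlated protein/carbohydrate errors, individual appetite
heterogeneity (points spread along the rail), day-to-day repeated measures.
Passing tests on these fixtures demonstrate the estimator's behaviour under
clean, independent measurement error — not robustness to those real-data
features.

## Noise-stability simulation

`noise_stability_simulation` measures how the angle estimate degrades as
measurement error grows. For each error family and each scale in the grid
(default 0.01 to 100 in steps of 0.5, i.e. 200 scales), `reps` = 100
replicate arrays of n = 100 points are drawn on the CDO feet of a known-90°
array, and the row records the mean of the per-replicate mean-β estimates
with their 95% t-band across replicates. `noise_proportion` is the scale
parameter divided by |T|. A root seed spawns an independent child stream
per (family, scale) cell, so the grid is bit-reproducible row by row.

The known-90° array defaults to *unit magnitude* (target (1,1), rails
1:4, 1:3, 3:1, 4:1), so the default grid spans error-free to
error-dominated conditions. This choice determines the qualitative result
and is worth being explicit about. In the small-noise (linear-propagation)
regime the dispersion of β depends on the error *variance* only, so at
matched scale parameter the Gaussian band (sd = s) is wider than the
Poisson/gamma bands (sd = √s) for s > 1. Once displacements exceed the
array magnitude the geometry inverts: the angle subtended by the
origin–target segment at a far-flung point shrinks as 1/|displacement|, so
the family with *larger* dispersion yields the narrower, more stable band.
On the unit-magnitude array the Gaussian family is strictly narrowest on
≈99% of the default grid; on a magnitude-100 array the mid-grid ordering
reverses. Consequently the simulation's "Gaussian errors are the most
stable" conclusion characterises arrays measured on scales comparable to or
smaller than the error — the band-width-vs-scale curve rises, peaks near
scale ≈ |T|, and falls, which is also why the band width is monotone
increasing only below the geometry scale.

## Calibration design

The null-calibration checks (CI coverage of 0 and omnibus type-I error on
CDO arrays) use target (30,30), rails {1:4, 1:3, 3:1, 4:1}, Gaussian
coordinate sd 1 (≈2% of |T|), n = 20 per rail, 1000 replicates. Coordinate
noise of sd σ maps to angular noise of variance ≈ 4σ²/(|T|·sin 2α)² at the
foot of a rail at angle α to the target ray, so per-rail angle variances are
*not* equal in general and the pooled model is only as calibrated as the
design is balanced in sin 2α. The calibration rails are symmetric pairs
with sin 2α of 0.88 and 0.80 (variance ratio 1.21), chosen a priori so the
pooled model's homoscedasticity assumption holds to a good approximation;
expected pooled coverage from the linearisation is 95.0%. Strongly
asymmetric designs (a rail nearly collinear with the target) should prefer
`pooled=False`.

## Numerical choices and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `tol_deg` | 1e-8 ° | on-circle classification tolerance; raise for noisy descriptive work |
| `ci_level` | 0.95 | confidence level of all intervals |
| `pooled` | True | pooled-variance cell-means CIs vs per-rail t-intervals |
| `holm` | False | Holm adjustment of per-rail p-values |
| `centered` | True | subtract the noise family's theoretical mean |
| rails | 1:5, 1:2, 1:1, 2:1, 5:1 | classic five-rail P:C design (generators) |
| target | (25, 35) mg | generator default, P:C ≈ 1:1.4, collinear with no default rail |
| stability grid | 0.01:100:0.5, n=100, reps=100 | noise-stability defaults |

Units are opaque metadata (mg by convention); no conversion is performed.
Rail labels are scale-invariant ratios ("7:35" ≡ "1:5"); "0:0" and
malformed labels are rejected at parse time. All simulation problem sizes
above are the package defaults; the test suite runs reduced replicate
counts of the same designs where a full run would add nothing but time.

## Known limitations

- Target uncertainty is not propagated into the angles; with independently
  collected rail and choice data the resulting significance statements are
  conservative, but correlated errors would violate that.
- Two nutrients only, by mathematical necessity of the construction.
- The pooled CI assumes comparable angular variance across rails (see
  calibration design above).
- Repeated measures (e.g. per-day intakes of the same individuals) are
  carried as an optional `group` column but modelled as independent; no
  mixed-effects support.
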