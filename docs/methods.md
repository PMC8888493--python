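# Methods

This note documents the statistical procedures implemented in nutriscape,
the choices made where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Diet space

A diet is a P:C ratio in parts plus a total-nutrition dilution (the
fraction of diet mass that is protein + carbohydrate; the rest is inert
bulk).  The landscape coordinates are protein % and carbohydrate % of
total diet mass, so a ratio r = p:c at dilution T sits at
(100·T·p/(p+c), 100·T·c/(p+c)) and all diets of one dilution lie on the
line P + C = 100·T.  The reference design crosses 10 ratios
(3:1 … 1:16) with 4 dilutions (12/36/60/80%), giving 40 diets whose
convex hull is the admissible search region for optima: no optimum is
ever reported outside the sampled nutrient space.

## Response surfaces

Per trait × sex, the trait and both coordinates are z-scored within the
fitted dataset (sample SD, ddof 1) and the trait is regressed on
{P, C, P², C², P·C} with an intercept by OLS (statsmodels).  Reported
gradients are therefore standardized effect sizes comparable across
traits.  Conventions worth knowing:

- Quadratic gradients are the raw OLS coefficients on the squared
  standardized predictors — *not* doubled.  The fit records this in
  `quadratic_convention` so the doubled (curvature-matrix) convention can
  be derived if needed.
- Residual df = n − 6; p-values are two-sided from t with that df.
- Squares/products are formed *after* standardization, never re-scaled,
  so the design is exactly reproducible from the stored constants.
- Standardization is within the fitted dataset.  When datasets are later
  compared, each group's trait is re-scored within its own group (see
  below), so a comparison never depends on which group came first.

## Thin-plate-spline landscapes

Records sit on few distinct diets, so the spline is fitted to per-diet
weighted means (weights = replicate counts n_i), minimising

    Σ_i n_i (ȳ_i − f(x_i))² + λ·cᵀKc

over f(x) = Σ_j c_j Φ(‖x − x_j‖) + a₀ + a_P·P + a_C·C with
Φ(r) = r²·log r.  Stationarity gives the symmetric saddle system
[[K + λW⁻¹, T], [Tᵀ, 0]]; λ = 0 interpolates the diet means and λ → ∞
recovers the weighted least-squares plane (the affine null space of the
penalty).  Knot coordinates are z-scored before kernel evaluation — this
makes the fit equivariant under common rescaling of the axes — and all
public I/O stays on the raw percentage scale.

λ is selected by minimising the weighted GCV score
(Σ n_i e_i²/N) / (1 − tr(A)/m)² over a fixed grid of 61 log-spaced values
spanning 12 decades around a data-scale pivot (mean absolute off-diagonal
kernel entry × mean weight).  A fixed grid rather than a continuous
optimiser keeps the selection bit-reproducible across platforms; the
grid is wide enough that the selected λ is interior in practice.
Effective df = tr(A) decreases monotonically from m (interpolation)
to 3 (plane).

## Optima and confidence regions

The landscape maximum is located by evaluating a dense grid over the diet
hull (default 101², vertices always included) and refining the best seed
with SLSQP under the hull's half-space constraints; ties break toward
lower protein.  The result never falls below the best grid seed.

Uncertainty: individuals are resampled with replacement within each diet
(stratified, preserving per-diet sample sizes), the spline is refitted
and re-optimised, B times.  Because stratified resampling leaves the
knots and weights unchanged, the penalized systems for the whole λ grid
are factored once and every replicate costs one back-substitution per
candidate λ — so each replicate re-selects λ by GCV, mimicking the full
estimation pipeline.  This matters: freezing λ at the point estimate's
value removes smoothing-selection variability from the cloud and
measurably undercovers (0.82 vs 0.92 empirical coverage at nominal 95%
in the package's own paraboloid simulation); re-selection is the
default, `lambda_reselect=False` or a numeric λ freezes it.  Replicate
optima are searched on a cached 61² hull grid followed by two local
7×7 zoom passes (final resolution ≈ 0.1% nutrient units), which keeps
B = 1000 runs in seconds.

The 95% CR is the convex hull of the bootstrap optima after discarding
the ceil(α·B) most outlying points, ranked by Mahalanobis distance from
the coordinate-wise median under the cloud's own covariance.  Euclidean
ranking was rejected because optimum clouds are typically elongated
(curvature differs along and across the dilution axis) and isotropic
trimming over-trims the major axis, shrinking coverage.  For degenerate
(zero-variance) clouds the rule falls back to Euclidean distance.

Coverage caveat: a 2-D confidence region is only meaningful for an
interior optimum.  When the true optimum lies on the hull boundary
(e.g. lifespan maximised at the highest sampled dilution), every
constrained estimate is edge-pinned, the CR collapses toward a segment
of the boundary, and "the true point is inside the region" becomes a
measure-zero event even for a perfectly calibrated procedure.  The
package still reports the region (it is informative about position along
the edge), but containment-based coverage claims are restricted to interior
optima, and the calibration simulation in the test suite places its
paraboloid peak in the hull interior for exactly this reason.

Distances between two optima: d = mean of all pairwise Euclidean
distances between the two bootstrap clouds (deterministically subsampled
above 10⁶ pairs), with the 2.5th/97.5th percentiles of that pairwise
distribution as bounds.  d is symmetric and nonnegative; note the mean
need not lie between the percentile bounds by construction, though it
does in practice.

## Sequential model-building comparisons

To compare nutrient effects between two datasets (sexes, or traits
within a sex), each dataset's trait is z-scored internally, the records
are stacked with a group indicator g, and the nutrient coordinates are
z-scored on the pooled design.  Three nested partial F-tests follow, each
stage inheriting the previous stage's group-specific structure:

| stage | reduced model | complete model | df₁ | df₂ |
|---|---|---|---|---|
| linear | 1, g, P, C | + g·P, g·C | 2 | n−6 |
| quadratic | stage-1 complete + P², C² | + g·P², g·C² | 2 | n−10 |
| correlational | stage-2 complete + P·C | + g·P·C | 1 | n−12 |

F = ((SS_R − SS_C)/df₁)/(SS_C/df₂).  With two groups of 800 the df₂
sequence is 1594/1590/1588.  Univariate follow-ups drop a single group ×
term column from the stage's complete model (df₁ = 1, df₂ as the stage).
Within-sex trait comparisons (e.g. lifespan vs daily reproductive effort
measured on the same flies) are run as independent stacks; the resulting
non-independence of residuals is a known caveat of this design and is
not corrected.

The angle between two traits' nutritional vectors is
θ = arccos(v₁·v₂/‖v₁‖‖v₂‖) ∈ [0°, 180°], with a percentile bootstrap CI
from within-diet stratified resampling of each dataset independently.
Percentile (not BCa) intervals are used throughout for determinism; note
arccos is ill-conditioned near 0° and 180° (≈10⁻⁴ degrees of numerical
noise at exact collinearity), which is far below any biological signal.

## Synthetic-data generator

The generator emulates the reference experiment: each (trait, sex) has a
true quadratic surface on standardized grid coordinates; per diet × sex,
n individuals receive a lifespan from a zero-truncated Gaussian around
the surface value, then one reproduction count per 5-day assay survived
(day 5, 10, …), drawn negative-binomially around the sex's per-assay
rate surface (Poisson and rounded-Gaussian available).  Daily
reproductive effort is the mean count per assay, total effort the sum —
so total effort is structurally correlated with lifespan through the
number of assays, exactly the trade-off structure the analysis probes.
Individuals dying before day 5 carry no reproductive data and are
dropped with a log message (never resampled, to keep the RNG stream
stable); under the default surfaces and noise levels this is a rare
event (worst-diet probability below 10⁻³ per fly, usually far less).

Default study conditions (chosen once to mirror the biology the design
embodies, in days and counts): male lifespan 45 − 7P + 7C + 1.5P² −
4.5C² − 4PC (SD 8), female lifespan 50 − 4.5P + 5C + P² − 3.8C² − 2PC
(SD 8); male per-assay siring rate 12 − 2.5P + 2.2C + 0.3P² − 1.4C² −
1.5PC, female per-assay fecundity 40 + 8P + 7C − 9P² − 8C² + PC (both
negative binomial, dispersion 2).  These place the noise-free lifespan
argmax of both sexes on the 1:16 ratio at 60% dilution (protein-averse,
steeper in males), male reproduction likewise carbohydrate-biased, and
female fecundity near a balanced blend — protein-hungry relative to
lifespan, so the female lifespan–reproduction conflict is present in the
defaults.  Rate surfaces are floored at 0.05 counts/assay where the
quadratic dips negative at grid extremes.

What the generator does *not* emulate: mating-partner dynamics, sperm or
egg depletion, age-dependent fecundity decline within individuals,
censoring (all lifespans are observed to death), diet-dependent
overdispersion, or measurement error in diet composition.  Passing tests
therefore demonstrate that the estimation machinery recovers known
structure under idealised sampling — not that real fly data satisfy the
quadratic-plus-noise model.

## Problem sizes and numerical defaults

The test suite and the acceptance script use the full 40-diet design
with 20 individuals per sex per diet (N = 1600) for design-structure
checks; calibration simulations use B = 200 bootstrap replicates and
200 Monte-Carlo repetitions, and the full pipeline default for reported
runs is B = 1000.  Grid resolutions: 101² for point optima, 61² plus
two 7×7 zooms for bootstrap optima, 100² for exported landscape grids.
Degenerate inputs fail loudly: constant variables cannot be z-scored,
collinear diet sets cannot support a spline, a single-diet design is
rejected as rank-deficient, and two-dilution subdesigns are rejected
because {1, P, C, P², C², P·C} is exactly collinear when P + C takes
only two values.
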