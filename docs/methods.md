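# Methods

This note documents the models, numerical choices and known limitations
behind `hamqc`.

## Cole model and the Py statistic

Tissue impedance over the beta-dispersion band is modeled as

    Z(f) = R∞ + (R0 − R∞) / (1 + (j·2πf·τ)^α)

with R0 > R∞ ≥ 0 (Ω), τ > 0 (s) and α ∈ (0, 1]. The quality statistic is
the normalized dispersion drop Py = (R0 − R∞)/R0 × 100 (dimensionless
percent, scale-invariant in the resistances), and the characteristic
frequency is f_c = 1/(2πτ) — the exact location of the −Im(Z) peak in the
Debye limit α = 1.

### Fitting

The fit criterion is the proportionally weighted complex least-squares
objective Σ_f |Z_meas − Z_model|² / |Z_meas|². |Z| spans a wide range
over 10 Hz–1 MHz; unweighted residuals would be dominated by the
low-frequency end and starve the high-frequency tail that pins down R∞
and α. Implementation:

* Optimizer: `scipy.optimize.least_squares` (trust-region reflective) on
  the vector (R∞, R0 − R∞, log τ, α). Parameterizing the *difference*
  R0 − R∞ > 0 enforces R0 > R∞ by a bound instead of a constraint, and
  log-space τ removes its scale pathology.
* Bounds: R∞ ≥ 0, R0 − R∞ ≥ 10⁻⁹, log τ ∈ [log 10⁻¹², log 10⁴],
  α ∈ [0.05, 1.0]. The α upper bound is inclusive (Debye limit); the
  lower bound excludes numerically flat dispersions.
* Tolerances 10⁻¹⁰ (ftol/xtol/gtol), at most 2000 objective evaluations,
  up to 3 deterministically seeded jittered restarts on failure. A final
  failure raises a non-convergence error that still carries the best
  result found, so pipeline callers can flag rather than drop the row.

### Initialization

R0 starts at |Z| at the lowest measured frequency and τ at 1/(2π f_peak)
where f_peak maximizes |Im Z|; α starts at 0.8. The raw |Z| endpoint at
the top frequency *overestimates* R∞ whenever the dispersion tail extends
beyond the measured band (with f_c ≈ 32 kHz and α = 0.8 the 1 MHz
endpoint is still ~9 % above R∞), so the guess applies one fixed-point
correction: subtract the model-predicted residual dispersion at f_max
from the measured real part, using the R0/τ/α guesses already in hand.
This brings the starting R∞ within a fraction of a percent on clean
spectra at negligible cost. A spectrum with constant |Z| (relative range
below 10⁻⁶) has no dispersion to fit and is rejected as degenerate.

### Replicates

Each replicate reading is fitted separately and the *Py values* are
averaged — not the raw Cole parameters — because Py is the quantity
carried into the statistics and is scale-invariant, whereas averaging
resistances across replicate electrode placements would mix geometry
factors. An aggregate is flagged when the replicate Py range exceeds a
configurable threshold (default 5 Py units).

Electrode geometry, cell constants and temperature compensation are not
modeled; spectra are taken as-is.

## DES scoring

Observer scores are integers 0–3; the final DES value is the two-observer
mean on the half-integer grid, grouped as DES0 {0, 0.5}, DES1 {1, 1.5},
DES2 {2, 2.5}, DES3 {3}. Joint (training) samples carry identical scores
for both observers and a `joint` flag so analyses can include or exclude
them.

Inter-observer "prediction error" is the RMSE of the residuals of an
ordinary least-squares degree-2 polynomial regression of observer 2 on
observer 1 (MAE is co-reported as a secondary diagnostic). RMSE is used
because the companion multivariate prediction error is also an RMSE-type
average deviation; the quadratic is fitted on {1, x, x²} by `lstsq`,
which tolerates the rank deficiency that arises when a score series
contains fewer than three distinct values. Integer ties are left as-is.

## Synthetic cohort generator

The generator emulates a slaughterhouse cohort in which one latent defect
severity drives every quality variable:

* Latent scale: a multivariate normal over the six continuous variables
  (Py AD/SM, pH_u, L\*, a\*, b\*) plus a standard-normal severity factor.
  Pairwise latent correlations are factor-implied (loading products) plus
  explicit residual terms for pairs the single factor cannot hit; pairs
  with no configured target keep a zero residual and are reported as
  unconstrained. The SM Py loading is tied to the AD loading (same tissue
  property), with the AD–SM target met through the residual term.
* Marginals: location/scale transforms of the latent normals, truncated
  by rejection resampling (redraw whole rows, no point masses at the
  bounds). Defaults — pH_u 5.6 ± 0.15 in (4.5, 7.5); L\* 50 ± 4;
  a\* 8 ± 2; b\* 4 ± 1.5; Py(AD) 45 ± 15 in (0, 100); Py(SM) shifted
  +8 units above AD. **These marginal locations and scales are invented
  defaults**: no published descriptive table backs them, so they were
  chosen once as plausible values for 24-h post-mortem pork ham and are
  not calibration targets.
* Scores: observer k's latent score is w·severity + √(1−w²)·ε_k, cut at
  the standard-normal quantiles of the marginal score probabilities
  (default 0.35/0.30/0.20/0.15 for scores 0–3 — heterogeneous, all four
  ranks well populated). Joint samples take the consensus score from
  severity alone. The shared weight w is the free parameter behind the
  observer-agreement target.

### Calibration

Thresholding and truncation attenuate correlations, so latent parameters
are calibrated by a simulate–measure–adjust fixed point: each iteration
simulates a pilot cohort (default 50 000 rows) with a *fixed* calibration
seed — reusing the same normal draws makes the iteration a smooth
deterministic map — measures every target pair on the observed scale, and
shifts the responsible parameter by the residual (loadings answer for
variable–DES pairs, w² for the observer pair, residual correlations for
continuous pairs). Convergence: all errors ≤ 0.0075 correlation units
(typically 3 iterations). A stagnant error that no update removes is
accepted only if it is below the Monte-Carlo resolution of the pilot
(4/√n); otherwise calibration fails with the achieved values attached.
Latent matrices that drift mildly indefinite are repaired by eigenvalue
clipping; strongly indefinite structures (minimum eigenvalue < −0.05)
are reported as infeasible. As a consequence of attenuation, calibrated
latent magnitudes always weakly exceed the observed-scale targets for
ordinal-involved pairs.

The observer-agreement statistic is defined on separately scored samples
only; joint samples agree by construction and would inflate it, so
calibration and the agreement checks use a cohort with `joint_fraction`
0.

### Spectra

Per record and muscle, Cole parameters are drawn with R0 ~ U(150, 450) Ω,
f_c log-uniform in (2, 80) kHz (comfortably inside the measured band),
α ~ U(0.6, 0.9), and R∞ = R0(1 − Py/100) so the spectrum's Py matches
the record exactly. Two replicates are emitted on the 40-point log grid
with proportional complex Gaussian noise (default 1 % of |Z| per point
and component).

### What the generator does not emulate

Breed, farm, slaughter-day and anatomical-location effects; drip loss;
non-Gaussian marginal shapes; systematic observer bias (only symmetric
observer noise). Passing tests therefore demonstrate that the *pipeline*
recovers what the generator encodes — correlation structure, Py values,
score distributions — not that real ham cohorts follow this generative
model.

## Statistics

* Pearson correlations use the product-moment estimate with the exact
  two-sided t-transform p-value (t = r√((n−2)/(1−r²)), df = n−2);
  a correlation of −0.461 corresponds to R² = 21.25 %.
* Stepwise regression is the classic forward–backward procedure on OLS:
  add the candidate with the smallest partial-F p-value (equivalently the
  t-test of its coefficient in the augmented model) while below α-enter,
  then remove included terms above α-remove, until no move is possible.
  Defaults α-enter = α-remove = 0.15. Ties break on candidate order;
  terms that make the design singular are skipped with a warning; a
  repeated model state terminates the loop; an empty selection returns a
  flagged intercept-only model. Term hierarchy is *not* enforced by
  default (squares and interactions may enter without their parents); a
  `force_hierarchy` flag turns it on.
* "Prediction error" is in-sample RMSE, with MAE co-reported.
  A leave-one-out cross-validated RMSE for a fixed term set is available
  (`loo_rmse`, closed-form hat-matrix identity) but is not the headline
  metric.
* The DES average is treated as a continuous response in correlation and
  regression; ordinal-regression alternatives are out of scope.
* Full-cohort analyses include joint-scored training samples; the
  joint-excluded subset is analyzed in parallel, mirroring the two ways a
  mixed training/evaluation cohort can be summarized.

## Problem sizes

The test suite and the acceptance script use: 50 noiseless and 200 noisy
(1 %) spectra for parameter-recovery checks; 100 small stepwise problems
(n ≤ 50, ≤ 8 candidate terms) against a from-scratch greedy oracle;
pilot cohorts of 50 000 rows for calibration; 5000-animal cohorts for
correlation recovery; and a 136-animal end-to-end run with spectra
(544 Cole fits). These sizes give Monte-Carlo standard errors a factor of
a few below the corresponding test tolerances.

## Known limitations

* Single-dispersion Cole only; no electrode-polarization correction, no
  double-Cole or multi-dispersion models, no temperature or geometry
  compensation.
* The frozen reference equation is reproduced as printed and is reliable
  only inside its fitted data manifold; evaluated at arbitrary points it
  strays far off the 0–3 scale (an optional clamp is provided).
* The pH_u–DES correlation is reported with inconsistent sign in the
  literature its default derives from; the generator uses −0.44 and
  magnitude-based checks are preferred where that pair is involved.
* Stepwise selection at n = 136 is intrinsically unstable; selected term
  sets vary across seeds even when prediction errors do not.
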