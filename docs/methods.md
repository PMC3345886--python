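# Methods

## Model

Per grid cell, presence/absence is modelled as Bernoulli with

    logit P = y = β₀ + Σᵢ βᵢ xᵢ

fitted by maximum likelihood (statsmodels' Newton/IRLS). Covariates enter
in natural units — coefficients read "per mm of precipitation", "per metre
of altitude" — but are standardized internally for conditioning; the
coefficient vector and its covariance are back-transformed before
reporting, so standard errors are exact for the raw-unit parameterization.
Convergence: |Δ log-likelihood| < 1e-8 or 100 Newton iterations. The
intercept-only model is returned in closed form (β₀ = log n₁/n₀,
SE = √(1/n₁ + 1/n₀)).

The favourability transform is

    F = e^y / (n₁/n₀ + e^y)

computed directly from the linear predictor (numerically stable at any
|y|); the probability-form `favourability(P, n1, n0)` clips P into
[1e-12, 1−1e-12] before forming odds, and maps the endpoints P ∈ {0, 1}
to their exact limits F ∈ {0, 1}. F = P when n₁ = n₀, F = 0.5 exactly at
the training prevalence, and F is strictly increasing in P and strictly
decreasing in n₁/n₀.

Assumptions worth keeping in view: cells are conditionally independent
given the covariates (no autologistic/spatial-error term), detection is
perfect (an absence means "surveyed, not found"), and one cell is one
Bernoulli trial — a survey whose support is finer than the cell (e.g.
river stretches within an 8-km cell) is treated as aggregated to the cell.

## Stepwise selection

Forward-only. At each round every remaining candidate is refitted with
the current model; the candidate with the smallest likelihood-ratio
p-value (χ², 1 df) enters while p < `entry_alpha` (default 0.05; an AIC
mode adds the best candidate while AIC improves). `inclusion_order`
records the 1-based round at which each variable entered. `entry_alpha=0`
yields the intercept-only model. Candidates that cannot be fitted (e.g.
constant-valued in the data) are skipped, not fatal. Selection p-values
are nominal, not corrected for the search — the order of inclusion, not
inference on it, is the quantity of interest here.

Published coefficient tables sometimes carry internally inconsistent
ranks; `CoefficientSet.rank_warnings()` surfaces any rank multiset that is
not a permutation of 1..k rather than repairing it, and the packaged
fixtures preserve the printed values verbatim.

## Complete separation

statsmodels no longer raises on separation by default, so the fit checks
the definition directly: if the fitted linear predictor perfectly
separates the classes (min over presences > max over absences) and some
standardized coefficient exceeds 20 in magnitude, a `SeparationWarning`
reports the diverging coefficients. The fit is still returned — the
coefficients are usable as a classifier even when their MLE diverges.

## Evaluation suite

Threshold-dependent indices come from the confusion matrix at a stated
threshold (predicted present iff score ≥ threshold; ties side with
presence, deterministically). Sensitivity, specificity, PCC/OA, PPP and
NPP are simple count ratios; an index whose denominator is zero is
reported as NaN ("undefined"), never 0 or 1, so degenerate predictions
cannot look perfect. TSS and Kappa are computed as single exact integer
ratios —

    TSS   = (tp·tn − fn·fp) / ((tp+fn)(tn+fp))
    Kappa = 2(tp·tn − fn·fp) / ((tp+fp)(fp+tn) + (tp+fn)(fn+tn))

— algebraically identical to sensitivity + specificity − 1 and to
(pₒ−pₑ)/(1−pₑ) but correctly rounded, so they match a rational-arithmetic
oracle bit-for-bit.

AUC uses the Mann–Whitney rank statistic with midranks on ties,
(R₁ − n₁(n₁+1)/2)/(n₁n₀); for n ≤ 500 the rank sums are exact in double
precision, so the result equals exhaustive pair counting identically. AUC
is invariant under strictly increasing transforms of the scores, so logit,
probability and favourability surfaces give the same AUC.

Threshold policies: a fixed value (default 0.5 — on the favourability
scale this classifies cells more favourable than the training average as
present, the conventional choice in the favourability literature),
`prevalence` (the observed prevalence, natural for raw probabilities), or
`max_tss` (the observed score maximizing TSS, ties broken toward the
lowest score). Evaluation defaults to resubstitution (scoring on the data
in hand); held-out evaluation is just the same functions applied to other
observations.

## Transference

`transfer_model` applies a `CoefficientSet` to another region's grid. The
favourability correction defaults to the model's own training n₁/n₀ (the
coefficients and the correction travel together); `prevalence_source=
"target"` re-anchors on the target survey's prevalence instead — both are
defensible, so both are supported. Coverage diagnostics report, per model
variable, the fraction of target cells outside the training range: the
operational measure of how much of the target landscape the model has
never seen. The packaged published models carry no training n₁/n₀ (not
published), so using them requires supplying a prevalence explicitly
(`--n1/--n0` on the CLI) or `prevalence_source="target"`.

## Synthetic landscapes

Covariate surfaces are white Gaussian noise smoothed with a Gaussian
kernel (σ = `autocorrelation_range`, in cells; 0 = i.i.d.), then affinely
rescaled so the empirical min/max equal the declared range exactly (a
constant field — possible only on degenerate grids — maps to the range
midpoint). Smoothing demonstrably raises lag-1 Moran's I; the tests check
this against a direct Moran's I computation. The latitude variable (`Lati`)
is not a random field: it is the cell-centre y coordinate rescaled into
the declared range, since latitude is a coordinate, not a measurement.

Outcomes are independent Bernoulli draws from the truth's logistic P.
The truth may declare per-variable saturation bounds (`response_clamp`):
the covariate is clipped into the bounds before multiplying by its
coefficient, making the truth nonlinear outside the window while every
fitted model remains linear-logistic — the controlled misspecification
that makes transference fail under a range shift.

Default study conditions: 40×40 grids (1600 cells, matching the scale of
the ~1600-record field surveys such models are fitted to in practice);
five variables named after the reduced predictor set of an edge-of-range
favourability model (Alti 0–3000 m, Prec 500–1500 mm, SRad 2–7 kWh/m²/day,
DPre 80–180 days/yr, Lati 42–43.5 °N); truth
y = −7 + 0.01·min(Prec, 1100) − 0.002·Alti, autocorrelation range 3
cells. Realized prevalence is moderate (roughly 0.3–0.6 across seeds).
In the two-region scenario the target region's precipitation range is
1200–2200 mm — entirely inside the saturated zone — so precipitation
carries no signal there while the transferred model still weights it
heavily; with `shifted=False` the regions are identically configured.

What the generator does *not* emulate: detection error, spatially
clustered survey effort, residual spatial autocorrelation in occupancy
beyond what the smoothed covariates induce, and covariate
cross-correlation structure. Passing tests therefore demonstrate the
correctness of the estimators and the logic of the transferability
mechanism, not field realism.

## Verification experiments (problem sizes)

All experiments run in seconds on one CPU and are fully seeded.

- Favourability identities: 1000-point sweep of P × 10 (n₁, n₀) pairs,
  tolerance 1e-12.
- AUC: 100 random instances, n ≤ 500, ties injected by coarse rounding,
  rank vs brute-force pair counting, tolerance 1e-12 (observed 0).
- Index suite: the 40/10/30/20 hand example plus 20 random matrices vs a
  `fractions.Fraction` oracle, exact equality.
- Parameter recovery: 50 replicates of 5000-cell (50×100) landscapes,
  truth β = (0.8, −0.5), intercept −0.3 on covariates in (−2, 2); all
  three parameters within 3 estimated SE in ≥ 95% of replicates.
- Stepwise: 50 replicates, one β = 2 signal vs three noise candidates on
  40×40 grids; the signal enters first in ≥ 95% of replicates.
- Transferability: 20 shifted replicates (transferred AUC below local AUC
  in ≥ 90%); the exchangeable control uses 100 replicates because it
  estimates a mean expected to be zero and needs a tight Monte-Carlo SE
  (~8e-4). Both fits are scored on a third independent landscape drawn
  from the target configuration, which makes the two estimators
  exchangeable by symmetry in the identical-ranges case — scoring on the
  local model's own landscape would leave it a small adaptation advantage
  under the clamped (misspecified-linear) truth even without any range
  shift.
- TSS vs Kappa: 20 benchmark landscapes; the evaluation set's prevalence
  is halved by subsampling presence cells with the scores held fixed;
  mean |ΔTSS| is compared with mean |ΔKappa| (observed ≈ 0.016 vs
  ≈ 0.08).

## Known limitations

- No spatial autocovariate, regularization, or blocked cross-validation;
  no calibration/reliability assessment (discrimination only).
- The ESRI ASCII raster writer stores full-precision `repr` floats —
  byte-reproducible, but files are larger than binary rasters; no GeoTIFF.
- Stepwise entry tests are nominal χ² and the procedure is forward-only.
- The clamp-style nonlinear truth is one convenient mechanism for
  transfer failure; real transfer failures also arise from missing
  predictors, biotic interactions and detection differences, none of
  which are simulated.
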