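# Methods

Statistical conventions, model definitions, and the design of the synthetic
cohort generator. Times are months throughout; events are 0/1 flags.

## IHC scoring

- **IRS** = SI × PP with SI, PP ∈ {0,1,2,3}; attainable values are
  {0,1,2,3,4,6,9}. The percent-positive band PP maps 0% → 0, (0,10)% → 1,
  [10,50)% → 2, [50,100]% → 3; boundary conventions are inclusive at 10 and
  50 (`bin_percent_positive`).
- **H-score** = 1·weak% + 2·moderate% + 3·strong%, range 0–300; the three
  band percentages may sum to less than 100 (the remainder is unstained)
  but never more.
- **Positivity rules**: ER/PgR positive at ≥1% stained nuclei; Ki67 high at
  ≥14%; HER2 positive when IHC 3+ OR FISH ratio > 2.2 OR gene copies > 6
  (all three missing ⇒ status missing, never imputed negative); EGFR
  positive at ≥1%; CK5 positive on any staining. Each returned status
  carries the rule it applied.

## Subtype classifier

Hormone receptor (HR) positive = ER or PgR positive. Five classes:

| HR | HER2 | Ki67 | subtype |
| --- | --- | --- | --- |
| + | − | <14% | luminal_A |
| + | − | ≥14% | luminal_B |
| + | + | (not consulted) | luminal_HER2 |
| − | + | — | HER2_enriched |
| − | − | — | triple_negative |

Calling a tumor HR-negative requires both ER and PgR observed negative; a
missing input that the row's rule actually needs yields `unclassifiable`
(explicit, never a silent default).

## Dichotomization and cut-point selection

"High" means score ≥ cut-off. Medians use the averaging convention;
quartiles and deciles of coarse ordinal scores use lower interpolation so
every candidate is an attainable score value. The 9-decile log-rank scan is
exploratory only: the result object carries a multiplicity warning and no
auto-selection, because the minimum p over nine data-driven cuts is not a
valid single test.

Internal cross-validation (`internal_cross_validation`): 100 stratified
train/validation splits (default strata: nodal status, surgery type,
subtype, taxane treatment; per-cell balance within one patient). Each
replication applies the training median to the validation half and fits a
proportional-hazards model of the dichotomized marker in both halves. The
default acceptance rule (`validate_candidate`, configurable) rejects a
candidate when more than 80% of validation confidence intervals cross
HR = 1 **and** the median validation HR sits in [0.8, 1.25] — estimates
oscillating around the null. The final pre-defined cut-off is the median of
the per-replication training medians. When that cut-off equals the minimum
observed score (as happens for a marker whose median IRS is 0) the pipeline
applies a present-vs-absent split at the next attainable value and records
`cutoff_adjusted`; the original median-of-medians is still reported.

## Survival models

Kaplan-Meier estimation and the k-sample log-rank test wrap lifelines;
Greenwood's variance is recomputed from the event table. Cox models use
Efron tie handling by default (lifelines, with a tightened stopping rule —
the library default leaves ~1e-6 coefficient error) and Breslow via
statsmodels `PHReg` behind a flag. Constant covariates and models with more
covariates than events are refused; non-convergence (including |coef| > 50,
a separation heuristic) is flagged, never silently reported.

Multivariate models use backward elimination on blocks (a categorical
covariate's dummy set is dropped or kept as a unit via a Wald chi-square
test) with stay level α = 0.15; the combined biomarker variable is always
retained. The elimination path, not only the final model, is deterministic
given the design matrix. Effect-modification checks use a Wald test on a
cluster × group product term.

## Combined biomarker clusters

Primary variables, defined within luminal A+B: IGF1R-alpha high with IGF2R
low, and IGF1R-alpha high with EGFR negative. Comparator is "the rest"
within the same subtype filter; patients outside the filter or missing a
constituent marker are unassessable and excluded (counted in the attrition
report). Four complementary combinations serve as negative controls. A
sensitivity analysis widens the filter to include luminal-HER2 and reports
the interaction p-value between cluster membership and the added group.

## Multiple correspondence analysis

Indicator-matrix MCA: dummies per category, chi-square metric, SVD of the
standardized residual matrix, J − Q structural dimensions, category
principal coordinates. Complete-case analysis with the dropped count
reported. Total inertia equals J/Q − 1 exactly for complete data (a test
asserts this, plus agreement with a Burt-matrix eigendecomposition oracle
to 1e-10). Raw inertia percentages are reported by default; the Benzécri
adjustment is available behind a flag. `inverse_association_check` computes
the signed cosine between two categories' coordinate vectors; a cosine
below −0.3 (configurable) is called an inverse association.

## Synthetic cohort generator

- **Subtypes** are drawn from fixed proportions (defaults ≈
  24.7/38.6/13.4/10.7/12.6%).
- **Markers** (IGF1R-alpha, IGF1R-beta, IGF2R, IGFBP2, EGFR) come from a
  Gaussian copula: one latent multivariate normal draw per patient
  (eigendecomposition factor of the configured correlation matrix),
  thresholded into ordinal categories using subtype-specific marginal
  distributions, then expanded into consistent SI/PP pairs, H-score band
  percentages, and EGFR percentages. ER/PgR/Ki67/HER2/CK5 readings are
  generated so that the classifier recovers the generating subtype exactly
  when nothing is missing.
- **Covariates** (menopause, nodes, size, grade, histology, surgery,
  radiotherapy, hormonotherapy, taxane) are drawn independently from
  configurable marginal frequencies. They are independent of the markers
  given subtype — only marginals are matched, a deliberate simplification.
- **Events**: one linear predictor η (configurable log-hazard coefficients
  over covariate indicators and the two true cluster memberships, defined at
  the theoretical population medians of the generating IRS mixtures) drives
  two independent event processes, relapse and death, each exponential (or
  Weibull) with hazard λ·exp(η). DFS = min(relapse, death), OS = death, so
  **both endpoints are exactly proportional-hazards in η and DFS ≤ OS by
  construction**. An earlier coupled design (OS = DFS + post-relapse
  survival) amplified the cluster effect on OS roughly twofold and was
  abandoned; with independent processes the configured hazard ratio is
  recovered without bias (mean estimated HR 0.56 for a true 0.55 over 150
  replications at n = 1000, CI coverage ≈ 97%).
- **Censoring**: administrative horizon 166.7 months plus uniform dropout
  with probability 0.5 — a proxy for staggered accrual, which is not
  modelled. Baseline hazards (relapse 0.0022/month, death 0.0015/month)
  were calibrated to 4-year anchors of ≈76% DFS and ≈90% OS. Cumulative
  observed event fractions are consequently higher than in a staggered-entry
  cohort with the same 4-year rates; this is a known, documented property,
  not tuned away.
- **Missingness** is MCAR per marker group (SI and PP vanish together).
- Determinism: `numpy.random.default_rng(seed)` throughout; replication
  seeds are spawned from `SeedSequence` and kept below 2³¹.

### Known behaviour of the negative controls

With a single protective cluster configured, the complementary "control"
combinations mechanically show mirror-image adverse effects in simulation
(their comparator group contains the protected members). Interpreting
control-cluster effects therefore requires a null-configured generator, as
the calibration tests do.

## Problem sizes and budgets

Defaults — 1,021 patients, 100 cross-validation replications, 4 markers ×
2 endpoints — are package configuration choices; the full default pipeline
runs in under a minute on one CPU and is tested to be byte-identical across
reruns with the same seed. All artifacts are CSV/JSON with sorted keys.

## Limitations

- Covariate–marker dependence beyond the marker copula is not modelled.
- The dropout model is uniform, not accrual-based; absolute event counts
  should not be compared to staggered-entry cohorts.
- The backward-elimination stay level (0.15) and the cut-off acceptance
  rule are conventional defaults exposed as parameters, not estimated.
- MCA inference is descriptive; no bootstrap of the coordinates.
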