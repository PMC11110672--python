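# Methods note

Statistical models, numerical choices and design decisions behind
`flowerhabit`. Notation: `a` accessions, `y` years, `r` blocks per year
(replicates); Vg, Vy, Vgy, Vb, Ve are the genotype, year, genotype-by-year,
block-within-year and residual variance components.

## Trial model

Multi-year randomized-complete-block observations of plot-level flowering
percentage are modeled as

```
T_ijk = u + g_i + y_j + (gy)_ij + b_k(j) + e_ijk
```

with accession `i`, year `j`, block `k` nested in year. Single-year analyses
drop the year terms. The same linear decomposition underlies the ANOVA tables,
the variance-component estimators and the Gaussian self-check simulator
(`simulate_gaussian_trial`, which draws directly from this model so that
recovery tests have a known truth).

## ANOVA and Type III sums of squares

`anova_single_year` / `anova_multi_year` build sum-to-zero (Sum-contrast)
design matrices by hand and compute each term's Type III sum of squares as a
drop-term comparison: SS(term) = RSS(model without term) − RSS(full model),
with degrees of freedom from the corresponding rank difference. Under
balance this equals the sequential decomposition; for unbalanced data it
matches the conventional Type III tables produced by standard OLS software
(cross-checked against statsmodels in the test suite). Hand-built design
matrices keep the computation fast for factors with several hundred levels.
F tests use the residual mean square; significance stars follow the usual
0.001/0.01/0.05 legend with "NS" otherwise.

## Variance components

Two estimators are provided.

**Expected mean squares / method of moments** (`method="ems_mom"`, balanced
designs only) solves the classical EMS identities:

```
Ve  = MS_e
Vgy = (MS_gy − MS_e) / r
Vg  = (MS_g − MS_gy) / (r·y)
Vb  = (MS_b − MS_e) / a
Vy  = (MS_y − MS_gy − MS_b + MS_e) / (a·r)
```

Negative solutions are truncated to zero and recorded in the estimate's
`truncated` list rather than silently hidden.

**REML** (`method="reml"`). For balanced designs the restricted likelihood
factors exactly over the ANOVA strata:

```
−2·RLL = Σ_s [ df_s · log θ_s + SS_s / θ_s ]   (up to a constant)
```

where each stratum expectation θ_s is a known linear combination of the
variance components. This is optimized with L-BFGS-B on a squared
parameterization (which enforces nonnegativity) with an analytic gradient and
a warm start at the method-of-moments solution. Because balanced REML equals
the ANOVA estimators whenever those are interior (a classical result), the
two methods agree to machine precision on balanced data — the acceptance run
observes a maximum relative disagreement of ~2×10⁻¹⁶. Unbalanced designs
fall back to a generic Gaussian REML with the explicit n×n covariance,
Cholesky factorization and fixed effects profiled out; this is O(n³) and is
intended for the plot-count scales of real trials (hundreds to a few thousand
rows), not for arbitrarily large data.

`env_terms` selects how year and block enter: `"random"` (default) estimates
all five components; `"fixed"` absorbs year and block as fixed effects and
estimates only (Vg, Vgy, Ve). The fixed variant is what the recovery
benchmark uses, since truncation of a truly-zero Vy or Vb at the boundary
otherwise makes constrained REML and naive truncated moments differ slightly.

## Heritability

Entry-mean broad-sense heritability:

```
H²_single = Vg / (Vg + Ve/r)
H²_multi  = Vg / (Vg + Vgy/y + Ve/(y·r))
```

`h2_multi` requires y ≥ 2; both reject negative components and a zero
denominator. `HeritabilityEstimator` infers y and r from the data (r may be
overridden) and exposes the fitted components and H² as trailing-underscore
attributes in scikit-learn style.

## Estimated marginal means

`accession_emmeans` averages plots to (accession, year) cell means and then
averages the cell means with equal year weights. This equals the
least-squares (marginal) mean from a sum-to-zero OLS fit of the year factor
and, for balanced data, the raw mean — both equalities are tested. Accessions
missing from some years are kept (with a warning) unless filtered by
`min_years`.

## Trait ontology

EMMs are rounded to 4 decimals before comparison so that classification is
stable against sub-micropercent floating-point noise. The partition of
[0,100]² is total and disjoint by construction (verified exhaustively on a
0.5-step grid): biennial ⇔ emm100 = 0; annual ⇔ emm100 > t_high, subdivided
on emm60 (> t_high early, ≤ t_low late, otherwise non-uniform); everything
else is a mixture, *predominantly biennial* when both EMMs are ≤ t_low and
emm100 > 0. The baseline scheme uses only emm100 (0 / 100 / otherwise), and
both schemes provably call the same biennial set because both demand a
literal 0% at 100 DAS. Summary percentages are rendered at 2 decimals with
half-away-from-zero rounding (`round_half_away`), matching how such tables
are conventionally printed (e.g. 50/668 → 7.49).

## Phenotyping

The 5-point field scale supports two quantization policies: `"nearest"`
(round to the nearest of 0/25/50/75/100, ties away from zero) and `"detect"`
(any positive flowering fraction scores at least 25, reflecting scorers who
record presence before abundance). Senescence is flagged when an accession's
100 DAS score falls below its 60 DAS score. Outlier screening uses Rosner's
generalized ESD test with the standard critical values

```
λ_i = (n−i)·t_{p, n−i−1} / sqrt((n−i−1+t²)(n−i+1)),  p = 1 − α/(2(n−i+1))
```

declaring the largest `i` with R_i > λ_i outliers. The implementation is
hand-built (the reference implementation lives in an R-only package); the
test suite checks it against a literal textbook-formula oracle.

## Synthetic collections and trial realism

Each accession is a composition (p_early, p_late, p_biennial) over plant life
forms. `generate_collection` allocates category counts by largest-remainder
rounding of the requested mix, then rejection-samples Dirichlet draws until
the composition's noise-free expectation classifies into the requested
category; obligate biennials are the exact point (0, 0, 1). Trials draw each
plot's plant life forms from a multinomial, after perturbing the accession's
annual fraction on the logit scale by year, G×Y and block effects (0 and 1
are fixed points, so obligate biennials never flower and pure annuals always
do). Stand-loss events thin plants binomially with an optional bias against
early-flowering plants (mimicking poor-establishment years that overcount
biennials), and senescence removes a binomial fraction of early plants from
the 100 DAS count. Random streams are derived per plot from a SHA-256 hash of
(seed, accession, year, block), so results are independent of accession
ordering and fully reproducible.

Known limitations of the generator: plants are independent within a plot (no
spatial autocorrelation), environment effects act only through the annual
fraction's logit (no effect on flowering *timing* within annuals), and
quantization noise is the only measurement error. These simplifications keep
every moment checkable in closed form, which the property-based tests
exploit.

## Category recovery and quantization

Recovery benchmarks classify *unquantized* plot percentages. The 25-point
grain of the field scale cannot express the (0, 15] predominantly-biennial
band from noise-free plots — any small positive fraction scores 0 or 25
depending on policy — so quantized recovery of that subcategory is
structurally impossible, not an estimator failure. With unquantized
percentages, 200 plants per plot and compositions at least 2 percentage
points from every threshold, recovery is 100% in the acceptance run
(n = 317 eligible accessions at seed 1).

## Interfaces

Operations that are fit/predict/transform-shaped follow scikit-learn
conventions (`FloweringHabitClassifier`, `AccessionMarginalMeans`,
`VarianceComponentEstimator`, `HeritabilityEstimator`): constructor-only
hyperparameters, `clone`-compatible, fitted state in trailing-underscore
attributes. Module-level functions wrap them for one-line use. I/O is
schema-validated CSV/TSV with deterministic writers; the CLI records its
resolved configuration in `run_config.yaml` for every run.
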