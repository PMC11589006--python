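# Methods

This note documents the models implemented in `famvar`, the simulator
that exercises them, the numerical and inferential choices made where
the design was genuinely open, and what the validation experiments do
and do not establish.

## The multiplicative normal risk model

Risk is defined as age-specific log(incidence). A risk score is a
measured or latent predictor transformed, adjusted for age and
confounders, and standardized to mean 0 and SD 1 (the OPERA convention,
`valid.opera_standardize`, implemented as linear residualisation
followed by scaling; the fitted adjustment is retained so new
individuals can be scored on the construction-sample scale). Under the
multiplicative model the disease probability given score *x* is
proportional to exp(Δ·x), where Δ is the case–control difference in
mean score. Consequences used throughout:

* the score contributes Δ² to the variance of log incidence;
* a score correlated *r* within relative pairs induces a familial risk
  ratio FRR = exp(r·Δ²) (`frr_from_score` / `delta_from_frr`);
* case scores are the standard normal exponentially tilted by
  exp(Δ·x): mean Δ, SD 1 (in the rare-disease limit);
* with r = 1 (MZ twins, fully heritable score), familial variance is
  bounded by ln FRR_MZ and the AUC of any such score by
  Φ(√(ln FRR_MZ / 2)) (`max_auc`, `auc_from_delta`).

The simulator (`simulate_twin_pairs`) draws bivariate standard normal
scores with correlation *r* and Bernoulli outcomes with probability
p₀·exp(Δx − Δ²/2); the lognormal-mean identity makes the marginal
incidence exactly p₀. The model itself assigns probability > 1 to
sufficiently extreme scores (beyond x = (ln(1/p₀) + Δ²/2)/Δ). The
generator raises a hard error by default; `on_overflow="clip"`
truncates at 1 with a warning. At the validation conditions (p₀ = 0.01,
Δ ≤ 1.2, 10⁶ draws) the clipped excess mass is of order 10⁻⁷ of cases —
negligible against Monte-Carlo error but encountered often enough at
~5σ that large grids need the clip mode.

The empirical FRR estimator uses both orderings of each pair:
FRR̂ = ĉ/p̂² where ĉ is the concordant-affected pair fraction and p̂ the
marginal incidence; its standard error comes from the multivariate
delta method over the trinomial pair-outcome distribution.

## Variance decomposition by age group

`valid.decompose` takes a table of components (label, age group, Δ,
familial fraction, optional r_MZ/r_DZ metadata) and a total MZ FRR per
age group. Total familial variance per age group is ln FRR_MZ (the
unifying equation at r = 1); each component contributes
familial_fraction·Δ² familial and (1 − familial_fraction)·Δ²
nonfamilial variance, summed as if components were independent. The
residual unexplained familial variance is the total minus the sum,
floored at 0 with a warning when components overlap. Age enters only as
a grouping label — no smoothing across groups — and the module reports
familial vs nonfamilial only, not genetic vs shared-environment (the
r_MZ/r_DZ split needed for that is carried as metadata but no
separation formula is imposed). The packaged example table
(`famvar/data/example_components.csv`) is synthetic and illustrative:
it encodes the qualitative pattern of major genes dominating familial
variance at young ages, the polygenic component growing with age, a
partly familial mammographic component and mostly nonfamilial lifestyle
factors, with FRR_MZ declining from 5.0 to 1.9 across 10-year groups.

## Coefficient-change inference

Both procedures fit nested regressions of the outcome on the same rows
and compare a coefficient between its marginal and joint fits.

**Within-pair (ICE FALCON).** Every pair contributes both orderings
(each member once as index, once as co-relative); M1 regresses outcome
on own exposure, M2 on the co-relative's exposure, M3 on both.
Standard errors are cluster-robust over pairs, valid under arbitrary
within-pair correlation; the both-orderings construction is checked by
an exact A↔B symmetry test. Continuous outcomes use least squares,
binary outcomes the log-odds scale; no other links.

**Family-history (ICE CRISTAL).** For unrelated individuals the
co-relative's exposure is replaced by a binary family-history
indicator (counts are dichotomised at > 0 with a warning); the three
models are outcome on exposure, on family history, and on both, with
any covariates in every model.

**Uncertainty on changes.** Two routes:

* *Bootstrap* (default for the within-pair procedure): pairs (or
  individuals) resampled with replacement, the triplet refitted per
  replicate; percentile intervals and sign-flip two-sided p-values for
  change_cross, change_self and the attenuation difference. For linear
  outcomes the refits use per-cluster sufficient statistics
  (cross-product matrices weighted by multinomial counts), so B = 1000
  replicates cost milliseconds; logistic refits loop over replicates.
  Replicates that fail are dropped; > 5 % failures is an error.
* *Analytic* (default for the family-history procedure, the
  Freedman-style change test): the joint covariance of the nested fits
  is computed by stacking their estimating equations — for canonical
  GLMs, scores ψᵢ = xᵢ(yᵢ − μᵢ), bread X′WX, meat summed per cluster —
  giving Cov(θ̂ₐ, θ̂_b) = Aₐ⁻¹(Σ_c ψₐψ_b′)A_b⁻¹, from which each change
  and (by the delta method) the attenuation difference get normal-theory
  variances. The two routes agree on linear models at large n (tested).

A calibration caveat that shaped the validation design: the change
test's null hypothesis is "marginal coefficient = adjusted
coefficient". When *everything* is independent the change statistic is
a product of two vanishing estimates — second-order degenerate — and
its z-based p-value is not uniform. The null-calibration experiment
therefore uses a world where the exposure affects the outcome but is
independent of family history, the non-degenerate null for which the
test is designed; there the p-value is uniform (KS ≈ 0.04 over 200
replicates at n = 5000).

**Classification.** With significance level α (default 0.05):
no_association when neither marginal coefficient is significant;
consistent_with_causation when the cross (co-relative / family-history)
coefficient attenuates to the null — significant change, nonsignificant
adjusted value — while the self/exposure change is nonsignificant;
consistent_with_familial_confounding when both changes are significant
and (within-pair procedure only) their attenuation proportions do not
differ significantly; mixed (within-pair only) when both changes are
significant but to different extents; inconclusive otherwise. The
family-history classifier imposes no equal-extent condition because the
exposure and the dichotomised indicator live on different scales: under
pure confounding their attenuation proportions differ by construction
(covariance algebra on the generative model gives ≈ 0.29 vs ≈ 0.11 at
the default settings), so an equal-extent requirement would mislabel
confounded worlds.

**Reverse causation** is probed by exchanging the roles of exposure and
outcome and rerunning the full procedure.

## Structural-equation worlds

`simulate_pair_scenario` realises five linear structural models with
standard-normal sources (noise SDs configurable, default 1): *null*
(optionally correlated exposures, no outcome link), *causal* (exposures
bivariate normal with correlation ρₓ; Y = β·X_own + ε), *confounded*
(pair-shared factor F with loadings λₓ, λ_y on exposure and outcome; no
direct path), *reverse* (outcome liability first, correlated within
pair; X = β·Y + ε) and *mixed* (causal + confounder). Exactly the
parameters relevant to a kind may be nonzero, and zero-effect scenarios
reduce to the null generator. Closed-form regression coefficients from
the implied covariance matrices serve as oracles: e.g. causal
(β = 0.3, ρₓ = 0.6) gives marginal cross-pair slope 0.18 and joint
(0.3, 0); confounded (0.7/0.7, unit noise) gives marginal slopes
0.49/1.49 attenuating to 0.49/1.98 jointly.

`simulate_fh_cohort` gives each proband one latent first-degree
relative generated under the same structural model; the relative's
outcome dichotomised at its 0.8 sample quantile (≈ 20 % family-history
prevalence, configurable) defines the indicator. Outcomes are
continuous by default because the linear case has exact oracles; a
logistic-outcome route exists for both procedures.

The canonical recovery conditions are β = 0.3 with ρₓ = 0.6 (causal),
loadings 0.7/0.7 (confounded), and all effects zero (null), at 2000
pairs / 5000 individuals with B = 500 bootstrap replicates and 100
simulation replicates per scenario.

## Sliding-window region scan

Genotype panels: dosages 0/1/2 with allele frequencies uniform on a
configurable range (default 0.1–0.5) and block-wise linkage
disequilibrium by copy-with-mutation (within a block each variant
copies the previous one per sample, resampling from its own binomial
with probability 0.1; blocks of 10 variants by default). Phenotypes are
Bernoulli from a logistic model over centred planted dosages with
per-variant log odds ratios; the intercept sets the sampling prevalence
(default 0.5, a balanced case–control design). The canonical panel is
2000 samples × 500 variants with a 5-variant region of per-variant OR
1.4.

Each window of k consecutive variants (default k = 5, step 1) is scored

    sonar = (BIC_null − BIC_window) / (2·ln 10),

a BIC-approximated log₁₀ Bayes factor for the window's logistic model
over the intercept-only null on the same samples. This scoring is a
deliberately simple, fully specified stand-in for published
sliding-window log-odds scores whose internals are not public; it
should be read as "decisive evidence ≈ sonar ≥ 1 (10:1 posterior odds
under unit prior odds)". Missing genotypes are mean-imputed per
variant; monomorphic variants are dropped from a window's design (the
reported variant count reflects this); windows with unresolvable
separation are skipped with a warning. Windows live in variant-index
space with genomic coordinates from their first/last variant; calls
merge overlapping or abutting windows with sonar ≥ t (default t = 1)
and are exported as BED6 with score = round(1000·min(sonar,3)/3).

Under permuted phenotypes the k·ln(n) complexity penalty dominates
(mean sonar ≈ −7 at the canonical sizes), so the < 1 % false-window
criterion is met with large margin; the planted region at OR 1.4 per
variant yields likelihood-ratio signal far above the penalty and the
top window hit the planted region in 100/100 replicates.

## Reproducibility and problem sizes

All generators take integer seeds; experiment drivers derive
per-replicate substreams from a single top-level seed
(`evaluation.spawn_seeds`, values < 2³¹). Identical seeds give
byte-identical outputs. The validation experiments run at the study
conditions stated above — 5×10⁵ pairs per grid cell for the
unifying-equation and tilting checks, 100 classification replicates
per scenario, 100 panel replicates plus 50 phenotype permutations for
the scan — completing in a few minutes on one CPU.

## Limitations

* The simulator emulates idealised worlds: bivariate-normal scores,
  linear structural equations, a single latent relative, no
  ascertainment, no missingness (except optional genotype NaNs), no
  covariate structure unless supplied. Passing recovery tests shows the
  procedures recover their own generative assumptions, not that real
  cohorts satisfy them.
* No pedigrees beyond pairs plus one relative; no
  liability-threshold/tetrachoric modelling (deliberately — the
  multiplicative model is the point); no estimation of Δ or r from raw
  cohorts beyond OPERA standardization and case–control differences.
* The window model fits genotypes only: no covariates, relatedness
  correction, or parallelism.
* Correlated variance components are summed as if independent, with a
  floored residual and a warning rather than a covariance treatment.
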