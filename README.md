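# famvar

Statistical tools for family and twin studies of disease risk: how much
of the variation in risk is familial, how well any risk score could ever
discriminate, and whether an exposure–outcome association within
families reflects causation or familial confounding.

The package is aimed at genetic epidemiologists working with twin/
relative-pair cohorts, family-history data, and case–control genotype
panels. Everything is exercised against a built-in simulator with known
ground truth.

## What it implements

**VALID — variance in age-specific log incidence decomposition**
(`famvar.valid`). Under a multiplicative normal risk model, a risk
score standardized to unit variance (the OPERA convention: residualised
on age and confounders, divided by its SD) with case–control mean
difference Δ contributes Δ² to the variance of age-specific
log(incidence). A score correlated *r* within relative pairs induces a
familial risk ratio

    FRR = exp(r · Δ²)

so the MZ-twin FRR bounds the familial variance (ln FRR_MZ) and the best
achievable risk discrimination:

    AUC_max = Φ(√(ln FRR_MZ / 2))

`decompose` splits ln FRR_MZ per age group into named component
contributions (familial_fraction · Δ² each) plus an unexplained
residual, with a stacked-band plot.

**ICE FALCON** (`famvar.ice_falcon`). For pairs of relatives correlated
in their exposure, three regressions of an individual's outcome are
fitted: on the own exposure (M1), on the co-relative's exposure (M2),
and on both (M3), using both orderings of every pair with cluster-robust
uncertainty. A cross-pair coefficient that attenuates to the null while
the own-exposure coefficient is stable is consistent with causation;
both attenuating to the same extent is consistent with familial
confounding. Changes get pair-bootstrap (default) or analytic
joint-sandwich inference; `reverse_test` swaps exposure and outcome.

**ICE CRISTAL** (`famvar.ice_cristal`). The analogue for unrelated
individuals: the co-relative's exposure is replaced by a binary
family-history indicator, and the change in each coefficient between
marginal and joint fits is tested with a Freedman-style analytic
variance (joint sandwich of nested fits on shared rows), with an
individual-level bootstrap as cross-check.

**Region scan** (`famvar.region_scan`). A sliding window of k
consecutive variants is scored by a SONAR log₁₀-odds
`(BIC_null − BIC_window) / (2 ln 10)` comparing a multi-variant logistic
model against the intercept-only null; windows above threshold merge
into risk-region calls (TSV + BED6 output).

**Simulator** (`famvar.simulate`) and recovery experiments
(`famvar.evaluation`): twin pairs under the multiplicative model,
causal/confounded/reverse/null structural worlds, family-history
cohorts, and genotype panels with planted risk regions — all seeded and
byte-reproducible.

## Worked example

```python
from famvar import frr_from_score, max_auc
from famvar.simulate import SimScenario, simulate_pair_scenario
from famvar import ice_falcon

print(f"FRR = {frr_from_score(0.8, 0.5):.4f}")
print(f"max AUC = {max_auc(4.0):.4f}")

scenario = SimScenario(kind="causal", beta_causal=0.3, rho_x=0.6,
                       n_pairs=2000, seed=3)
pairs = simulate_pair_scenario(scenario)
report = ice_falcon.bootstrap_changes(pairs, B=500, seed=7)
print(report.summary())
```

prints

```
FRR = 1.3771
max AUC = 0.7975
Coefficient-change report (forward, bootstrap, n_pairs=2000)
  Model 1  beta_self   = +0.3023 (SE 0.0164)
  Model 2  beta_cotwin = +0.1904 (SE 0.0169)
  Model 3  beta_self   = +0.2907 (SE 0.0202)
  Model 3  beta_cotwin = +0.0197 (SE 0.0202)
  change_cotwin = +0.1708 [+0.1492, +0.1935] p=0.003992
  change_self   = +0.0115 [-0.0125, +0.0338] p=0.3194
  attenuation difference (cotwin - self) = +0.8586 p=0.003992
  classification: consistent_with_causation (alpha=0.05)
```

Reading it: a score with Δ = 0.8 correlated 0.5 in relatives gives a
familial risk ratio of 1.38; an MZ FRR of 4 caps any genetic score's AUC
at 0.80. In the simulated causal world (own-exposure effect 0.3,
within-pair exposure correlation 0.6) the marginal cross-pair
coefficient is ≈ 0.6 × 0.3 = 0.18, collapses to ≈ 0 once the own
exposure enters the model while the own-exposure coefficient stays at
≈ 0.3 — the signature of causation rather than familial confounding.

## Command line

Five subcommands mirror the library: `famvar simulate
pairs|scenario|fhcohort|genotypes`, `famvar valid decompose`, `famvar
icefalcon`, `famvar icecristal`, `famvar depth scan`. Every run writes a
JSON manifest (inputs, settings, seed, version) beside its outputs.

```bash
famvar simulate scenario --config causal.yaml --seed 3 --out pairs.csv
famvar icefalcon --pairs pairs.csv --boot 1000 --seed 7 --reverse --out falcon
famvar depth scan --vcf panel.vcf --pheno panel.pheno.tsv --k 5 --threshold 1 --out scan
```

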