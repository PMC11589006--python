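"""Generator correctness: marginal rates, known moments, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from cyvcf2 import VCF

from famvar.simulate import (
    GenotypePanelSpec,
    RiskModelParams,
    SimScenario,
    empirical_frr,
    pairs_to_wide,
    simulate_fh_cohort,
    simulate_genotype_panel,
    simulate_pair_scenario,
    simulate_panel_arrays,
    simulate_twin_pairs,
)


def twin_table(delta, r, p0=0.01, n=100_000, seed=1):
    return simulate_twin_pairs(
        RiskModelParams(delta=delta, r=r, baseline_incidence=p0, n_pairs=n, seed=seed)
    )


class TestTwinPairs:
    @pytest.mark.parametrize("delta,r", [(0.0, 0.5), (0.5, 0.25), (1.0, 1.0)])
    def test_marginal_incidence_matches_baseline(self, delta, r):
        """E[outcome] = p0 exactly under the lognormal normalisation."""
        p0, n = 0.01, 100_000
        table = twin_table(delta, r, p0, n)
        inc = table["outcome"].mean()
        se = math.sqrt(p0 * (1 - p0) / (2 * n))  # conservative: ignores pairing
        assert abs(inc - p0) < 3 * se * 1.5

    def test_no_score_effect_gives_unit_frr(self):
        table = twin_table(0.0, 0.5)
        frr, se = empirical_frr(table)
        assert abs(frr - 1.0) < 3 * se

    def test_frr_matches_unifying_equation(self):
        """Empirical FRR agrees with exp(r * delta^2) at delta=0.8, r=0.5."""
        table = twin_table(0.8, 0.5, n=500_000, seed=2)
        frr, se = empirical_frr(table)
        assert abs(frr - math.exp(0.5 * 0.64)) < 3 * se

    def test_case_scores_are_exponentially_tilted(self):
        """Cases' score mean ~= delta and SD ~= 1 in the rare-disease limit."""
        table = twin_table(0.8, 0.5, n=500_000, seed=3)
        cases = table.loc[table["outcome"] == 1, "exposure"].to_numpy()
        n = len(cases)
        sd = cases.std(ddof=1)
        assert abs(cases.mean() - 0.8) < 3 * sd / math.sqrt(n)
        assert abs(sd - 1.0) < 3 / math.sqrt(2 * (n - 1))

    def test_probability_overflow_raises(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            twin_table(3.0, 0.5, p0=0.5, n=10_000)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r": 1.5},
            {"baseline_incidence": 0.0},
            {"baseline_incidence": 1.0},
            {"delta": float("nan")},
            {"n_pairs": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        base = dict(delta=0.5, r=0.5, baseline_incidence=0.01, n_pairs=100, seed=0)
        with pytest.raises(ValueError):
            RiskModelParams(**{**base, **kwargs})

    def test_same_seed_byte_identical_distinct_seed_differs(self):
        a = twin_table(0.5, 0.5, n=1000, seed=42)
        b = twin_table(0.5, 0.5, n=1000, seed=42)
        c = twin_table(0.5, 0.5, n=1000, seed=43)
        assert a.to_csv() == b.to_csv()
        assert not a["exposure"].equals(c["exposure"])


class TestPairScenarios:
    def test_null_has_no_associations(self):
        table = simulate_pair_scenario(SimScenario(kind="null", n_pairs=10_000, seed=5))
        wide = pairs_to_wide(table)
        for xcol in ("exposure_A", "exposure_B"):
            for ycol in ("outcome_A", "outcome_B"):
                r = np.corrcoef(wide[xcol], wide[ycol])[0, 1]
                assert abs(r) < 3.5 / math.sqrt(len(wide))

    def test_causal_with_zero_effect_equals_null_generator(self):
        """With every effect parameter 0 the scenarios share one stream."""
        null = simulate_pair_scenario(
            SimScenario(kind="null", rho_x=0.6, n_pairs=500, seed=9)
        )
        causal0 = simulate_pair_scenario(
            SimScenario(kind="causal", beta_causal=0.0, rho_x=0.6, n_pairs=500, seed=9)
        )
        pd.testing.assert_frame_equal(null, causal0)

    def test_causal_cross_pair_slope_matches_path_tracing(self):
        """Marginal slope of Y_A on X_B is rho_x * beta; conditional ~ 0."""
        sc = SimScenario(kind="causal", beta_causal=0.3, rho_x=0.6,
                         n_pairs=50_000, seed=6)
        wide = pairs_to_wide(simulate_pair_scenario(sc))
        xa = wide["exposure_A"].to_numpy()
        xb = wide["exposure_B"].to_numpy()
        ya = wide["outcome_A"].to_numpy()
        marg = np.polyfit(xb, ya, 1)[0]
        assert marg == pytest.approx(0.18, abs=0.02)
        X = np.column_stack([np.ones_like(xa), xa, xb])
        joint = np.linalg.lstsq(X, ya, rcond=None)[0]
        assert joint[2] == pytest.approx(0.0, abs=0.02)
        assert joint[1] == pytest.approx(0.3, abs=0.02)

    def test_confounded_slopes_match_covariance_algebra(self):
        """Loadings 0.7/0.7, unit noise: marginal 0.49/1.49, joint 0.49/1.98."""
        sc = SimScenario(kind="confounded", confounder_loading_x=0.7,
                         confounder_loading_y=0.7, n_pairs=50_000, seed=7)
        wide = pairs_to_wide(simulate_pair_scenario(sc))
        xa = wide["exposure_A"].to_numpy()
        xb = wide["exposure_B"].to_numpy()
        ya = wide["outcome_A"].to_numpy()
        marg_self = np.polyfit(xa, ya, 1)[0]
        marg_cross = np.polyfit(xb, ya, 1)[0]
        assert marg_self == pytest.approx(0.49 / 1.49, abs=0.02)
        assert marg_cross == pytest.approx(0.49 / 1.49, abs=0.02)
        X = np.column_stack([np.ones_like(xa), xa, xb])
        joint = np.linalg.lstsq(X, ya, rcond=None)[0]
        plateau = 0.49 / (1.49 + 0.49)
        assert joint[1] == pytest.approx(plateau, abs=0.02)
        assert joint[2] == pytest.approx(plateau, abs=0.02)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario kind"):
            SimScenario(kind="sideways", n_pairs=10, seed=0)

    def test_irrelevant_parameters_rejected(self):
        with pytest.raises(ValueError, match="loadings must be zero"):
            SimScenario(kind="causal", beta_causal=0.3, confounder_loading_x=0.5,
                        n_pairs=10, seed=0)


class TestFHCohort:
    def test_null_cohort_mutually_independent(self):
        table = simulate_fh_cohort(10_000, "null", seed=8, rho_x=0.6)
        n = len(table)
        for a, b in [("exposure", "outcome"), ("exposure", "family_history"),
                     ("outcome", "family_history")]:
            r = np.corrcoef(table[a], table[b])[0, 1]
            assert abs(r) < 3.5 / math.sqrt(n)

    def test_fh_prevalence_follows_quantile(self):
        table = simulate_fh_cohort(5000, "null", seed=8, fh_quantile=0.8)
        assert table["family_history"].mean() == pytest.approx(0.2, abs=0.02)

    def test_causal_cohort_fh_attenuates_exposure_stable(self):
        """Covariance algebra: adjusted fh slope is 0, exposure slope beta."""
        table = simulate_fh_cohort(50_000, "causal", seed=9, beta_causal=0.3,
                                   rho_x=0.6)
        x = table["exposure"].to_numpy()
        f = table["family_history"].to_numpy().astype(float)
        y = table["outcome"].to_numpy()
        marg_fh = np.polyfit(f, y, 1)[0]
        X = np.column_stack([np.ones_like(x), x, f])
        joint = np.linalg.lstsq(X, y, rcond=None)[0]
        assert marg_fh > 0.05
        assert joint[2] == pytest.approx(0.0, abs=0.02)
        assert joint[1] == pytest.approx(0.3, abs=0.02)


class TestGenotypePanel:
    def test_vcf_round_trips_through_cyvcf2(self, small_panel_spec, small_panel_files):
        vcf_path, pheno_path = small_panel_files
        panel = simulate_panel_arrays(small_panel_spec)
        vcf = VCF(str(vcf_path))
        assert list(vcf.samples) == panel["samples"]
        doses = []
        for v in vcf:
            gt = np.asarray(v.gt_types, dtype=float)
            doses.append(np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2]))
        vcf.close()
        np.testing.assert_array_equal(np.vstack(doses).T, panel["genotypes"])
        pheno = pd.read_csv(pheno_path, sep="\t", header=None)
        np.testing.assert_array_equal(pheno[1].to_numpy(), panel["status"])

    def test_no_planted_region_gives_independent_phenotype(self):
        spec = GenotypePanelSpec(n_samples=4000, n_variants=10, seed=21)
        panel = simulate_panel_arrays(spec)
        y = panel["status"].astype(float)
        for j in range(10):
            r = np.corrcoef(panel["genotypes"][:, j], y)[0, 1]
            assert abs(r) < 4 / math.sqrt(spec.n_samples)

    def test_ld_block_size_one_gives_uncorrelated_neighbours(self):
        spec = GenotypePanelSpec(n_samples=4000, n_variants=20, seed=22,
                                 ld_block_size=1)
        geno = simulate_panel_arrays(spec)["genotypes"].astype(float)
        corrs = [np.corrcoef(geno[:, j], geno[:, j + 1])[0, 1] for j in range(19)]
        assert np.max(np.abs(corrs)) < 4 / math.sqrt(spec.n_samples)

    def test_ld_blocks_correlate_neighbours(self, small_panel_spec):
        geno = simulate_panel_arrays(small_panel_spec)["genotypes"].astype(float)
        within = np.corrcoef(geno[:, 11], geno[:, 12])[0, 1]
        assert within > 0.5

    def test_planted_region_bounds_checked(self):
        with pytest.raises(ValueError, match="planted_region"):
            GenotypePanelSpec(n_samples=10, n_variants=5, seed=0,
                              planted_region=(3, 7))


def test_pairs_to_wide_drops_incomplete_pairs():
    table = simulate_pair_scenario(SimScenario(kind="null", n_pairs=50, seed=1))
    table = table.drop(index=table.index[0])  # orphan one member
    with pytest.warns(UserWarning, match="dropped 1 pairs"):
        wide = pairs_to_wide(table)
    assert len(wide) == 49
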