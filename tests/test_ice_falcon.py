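"""Three-model within-pair procedure: oracles, bootstrap, classification."""

import json

import numpy as np
import pandas as pd
import pytest

from famvar import ice_falcon
from famvar._inference import classify_changes
from famvar.simulate import RiskModelParams, SimScenario, simulate_pair_scenario, \
    simulate_twin_pairs


@pytest.fixture(scope="module")
def causal_pairs():
    return simulate_pair_scenario(
        SimScenario(kind="causal", beta_causal=0.3, rho_x=0.6,
                    n_pairs=2000, seed=100)
    )


@pytest.fixture(scope="module")
def confounded_pairs():
    return simulate_pair_scenario(
        SimScenario(kind="confounded", confounder_loading_x=0.7,
                    confounder_loading_y=0.7, n_pairs=2000, seed=101)
    )


@pytest.fixture(scope="module")
def null_pairs():
    return simulate_pair_scenario(
        SimScenario(kind="null", rho_x=0.6, n_pairs=2000, seed=102)
    )


class TestFitTriplet:
    def test_null_coefficients_near_zero(self, null_pairs):
        t = ice_falcon.fit_triplet(null_pairs)
        for beta, se in [
            (t.beta_self_m1, t.se_self_m1), (t.beta_cotwin_m2, t.se_cotwin_m2),
            (t.beta_self_m3, t.se_self_m3), (t.beta_cotwin_m3, t.se_cotwin_m3),
        ]:
            assert abs(beta) < 3.5 * se

    def test_causal_coefficients_match_structural_oracle(self):
        """Path tracing: marginal cross = rho*beta, joint cross = 0, self = beta."""
        pairs = simulate_pair_scenario(
            SimScenario(kind="causal", beta_causal=0.3, rho_x=0.6,
                        n_pairs=30_000, seed=103)
        )
        t = ice_falcon.fit_triplet(pairs)
        assert t.beta_cotwin_m2 == pytest.approx(0.18, abs=3 * t.se_cotwin_m2)
        assert t.beta_cotwin_m3 == pytest.approx(0.0, abs=3 * t.se_cotwin_m3)
        assert t.beta_self_m3 == pytest.approx(0.3, abs=3 * t.se_self_m3)

    def test_confounded_attenuations_equal(self):
        """Covariance algebra: both coefficients drop 0.329 -> 0.247."""
        pairs = simulate_pair_scenario(
            SimScenario(kind="confounded", confounder_loading_x=0.7,
                        confounder_loading_y=0.7, n_pairs=30_000, seed=104)
        )
        t = ice_falcon.fit_triplet(pairs)
        marginal, plateau = 0.49 / 1.49, 0.49 / 1.98
        assert t.beta_self_m1 == pytest.approx(marginal, abs=3 * t.se_self_m1)
        assert t.beta_cotwin_m2 == pytest.approx(marginal, abs=3 * t.se_cotwin_m2)
        assert t.beta_self_m3 == pytest.approx(plateau, abs=3 * t.se_self_m3)
        assert t.beta_cotwin_m3 == pytest.approx(plateau, abs=3 * t.se_cotwin_m3)

    def test_member_label_swap_leaves_estimates_unchanged(self, causal_pairs):
        swapped = causal_pairs.copy()
        swapped["member"] = swapped["member"].map({"A": "B", "B": "A"})
        t1 = ice_falcon.fit_triplet(causal_pairs)
        t2 = ice_falcon.fit_triplet(swapped)
        assert t1.beta_self_m1 == pytest.approx(t2.beta_self_m1, rel=1e-10)
        assert t1.beta_cotwin_m3 == pytest.approx(t2.beta_cotwin_m3, rel=1e-10)

    def test_too_few_pairs_rejected(self, causal_pairs):
        small = causal_pairs[causal_pairs["pair_id"] < 10]
        with pytest.raises(ValueError, match="at least 30"):
            ice_falcon.fit_triplet(small)

    def test_binary_outcome_fits_on_log_odds_scale(self):
        pairs = simulate_twin_pairs(
            RiskModelParams(delta=0.5, r=0.5, baseline_incidence=0.05,
                            n_pairs=5000, seed=105)
        )
        t = ice_falcon.fit_triplet(pairs, outcome_family="binary")
        # rare disease: log-OR per SD of the score is close to delta
        assert t.beta_self_m1 == pytest.approx(0.5, abs=3.5 * t.se_self_m1)

    def test_one_class_binary_outcome_rejected(self, causal_pairs):
        pairs = causal_pairs.copy()
        pairs["outcome"] = 0.0
        with pytest.raises(ValueError, match="both classes"):
            ice_falcon.fit_triplet(pairs, outcome_family="binary")


class TestBootstrap:
    def test_identical_seed_identical_report(self, causal_pairs):
        r1 = ice_falcon.bootstrap_changes(causal_pairs, B=300, seed=1)
        r2 = ice_falcon.bootstrap_changes(causal_pairs, B=300, seed=1)
        assert r1.to_json() == r2.to_json()

    def test_causal_intervals(self, causal_pairs):
        """Cross-pair change excludes 0; within-individual change includes it."""
        rep = ice_falcon.bootstrap_changes(causal_pairs, B=500, seed=2)
        assert rep.ci_change_cotwin[0] > 0
        assert rep.ci_change_self[0] < 0 < rep.ci_change_self[1]
        assert rep.classification == "consistent_with_causation"

    def test_confounded_attenuation_difference_includes_zero(self, confounded_pairs):
        rep = ice_falcon.bootstrap_changes(confounded_pairs, B=500, seed=3)
        assert rep.p_change_cotwin < 0.05
        assert rep.p_change_self < 0.05
        assert rep.ci_attenuation_diff[0] < 0 < rep.ci_attenuation_diff[1]
        assert rep.classification == "consistent_with_familial_confounding"

    def test_null_not_causal(self, null_pairs):
        rep = ice_falcon.bootstrap_changes(null_pairs, B=300, seed=4)
        assert rep.classification == "no_association"

    def test_analytic_agrees_with_bootstrap_on_linear_models(self, causal_pairs):
        boot = ice_falcon.bootstrap_changes(causal_pairs, B=500, seed=5)
        ana = ice_falcon.analytic_changes(causal_pairs)
        width = lambda ci: ci[1] - ci[0]
        assert width(ana.ci_change_cotwin) == pytest.approx(
            width(boot.ci_change_cotwin), rel=0.3
        )
        assert ana.classification == boot.classification

    def test_too_few_replicates_rejected(self, causal_pairs):
        with pytest.raises(ValueError, match="at least 200"):
            ice_falcon.bootstrap_changes(causal_pairs, B=50, seed=0)

    def test_binary_outcome_bootstrap(self):
        pairs = simulate_twin_pairs(
            RiskModelParams(delta=0.5, r=0.5, baseline_incidence=0.1,
                            n_pairs=800, seed=106)
        )
        rep = ice_falcon.bootstrap_changes(pairs, B=200, seed=6,
                                           outcome_family="binary")
        assert rep.n_failed <= 10
        assert np.isfinite(rep.change_cotwin)


class TestClassificationRules:
    SIG, NS = 0.001, 0.5

    def label(self, **kw):
        base = dict(p_marginal_self=self.SIG, p_marginal_cross=self.SIG,
                    p_change_self=self.NS, p_change_cross=self.SIG,
                    p_adjusted_cross=self.NS, p_attenuation_diff=self.NS)
        return classify_changes(**{**base, **kw})

    def test_causation_pattern(self):
        assert self.label() == "consistent_with_causation"

    def test_no_association(self):
        assert self.label(p_marginal_self=self.NS, p_marginal_cross=self.NS) \
            == "no_association"

    def test_confounding_pattern(self):
        assert self.label(p_change_self=self.SIG) \
            == "consistent_with_familial_confounding"

    def test_mixed_pattern(self):
        assert self.label(p_change_self=self.SIG, p_attenuation_diff=self.SIG) \
            == "mixed"

    def test_inconclusive_when_cross_persists(self):
        assert self.label(p_adjusted_cross=self.SIG) == "inconclusive"

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            self.label_with_alpha = classify_changes(
                p_marginal_self=0.5, p_marginal_cross=0.5, p_change_self=0.5,
                p_change_cross=0.5, p_adjusted_cross=0.5,
                p_attenuation_diff=0.5, alpha=1.5,
            )


class TestReverse:
    def test_causal_data_forward_causal_reverse_not(self, causal_pairs):
        fwd = ice_falcon.bootstrap_changes(causal_pairs, B=300, seed=7)
        rev = ice_falcon.reverse_test(causal_pairs, B=300, seed=7)
        assert fwd.classification == "consistent_with_causation"
        assert rev.classification != "consistent_with_causation"
        assert rev.direction == "reverse"

    def test_reverse_scenario_mirrored(self):
        pairs = simulate_pair_scenario(
            SimScenario(kind="reverse", beta_causal=0.3, rho_x=0.6,
                        n_pairs=2000, seed=107)
        )
        fwd = ice_falcon.bootstrap_changes(pairs, B=300, seed=8)
        rev = ice_falcon.reverse_test(pairs, B=300, seed=8)
        assert rev.classification == "consistent_with_causation"
        assert fwd.classification != "consistent_with_causation"


def test_report_json_parseable(causal_pairs):
    rep = ice_falcon.bootstrap_changes(causal_pairs, B=300, seed=9)
    decoded = json.loads(rep.to_json())
    assert decoded["classification"] == rep.classification
    assert decoded["triplet"]["n_pairs"] == 2000
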