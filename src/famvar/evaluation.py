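"""Recovery experiments validating the methods against simulated truth.

Each experiment generates data from :mod:`famvar.simulate` under known
parameters, runs the corresponding method, and summarises how well the
truth is recovered: the unifying-equation and maximum-AUC checks for the
variance model, scenario-classification rates for the two
coefficient-change procedures, and planted-region recovery plus the
permutation null for the sliding-window scan. These are the package's
own validation suite; the test suite and the acceptance script both run
them.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd
from scipy.stats import kstest, mannwhitneyu

from famvar import ice_cristal, ice_falcon
from famvar.region_scan import scan_matrix
from famvar.simulate import (
    GenotypePanelSpec,
    RiskModelParams,
    SimScenario,
    empirical_frr,
    simulate_fh_cohort,
    simulate_pair_scenario,
    simulate_panel_arrays,
    simulate_twin_pairs,
)
from famvar.valid import auc_from_delta, delta_from_frr, frr_from_score, max_auc

__all__ = [
    "spawn_seeds",
    "frr_grid_experiment",
    "max_auc_experiment",
    "auc_identity_max_error",
    "case_tilting_experiment",
    "falcon_scenario",
    "falcon_recovery",
    "cristal_scenario_table",
    "cristal_recovery",
    "cristal_null_pvalues",
    "region_recovery",
    "region_null_rate",
]

# Canonical study conditions for the scenario-recovery experiments.
CAUSAL_BETA = 0.3
CAUSAL_RHO_X = 0.6
CONFOUNDER_LOADING = 0.7


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-component substream seeds below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


# ---------------------------------------------------------------------------
# unifying equation, maximum AUC, case tilting


def frr_grid_experiment(
    n_pairs: int = 500_000,
    p0: float = 0.01,
    r_values=(0.0, 0.25, 0.5, 1.0),
    delta_values=(0.0, 0.5, 0.8, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical vs theoretical FRR over a (r, delta) grid.

    One simulation per cell; the ``z`` column is the discrepancy between
    the empirical familial risk ratio and ``exp(r * delta**2)`` in units
    of the estimator's Monte-Carlo standard error.
    """
    seeds = iter(spawn_seeds(seed, len(r_values) * len(delta_values)))
    rows = []
    for r in r_values:
        for delta in delta_values:
            params = RiskModelParams(
                delta=delta, r=r, baseline_incidence=p0,
                n_pairs=n_pairs, seed=next(seeds),
            )
            pairs = simulate_twin_pairs(params, on_overflow="clip")
            frr, se = empirical_frr(pairs)
            theory = frr_from_score(delta, r)
            rows.append(
                {
                    "r": r,
                    "delta": delta,
                    "frr_empirical": frr,
                    "frr_se": se,
                    "frr_theory": theory,
                    "z": (frr - theory) / se,
                }
            )
    table = pd.DataFrame(rows)
    table["within_3se"] = table["z"].abs() <= 3.0
    return table


def max_auc_experiment(
    frr_mz: float = 4.0,
    n_pairs: int = 500_000,
    p0: float = 0.01,
    seed: int = 0,
) -> dict:
    """Empirical AUC of the risk score versus the maximum-AUC bound.

    Simulates MZ pairs (r = 1) with delta chosen so the theoretical FRR
    equals ``frr_mz``, then measures the Mann-Whitney AUC of the score
    for cases versus controls across all individuals.
    """
    delta = delta_from_frr(frr_mz, 1.0)
    params = RiskModelParams(
        delta=delta, r=1.0, baseline_incidence=p0, n_pairs=n_pairs, seed=seed
    )
    pairs = simulate_twin_pairs(params, on_overflow="clip")
    scores = pairs["exposure"].to_numpy()
    cases = pairs["outcome"].to_numpy() == 1
    u = mannwhitneyu(scores[cases], scores[~cases], alternative="two-sided")
    auc = u.statistic / (cases.sum() * (~cases).sum())
    return {
        "delta": delta,
        "auc_empirical": float(auc),
        "auc_theory": max_auc(frr_mz),
        "n_cases": int(cases.sum()),
    }


def auc_identity_max_error(frr_values=None) -> float:
    """Max |auc_from_delta(delta_from_frr(f, 1)) - max_auc(f)| over a grid."""
    if frr_values is None:
        frr_values = np.linspace(1.0, 100.0, 991)
    errs = [
        abs(auc_from_delta(delta_from_frr(f, 1.0)) - max_auc(f)) for f in frr_values
    ]
    return float(max(errs))


def case_tilting_experiment(
    delta: float = 0.8,
    r: float = 0.5,
    p0: float = 0.01,
    n_pairs: int = 500_000,
    seed: int = 0,
) -> dict:
    """Mean and SD of the standardized score among simulated cases.

    In the rare-disease limit the case score distribution is the
    standard normal exponentially tilted by ``exp(delta * x)``: mean
    ``delta``, SD 1.
    """
    params = RiskModelParams(
        delta=delta, r=r, baseline_incidence=p0, n_pairs=n_pairs, seed=seed
    )
    pairs = simulate_twin_pairs(params, on_overflow="clip")
    case_scores = pairs.loc[pairs["outcome"] == 1, "exposure"].to_numpy()
    n = len(case_scores)
    sd = float(case_scores.std(ddof=1))
    return {
        "case_mean": float(case_scores.mean()),
        "case_mean_se": sd / math.sqrt(n),
        "case_sd": sd,
        "case_sd_se": sd / math.sqrt(2.0 * (n - 1)),
        "n_cases": n,
    }


# ---------------------------------------------------------------------------
# scenario recovery for the coefficient-change procedures


def falcon_scenario(kind: str, n_pairs: int, seed: int) -> SimScenario:
    """The canonical generative world used in the recovery experiments."""
    if kind == "causal":
        return SimScenario(kind="causal", beta_causal=CAUSAL_BETA,
                           rho_x=CAUSAL_RHO_X, n_pairs=n_pairs, seed=seed)
    if kind == "confounded":
        return SimScenario(kind="confounded",
                           confounder_loading_x=CONFOUNDER_LOADING,
                           confounder_loading_y=CONFOUNDER_LOADING,
                           n_pairs=n_pairs, seed=seed)
    if kind == "reverse":
        return SimScenario(kind="reverse", beta_causal=CAUSAL_BETA,
                           rho_x=CAUSAL_RHO_X, n_pairs=n_pairs, seed=seed)
    if kind == "null":
        return SimScenario(kind="null", rho_x=CAUSAL_RHO_X,
                           n_pairs=n_pairs, seed=seed)
    raise ValueError(f"no canonical scenario for kind {kind!r}")


def falcon_recovery(
    kind: str,
    n_reps: int = 100,
    n_pairs: int = 2000,
    B: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Classification rates of the within-pair procedure over replicates."""
    seeds = spawn_seeds(seed, 2 * n_reps)
    labels = Counter()
    for i in range(n_reps):
        scenario = falcon_scenario(kind, n_pairs, seeds[2 * i])
        pairs = simulate_pair_scenario(scenario)
        report = ice_falcon.bootstrap_changes(
            pairs, B=B, seed=seeds[2 * i + 1], alpha=alpha
        )
        labels[report.classification] += 1
    return {
        "kind": kind,
        "n_reps": n_reps,
        "labels": dict(labels),
        "fractions": {k: v / n_reps for k, v in labels.items()},
    }


def cristal_scenario_table(kind: str, n: int, seed: int) -> pd.DataFrame:
    """A family-history cohort under the canonical generative world."""
    if kind == "causal":
        return simulate_fh_cohort(n, "causal", seed, beta_causal=CAUSAL_BETA,
                                  rho_x=CAUSAL_RHO_X)
    if kind == "confounded":
        return simulate_fh_cohort(n, "confounded", seed,
                                  confounder_loading_x=CONFOUNDER_LOADING,
                                  confounder_loading_y=CONFOUNDER_LOADING)
    if kind == "null":
        return simulate_fh_cohort(n, "null", seed, rho_x=CAUSAL_RHO_X)
    raise ValueError(f"no canonical cohort for kind {kind!r}")


def cristal_recovery(
    kind: str,
    n_reps: int = 100,
    n: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Classification rates of the family-history procedure."""
    seeds = spawn_seeds(seed, n_reps)
    labels = Counter()
    for i in range(n_reps):
        table = cristal_scenario_table(kind, n, seeds[i])
        report = ice_cristal.fit_fh_models(table, alpha=alpha)
        labels[report.classification] += 1
    return {
        "kind": kind,
        "n_reps": n_reps,
        "labels": dict(labels),
        "fractions": {k: v / n_reps for k, v in labels.items()},
    }


def cristal_null_pvalues(
    n_reps: int = 200,
    n: int = 5000,
    seed: int = 0,
) -> dict:
    """Null distribution of the analytic change p-value.

    The change test's null is "marginal equals adjusted coefficient",
    which holds when the exposure is independent of family history. The
    calibration world therefore keeps a real exposure→outcome effect but
    makes the relative's exposure (hence family history) independent of
    the proband (``rho_x = 0``): the coefficient change is then an
    asymptotically normal zero-mean statistic and its p-value should be
    uniform. (A fully null world is degenerate for this test: the change
    is a product of two vanishing estimates and the z-approximation does
    not apply.) Returns the p-values and their Kolmogorov–Smirnov
    distance from Uniform(0, 1).
    """
    seeds = spawn_seeds(seed, n_reps)
    pvals = []
    for i in range(n_reps):
        table = simulate_fh_cohort(n, "causal", seeds[i],
                                   beta_causal=CAUSAL_BETA, rho_x=0.0)
        _, p = ice_cristal.freedman_test(table, which="fh")
        pvals.append(p)
    pvals = np.asarray(pvals)
    ks = kstest(pvals, "uniform").statistic
    return {"pvalues": pvals, "ks_distance": float(ks), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# region-scan recovery


def default_panel_spec(seed: int, planted: bool = True) -> GenotypePanelSpec:
    """The canonical panel: 2000 samples, 500 variants, 5-variant region."""
    return GenotypePanelSpec(
        n_samples=2000,
        n_variants=500,
        seed=seed,
        planted_region=(200, 204) if planted else None,
        causal_log_or=math.log(1.4) if planted else 0.0,
    )


def region_recovery(
    n_reps: int = 100,
    seed: int = 0,
    k: int = 5,
    step: int = 1,
    spec_factory=default_panel_spec,
) -> dict:
    """Fraction of replicates whose top-sonar window overlaps the truth."""
    seeds = spawn_seeds(seed, n_reps)
    hits = 0
    for i in range(n_reps):
        spec = spec_factory(seeds[i])
        panel = simulate_panel_arrays(spec)
        scores = scan_matrix(
            panel["genotypes"], panel["status"], positions=panel["positions"],
            chrom=panel["chrom"], k=k, step=step,
        )
        best = scores.loc[scores["sonar"].idxmax()]
        start, end = spec.planted_region
        planted_lo = panel["positions"][start]
        planted_hi = panel["positions"][end]
        if best["start"] <= planted_hi and best["end"] >= planted_lo:
            hits += 1
    return {"n_reps": n_reps, "hits": hits, "overlap_fraction": hits / n_reps}


def region_null_rate(
    n_perms: int = 50,
    seed: int = 0,
    k: int = 5,
    step: int = 1,
    sonar_threshold: float = 1.0,
    spec_factory=default_panel_spec,
) -> dict:
    """Fraction of windows exceeding a sonar threshold under permutation.

    The phenotype is randomly permuted (breaking any genotype association
    while preserving its marginal distribution) and all windows rescanned.
    """
    spec = spec_factory(seed)
    panel = simulate_panel_arrays(spec)
    rng = np.random.default_rng(seed + 1)
    exceed = total = 0
    sonar_all = []
    for _ in range(n_perms):
        y_perm = rng.permutation(panel["status"])
        scores = scan_matrix(
            panel["genotypes"], y_perm, positions=panel["positions"],
            chrom=panel["chrom"], k=k, step=step,
        )
        exceed += int((scores["sonar"] > sonar_threshold).sum())
        total += len(scores)
        sonar_all.append(scores["sonar"].to_numpy())
    return {
        "n_perms": n_perms,
        "n_windows": total,
        "n_exceed": exceed,
        "exceed_fraction": exceed / total,
        "mean_sonar": float(np.concatenate(sonar_all).mean()),
    }
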