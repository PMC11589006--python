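"""Inference about causation from examining familial confounding.

The procedure applies to pairs of relatives correlated in their
exposure. Three regressions of an individual's outcome are fitted:

* Model 1 — on the individual's own exposure,
* Model 2 — on the co-relative's exposure,
* Model 3 — on both together.

Every pair contributes both orderings (each member once as index, once
as co-relative), and uncertainty is cluster-robust over pairs.
Inference is made by comparing the changes in the pair of regression
coefficients between the marginal and joint models: a cross-pair
coefficient that attenuates to the null while the within-individual
coefficient is stable is consistent with causation; both coefficients
attenuating to the same extent is consistent with familial confounding.
Reverse causation is probed by exchanging the roles of exposure and
outcome.

Uncertainty on the coefficient changes comes from a pair-level
nonparametric bootstrap by default; a fast analytic alternative based on
the joint sandwich covariance of the three fits is also provided.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from famvar._inference import (
    GLMFit,
    bootstrap_percentile_p,
    classify_changes,
    fit_glm,
    joint_sandwich,
    two_sided_p,
)
from famvar.simulate import pairs_to_wide

__all__ = [
    "ModelTriplet",
    "CoefficientChangeReport",
    "fit_triplet",
    "bootstrap_changes",
    "analytic_changes",
    "classify",
    "reverse_test",
]

MIN_PAIRS = 30


@dataclass
class ModelTriplet:
    """Coefficients of the three-model fit with cluster-robust errors."""

    beta_self_m1: float
    se_self_m1: float
    p_self_m1: float
    beta_cotwin_m2: float
    se_cotwin_m2: float
    p_cotwin_m2: float
    beta_self_m3: float
    se_self_m3: float
    p_self_m3: float
    beta_cotwin_m3: float
    se_cotwin_m3: float
    p_cotwin_m3: float
    outcome_family: str
    n_pairs: int
    _fits: list[GLMFit] = field(default=None, repr=False, compare=False)
    _groups: np.ndarray = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_fits"), d.pop("_groups")
        return d


@dataclass
class CoefficientChangeReport:
    """Coefficient changes, their uncertainty, and the scenario label.

    ``change_cotwin = beta_cotwin_m2 - beta_cotwin_m3`` and
    ``change_self = beta_self_m1 - beta_self_m3``; attenuation
    proportions divide each change by its marginal coefficient and
    ``attenuation_diff`` is their difference (cotwin minus self).
    Intervals are percentile bootstrap (or normal-theory for the
    analytic route) at level ``1 - alpha``.
    """

    triplet: ModelTriplet
    change_cotwin: float
    change_self: float
    attenuation_cotwin: float
    attenuation_self: float
    attenuation_diff: float
    ci_change_cotwin: tuple[float, float]
    ci_change_self: tuple[float, float]
    ci_attenuation_diff: tuple[float, float]
    p_change_cotwin: float
    p_change_self: float
    p_attenuation_diff: float
    classification: str
    alpha: float
    n_pairs: int
    n_boot: int
    n_failed: int
    seed: int | None
    method: str  # "bootstrap" or "analytic"
    direction: str = "forward"

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["triplet"] = self.triplet.to_dict()
        return json.dumps(d, indent=kwargs.pop("indent", 2), default=float, **kwargs)

    def summary(self) -> str:
        t = self.triplet
        lines = [
            f"Coefficient-change report ({self.direction}, {self.method}, "
            f"n_pairs={self.n_pairs})",
            f"  Model 1  beta_self   = {t.beta_self_m1:+.4f} (SE {t.se_self_m1:.4f})",
            f"  Model 2  beta_cotwin = {t.beta_cotwin_m2:+.4f} (SE {t.se_cotwin_m2:.4f})",
            f"  Model 3  beta_self   = {t.beta_self_m3:+.4f} (SE {t.se_self_m3:.4f})",
            f"  Model 3  beta_cotwin = {t.beta_cotwin_m3:+.4f} (SE {t.se_cotwin_m3:.4f})",
            f"  change_cotwin = {self.change_cotwin:+.4f} "
            f"[{self.ci_change_cotwin[0]:+.4f}, {self.ci_change_cotwin[1]:+.4f}] "
            f"p={self.p_change_cotwin:.4g}",
            f"  change_self   = {self.change_self:+.4f} "
            f"[{self.ci_change_self[0]:+.4f}, {self.ci_change_self[1]:+.4f}] "
            f"p={self.p_change_self:.4g}",
            f"  attenuation difference (cotwin - self) = {self.attenuation_diff:+.4f} "
            f"p={self.p_attenuation_diff:.4g}",
            f"  classification: {self.classification} (alpha={self.alpha})",
        ]
        return "\n".join(lines)


def _stacked(
    pairs: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: list[str] | None,
):
    """Both-orderings stacked arrays from a long pair table."""
    covariates = list(covariates or [])
    needed = ["pair_id", "relationship", "member", exposure, outcome] + covariates
    wide = pairs_to_wide(pairs[needed])
    n = len(wide)
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} complete pairs, got {n}")
    xa = wide[f"{exposure}_A"].to_numpy(float)
    xb = wide[f"{exposure}_B"].to_numpy(float)
    ya = wide[f"{outcome}_A"].to_numpy(float)
    yb = wide[f"{outcome}_B"].to_numpy(float)
    if np.std(np.r_[xa, xb]) == 0:
        raise ValueError(f"exposure {exposure!r} does not vary")
    y = np.r_[ya, yb]
    xs = np.r_[xa, xb]
    xc = np.r_[xb, xa]
    cov = None
    if covariates:
        cov = np.column_stack(
            [np.r_[wide[f"{c}_A"].to_numpy(float), wide[f"{c}_B"].to_numpy(float)]
             for c in covariates]
        )
    groups = np.r_[np.arange(n), np.arange(n)]
    return y, xs, xc, cov, groups, covariates


def _fit_three(y, xs, xc, cov, groups, covariates, family):
    ones = np.ones_like(y)
    extra = [] if cov is None else [cov]
    extra_names = list(covariates)
    m1 = fit_glm(y, np.column_stack([ones, xs, *extra]),
                 ["const", "self", *extra_names], family, groups)
    m2 = fit_glm(y, np.column_stack([ones, xc, *extra]),
                 ["const", "cotwin", *extra_names], family, groups)
    m3 = fit_glm(y, np.column_stack([ones, xs, xc, *extra]),
                 ["const", "self", "cotwin", *extra_names], family, groups)
    return m1, m2, m3


def fit_triplet(
    pairs: pd.DataFrame,
    outcome_family: str = "continuous",
    exposure: str = "exposure",
    outcome: str = "outcome",
    covariates: list[str] | None = None,
) -> ModelTriplet:
    """Fit the three regression models on a long-format pair table.

    Both orderings of each pair are stacked and standard errors are
    cluster-robust over pairs, so they remain valid under arbitrary
    within-pair correlation. Covariates, when given, enter all three
    models.
    """
    y, xs, xc, cov, groups, covariates = _stacked(pairs, exposure, outcome, covariates)
    return _fit_with_groups(y, xs, xc, cov, groups, covariates, outcome_family)


def _changes_from_triplet(t: ModelTriplet):
    change_cotwin = t.beta_cotwin_m2 - t.beta_cotwin_m3
    change_self = t.beta_self_m1 - t.beta_self_m3
    att_cotwin = change_cotwin / t.beta_cotwin_m2 if t.beta_cotwin_m2 != 0 else math.nan
    att_self = change_self / t.beta_self_m1 if t.beta_self_m1 != 0 else math.nan
    return change_cotwin, change_self, att_cotwin, att_self, att_cotwin - att_self


# ---------------------------------------------------------------------------
# fast pair-bootstrap for the linear-outcome case


def _pair_crossprods(y, xs, xc, cov, n_pairs):
    """Per-pair cross-product matrices of [1, xs, xc, cov..., y]."""
    cols = [np.ones_like(y), xs, xc]
    if cov is not None:
        cols.extend(cov.T)
    cols.append(y)
    z = np.column_stack(cols)
    d = z.shape[1]
    # rows i and i + n_pairs belong to pair i
    zp = np.stack([z[:n_pairs], z[n_pairs:]], axis=1)  # (n, 2, d)
    return np.einsum("nij,nik->njk", zp, zp)  # (n, d, d)


def _solve_linear_models(S, n_cov):
    """Batched normal-equation solves for the three models.

    ``S`` is (B, d, d) with variable order [1, xs, xc, cov..., y].
    Returns (b1_self, b2_cotwin, b3_self, b3_cotwin) arrays of length B.
    """
    cov_idx = list(range(3, 3 + n_cov))
    yi = 3 + n_cov

    def solve(idx, want):
        A = S[np.ix_(np.arange(len(S)), idx, idx)]
        b = S[:, idx, yi]
        coefs = np.linalg.solve(A, b[..., None])[..., 0]
        return [coefs[:, idx.index(w)] for w in want]

    (b1_self,) = solve([0, 1] + cov_idx, [1])
    (b2_cotwin,) = solve([0, 2] + cov_idx, [2])
    b3_self, b3_cotwin = solve([0, 1, 2] + cov_idx, [1, 2])
    return b1_self, b2_cotwin, b3_self, b3_cotwin


def bootstrap_changes(
    pairs: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    outcome_family: str = "continuous",
    alpha: float = 0.05,
    exposure: str = "exposure",
    outcome: str = "outcome",
    covariates: list[str] | None = None,
    direction: str = "forward",
) -> CoefficientChangeReport:
    """Pair-level nonparametric bootstrap of the coefficient changes.

    Pairs are resampled with replacement (the pair is the exchangeable
    unit) and the model triplet refitted per replicate; percentile
    intervals and sign-flip two-sided p-values are reported for
    ``change_cotwin``, ``change_self`` and the attenuation difference.
    Replicates that fail to fit are dropped; more than 5% failures is an
    error.
    """
    if B < 200:
        raise ValueError(f"need at least 200 bootstrap replicates, got {B}")
    y, xs, xc, cov, groups, covariates = _stacked(pairs, exposure, outcome, covariates)
    triplet = _fit_with_groups(y, xs, xc, cov, groups, covariates, outcome_family)
    n_pairs = triplet.n_pairs
    rng = np.random.default_rng(seed)

    if outcome_family == "continuous":
        M = _pair_crossprods(y, xs, xc, cov, n_pairs)
        counts = rng.multinomial(n_pairs, np.full(n_pairs, 1.0 / n_pairs), size=B)
        S = np.tensordot(counts.astype(float), M.reshape(n_pairs, -1), axes=(1, 0))
        S = S.reshape(B, M.shape[1], M.shape[2])
        try:
            b1s, b2c, b3s, b3c = _solve_linear_models(S, 0 if cov is None else cov.shape[1])
            n_failed = 0
        except np.linalg.LinAlgError:
            b1s, b2c, b3s, b3c, n_failed = _solve_linear_loop(S, cov)
    else:
        b1s, b2c, b3s, b3c, n_failed = _bootstrap_binary(
            y, xs, xc, cov, covariates, n_pairs, B, rng
        )
    if n_failed > 0.05 * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to fit; data too fragile "
            "for bootstrap inference"
        )
    if n_failed:
        warnings.warn(f"dropped {n_failed} failed bootstrap replicates", stacklevel=2)

    ch_cotwin = b2c - b3c
    ch_self = b1s - b3s
    with np.errstate(divide="ignore", invalid="ignore"):
        att_diff = ch_cotwin / b2c - ch_self / b1s

    change_cotwin, change_self, att_c, att_s, att_d = _changes_from_triplet(triplet)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)

    def ci(samples):
        samples = samples[np.isfinite(samples)]
        if len(samples) == 0:
            return (math.nan, math.nan)
        return tuple(np.percentile(samples, [lo, hi]))

    report = CoefficientChangeReport(
        triplet=triplet,
        change_cotwin=change_cotwin,
        change_self=change_self,
        attenuation_cotwin=att_c,
        attenuation_self=att_s,
        attenuation_diff=att_d,
        ci_change_cotwin=ci(ch_cotwin),
        ci_change_self=ci(ch_self),
        ci_attenuation_diff=ci(att_diff),
        p_change_cotwin=bootstrap_percentile_p(ch_cotwin),
        p_change_self=bootstrap_percentile_p(ch_self),
        p_attenuation_diff=bootstrap_percentile_p(att_diff),
        classification="",
        alpha=alpha,
        n_pairs=n_pairs,
        n_boot=B,
        n_failed=n_failed,
        seed=seed,
        method="bootstrap",
        direction=direction,
    )
    report.classification = classify(report)
    return report


def _fit_with_groups(y, xs, xc, cov, groups, covariates, family) -> ModelTriplet:
    m1, m2, m3 = _fit_three(y, xs, xc, cov, groups, covariates, family)
    return ModelTriplet(
        beta_self_m1=m1.coef("self"), se_self_m1=m1.coef_se("self"),
        p_self_m1=m1.coef_p("self"),
        beta_cotwin_m2=m2.coef("cotwin"), se_cotwin_m2=m2.coef_se("cotwin"),
        p_cotwin_m2=m2.coef_p("cotwin"),
        beta_self_m3=m3.coef("self"), se_self_m3=m3.coef_se("self"),
        p_self_m3=m3.coef_p("self"),
        beta_cotwin_m3=m3.coef("cotwin"), se_cotwin_m3=m3.coef_se("cotwin"),
        p_cotwin_m3=m3.coef_p("cotwin"),
        outcome_family=family,
        n_pairs=len(groups) // 2,
        _fits=[m1, m2, m3],
        _groups=groups,
    )


def _solve_linear_loop(S, cov):
    """Per-replicate fallback when a batched solve hits a singular matrix."""
    n_cov = 0 if cov is None else cov.shape[1]
    out = [[], [], [], []]
    n_failed = 0
    for s in S:
        try:
            res = _solve_linear_models(s[None], n_cov)
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        for acc, val in zip(out, res):
            acc.append(val[0])
    return (*[np.asarray(a) for a in out], n_failed)


def _bootstrap_binary(y, xs, xc, cov, covariates, n_pairs, B, rng):
    """Replicate loop with logistic refits (no fast sufficient statistics)."""
    out = [[], [], [], []]
    n_failed = 0
    for _ in range(B):
        take = rng.integers(0, n_pairs, size=n_pairs)
        rows = np.r_[take, take + n_pairs]
        cov_b = None if cov is None else cov[rows]
        try:
            m1, m2, m3 = _fit_three(
                y[rows], xs[rows], xc[rows], cov_b, None, covariates, "binary"
            )
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        out[0].append(m1.coef("self"))
        out[1].append(m2.coef("cotwin"))
        out[2].append(m3.coef("self"))
        out[3].append(m3.coef("cotwin"))
    return (*[np.asarray(a) for a in out], n_failed)


def analytic_changes(
    pairs: pd.DataFrame,
    outcome_family: str = "continuous",
    alpha: float = 0.05,
    exposure: str = "exposure",
    outcome: str = "outcome",
    covariates: list[str] | None = None,
    direction: str = "forward",
) -> CoefficientChangeReport:
    """Analytic (joint-sandwich) inference on the coefficient changes.

    A fast alternative to the bootstrap: the joint cluster-robust
    covariance of the three fits yields normal-theory variances for each
    change and, by the delta method, for the attenuation difference.
    """
    triplet = fit_triplet(pairs, outcome_family, exposure, outcome, covariates)
    m1, m2, m3 = triplet._fits
    blocks = joint_sandwich([m1, m2, m3], groups=triplet._groups)
    i1, i2 = m1.names.index("self"), m2.names.index("cotwin")
    i3s, i3c = m3.names.index("self"), m3.names.index("cotwin")

    # covariance of (b1_self, b2_cotwin, b3_self, b3_cotwin)
    picks = [(0, i1), (1, i2), (2, i3s), (2, i3c)]
    V = np.array(
        [[blocks[ma][mb][ia, ib] for (mb, ib) in picks] for (ma, ia) in picks]
    )
    b1s, b2c = triplet.beta_self_m1, triplet.beta_cotwin_m2
    b3s, b3c = triplet.beta_self_m3, triplet.beta_cotwin_m3

    g_ch_cotwin = np.array([0.0, 1.0, 0.0, -1.0])
    g_ch_self = np.array([1.0, 0.0, -1.0, 0.0])
    # attenuation_diff = b3s/b1s - b3c/b2c
    g_att = np.array([-b3s / b1s**2, b3c / b2c**2, 1.0 / b1s, -1.0 / b2c]) \
        if b1s != 0 and b2c != 0 else np.full(4, np.nan)

    change_cotwin, change_self, att_c, att_s, att_d = _changes_from_triplet(triplet)
    se_cc = math.sqrt(max(g_ch_cotwin @ V @ g_ch_cotwin, 0.0))
    se_cs = math.sqrt(max(g_ch_self @ V @ g_ch_self, 0.0))
    var_att = float(g_att @ V @ g_att) if np.all(np.isfinite(g_att)) else math.nan
    se_att = math.sqrt(var_att) if var_att == var_att and var_att >= 0 else math.nan

    from scipy.stats import norm

    zq = norm.ppf(1 - alpha / 2)
    report = CoefficientChangeReport(
        triplet=triplet,
        change_cotwin=change_cotwin,
        change_self=change_self,
        attenuation_cotwin=att_c,
        attenuation_self=att_s,
        attenuation_diff=att_d,
        ci_change_cotwin=(change_cotwin - zq * se_cc, change_cotwin + zq * se_cc),
        ci_change_self=(change_self - zq * se_cs, change_self + zq * se_cs),
        ci_attenuation_diff=(
            (att_d - zq * se_att, att_d + zq * se_att)
            if np.isfinite(se_att) else (math.nan, math.nan)
        ),
        p_change_cotwin=two_sided_p(change_cotwin, se_cc),
        p_change_self=two_sided_p(change_self, se_cs),
        p_attenuation_diff=two_sided_p(att_d, se_att) if np.isfinite(se_att)
        else math.nan,
        classification="",
        alpha=alpha,
        n_pairs=triplet.n_pairs,
        n_boot=0,
        n_failed=0,
        seed=None,
        method="analytic",
        direction=direction,
    )
    report.classification = classify(report)
    return report


def classify(report: CoefficientChangeReport, alpha: float | None = None) -> str:
    """Scenario label from a coefficient-change report.

    See :func:`famvar._inference.classify_changes` for the decision
    rules; the significance level defaults to the one the report was
    built with.
    """
    a = report.alpha if alpha is None else alpha
    t = report.triplet
    return classify_changes(
        p_marginal_self=t.p_self_m1,
        p_marginal_cross=t.p_cotwin_m2,
        p_change_self=report.p_change_self,
        p_change_cross=report.p_change_cotwin,
        p_adjusted_cross=t.p_cotwin_m3,
        p_attenuation_diff=report.p_attenuation_diff,
        alpha=a,
    )


def reverse_test(
    pairs: pd.DataFrame,
    outcome_family: str = "continuous",
    exposure: str = "exposure",
    outcome: str = "outcome",
    method: str = "bootstrap",
    **kwargs,
) -> CoefficientChangeReport:
    """Run the full procedure with exposure and outcome exchanged.

    Probes reverse causation: if X truly causes Y, the forward analysis
    should look causal and the reversed one (regressing X on own and
    co-relative's Y) should not. ``outcome_family`` refers to the
    reversed outcome, i.e. the original exposure.
    """
    runner = bootstrap_changes if method == "bootstrap" else analytic_changes
    return runner(
        pairs,
        outcome_family=outcome_family,
        exposure=outcome,
        outcome=exposure,
        direction="reverse",
        **kwargs,
    )
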