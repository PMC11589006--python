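"""Coefficient-change causal inference for unrelated individuals.

The family-history analogue of the within-pair procedure: instead of the
co-relative's exposure, each individual carries a binary family-history
indicator (the outcome of a relative). Three regressions of the outcome
are fitted — on the exposure alone, on family history alone, and on both
— and inference is made from the changes in the two coefficients between
the marginal and joint fits. An exposure coefficient that is stable
while the family-history coefficient attenuates is consistent with the
exposure having a causal effect; both attenuating together is consistent
with familial confounding.

Inference on each change uses the analytic variance of the coefficient
difference for nested regressions fitted on shared data (the
Freedman-style coefficient-change test), computed here from the joint
sandwich covariance of the fits; an individual-level bootstrap is
available as a cross-check.
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
    fit_glm,
    joint_sandwich,
    two_sided_p,
)

__all__ = [
    "FHChangeReport",
    "fit_fh_models",
    "freedman_test",
    "classify_fh",
]

MIN_INDIVIDUALS = 50


@dataclass
class FHChangeReport:
    """Marginal and adjusted coefficients, their changes, and the label."""

    beta_exposure_marginal: float
    se_exposure_marginal: float
    p_exposure_marginal: float
    beta_fh_marginal: float
    se_fh_marginal: float
    p_fh_marginal: float
    beta_exposure_adjusted: float
    se_exposure_adjusted: float
    p_exposure_adjusted: float
    beta_fh_adjusted: float
    se_fh_adjusted: float
    p_fh_adjusted: float
    change_exposure: float
    change_fh: float
    attenuation_exposure: float
    attenuation_fh: float
    attenuation_diff: float
    stat_change_exposure: float
    p_change_exposure: float
    stat_change_fh: float
    p_change_fh: float
    p_attenuation_diff: float
    classification: str
    outcome_family: str
    n: int
    alpha: float
    method: str
    n_boot: int = 0
    seed: int | None = None
    ci_change_exposure: tuple[float, float] = (math.nan, math.nan)
    ci_change_fh: tuple[float, float] = (math.nan, math.nan)
    _fits: list[GLMFit] = field(default=None, repr=False, compare=False)

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d.pop("_fits")
        return json.dumps(d, indent=kwargs.pop("indent", 2), default=float, **kwargs)

    def summary(self) -> str:
        lines = [
            f"Family-history coefficient-change report (n={self.n}, {self.method})",
            f"  exposure: marginal {self.beta_exposure_marginal:+.4f} "
            f"-> adjusted {self.beta_exposure_adjusted:+.4f} "
            f"(change {self.change_exposure:+.4f}, p={self.p_change_exposure:.4g})",
            f"  family history: marginal {self.beta_fh_marginal:+.4f} "
            f"-> adjusted {self.beta_fh_adjusted:+.4f} "
            f"(change {self.change_fh:+.4f}, p={self.p_change_fh:.4g})",
            f"  attenuation difference (fh - exposure) = {self.attenuation_diff:+.4f} "
            f"p={self.p_attenuation_diff:.4g}",
            f"  classification: {self.classification} (alpha={self.alpha})",
        ]
        return "\n".join(lines)


def _prepare(table, exposure, fh, outcome, covariates):
    covariates = list(covariates or [])
    cols = [exposure, fh, outcome] + covariates
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    if "id" in table.columns and table["id"].duplicated().any():
        raise ValueError("duplicated individual ids")
    data = table[cols].dropna()
    n = len(data)
    if n < MIN_INDIVIDUALS:
        raise ValueError(f"need at least {MIN_INDIVIDUALS} individuals, got {n}")
    fh_vals = data[fh].to_numpy(float)
    uniq = np.unique(fh_vals)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        warnings.warn(
            f"family-history column {fh!r} is not binary; dichotomising as > 0",
            stacklevel=3,
        )
        fh_vals = (fh_vals > 0).astype(float)
        uniq = np.unique(fh_vals)
    if len(uniq) < 2:
        raise ValueError("both family-history classes must be present")
    x = data[exposure].to_numpy(float)
    y = data[outcome].to_numpy(float)
    cov = data[covariates].to_numpy(float) if covariates else None
    return x, fh_vals, y, cov, covariates


def _fit_fh_three(x, f, y, cov, covariates, family):
    ones = np.ones_like(y)
    extra = [] if cov is None else [cov]
    names_extra = list(covariates)
    ma = fit_glm(y, np.column_stack([ones, x, *extra]),
                 ["const", "exposure", *names_extra], family)
    mb = fit_glm(y, np.column_stack([ones, f, *extra]),
                 ["const", "fh", *names_extra], family)
    mc = fit_glm(y, np.column_stack([ones, x, f, *extra]),
                 ["const", "exposure", "fh", *names_extra], family)
    return ma, mb, mc


def _change_inference(fits):
    """Analytic variances of both changes and the attenuation difference."""
    ma, mb, mc = fits
    blocks = joint_sandwich(fits)
    picks = [
        (0, ma.names.index("exposure")),
        (1, mb.names.index("fh")),
        (2, mc.names.index("exposure")),
        (2, mc.names.index("fh")),
    ]
    V = np.array(
        [[blocks[i][j][a, b] for (j, b) in picks] for (i, a) in picks]
    )
    b_xm, b_fm = ma.coef("exposure"), mb.coef("fh")
    b_xa, b_fa = mc.coef("exposure"), mc.coef("fh")
    g_dx = np.array([1.0, 0.0, -1.0, 0.0])
    g_df = np.array([0.0, 1.0, 0.0, -1.0])
    se_dx = math.sqrt(max(g_dx @ V @ g_dx, 0.0))
    se_df = math.sqrt(max(g_df @ V @ g_df, 0.0))
    if b_xm != 0 and b_fm != 0:
        # attenuation_diff = b_xa/b_xm - b_fa/b_fm  (fh minus exposure change share)
        g_att = np.array([-b_xa / b_xm**2, b_fa / b_fm**2, 1.0 / b_xm, -1.0 / b_fm])
        var_att = float(g_att @ V @ g_att)
        se_att = math.sqrt(var_att) if var_att >= 0 else math.nan
    else:
        se_att = math.nan
    return se_dx, se_df, se_att


def fit_fh_models(
    table: pd.DataFrame,
    outcome_family: str = "continuous",
    exposure: str = "exposure",
    fh: str = "family_history",
    outcome: str = "outcome",
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    bootstrap: int = 0,
    seed: int = 0,
) -> FHChangeReport:
    """Fit the three family-history models and assemble the change report.

    The outcome is regressed on the exposure alone, on the binary
    family-history indicator alone, and on both together (the same
    covariates, if any, in every model). Changes between marginal and
    adjusted coefficients carry Freedman-style analytic p-values; pass
    ``bootstrap=B`` (with ``B >= 200``) to add individual-level
    percentile bootstrap intervals and use bootstrap p-values instead.
    """
    x, f, y, cov, covariates = _prepare(table, exposure, fh, outcome, covariates)
    fits = _fit_fh_three(x, f, y, cov, covariates, outcome_family)
    ma, mb, mc = fits
    b_xm, b_fm = ma.coef("exposure"), mb.coef("fh")
    b_xa, b_fa = mc.coef("exposure"), mc.coef("fh")
    change_x, change_f = b_xm - b_xa, b_fm - b_fa
    att_x = change_x / b_xm if b_xm != 0 else math.nan
    att_f = change_f / b_fm if b_fm != 0 else math.nan
    att_diff = att_f - att_x

    se_dx, se_df, se_att = _change_inference(fits)
    stat_dx = change_x / se_dx if se_dx > 0 else math.nan
    stat_df = change_f / se_df if se_df > 0 else math.nan
    p_dx, p_df = two_sided_p(change_x, se_dx), two_sided_p(change_f, se_df)
    p_att = two_sided_p(att_diff, se_att) if np.isfinite(se_att) else math.nan
    method = "freedman"
    n_boot = 0
    ci_dx = ci_df = (math.nan, math.nan)

    if bootstrap:
        if bootstrap < 200:
            raise ValueError(f"need at least 200 bootstrap replicates, got {bootstrap}")
        dxs, dfs, atts = _bootstrap_fh(
            x, f, y, cov, covariates, outcome_family, bootstrap, seed
        )
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        ci_dx = tuple(np.percentile(dxs[np.isfinite(dxs)], [lo, hi]))
        ci_df = tuple(np.percentile(dfs[np.isfinite(dfs)], [lo, hi]))
        p_dx = bootstrap_percentile_p(dxs)
        p_df = bootstrap_percentile_p(dfs)
        p_att = bootstrap_percentile_p(atts)
        method = "bootstrap"
        n_boot = bootstrap

    report = FHChangeReport(
        beta_exposure_marginal=b_xm, se_exposure_marginal=ma.coef_se("exposure"),
        p_exposure_marginal=ma.coef_p("exposure"),
        beta_fh_marginal=b_fm, se_fh_marginal=mb.coef_se("fh"),
        p_fh_marginal=mb.coef_p("fh"),
        beta_exposure_adjusted=b_xa, se_exposure_adjusted=mc.coef_se("exposure"),
        p_exposure_adjusted=mc.coef_p("exposure"),
        beta_fh_adjusted=b_fa, se_fh_adjusted=mc.coef_se("fh"),
        p_fh_adjusted=mc.coef_p("fh"),
        change_exposure=change_x, change_fh=change_f,
        attenuation_exposure=att_x, attenuation_fh=att_f,
        attenuation_diff=att_diff,
        stat_change_exposure=stat_dx, p_change_exposure=p_dx,
        stat_change_fh=stat_df, p_change_fh=p_df,
        p_attenuation_diff=p_att,
        classification="",
        outcome_family=outcome_family,
        n=len(y), alpha=alpha, method=method, n_boot=n_boot,
        seed=seed if bootstrap else None,
        ci_change_exposure=ci_dx, ci_change_fh=ci_df,
        _fits=list(fits),
    )
    report.classification = classify_fh(report)
    return report


def _bootstrap_fh(x, f, y, cov, covariates, family, B, seed):
    """Individual-level resampling of both coefficient changes."""
    rng = np.random.default_rng(seed)
    n = len(y)
    if family == "continuous":
        cols = [np.ones_like(y), x, f]
        if cov is not None:
            cols.extend(cov.T)
        cols.append(y)
        z = np.column_stack(cols)
        M = np.einsum("ni,nj->nij", z, z)
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)
        S = np.tensordot(counts, M.reshape(n, -1), axes=(1, 0)).reshape(
            B, z.shape[1], z.shape[1]
        )
        n_cov = 0 if cov is None else cov.shape[1]
        cov_idx = list(range(3, 3 + n_cov))
        yi = 3 + n_cov

        def solve(idx, want):
            A = S[np.ix_(np.arange(B), idx, idx)]
            b = S[:, idx, yi]
            coefs = np.linalg.solve(A, b[..., None])[..., 0]
            return [coefs[:, idx.index(w)] for w in want]

        (bxm,) = solve([0, 1] + cov_idx, [1])
        (bfm,) = solve([0, 2] + cov_idx, [2])
        bxa, bfa = solve([0, 1, 2] + cov_idx, [1, 2])
    else:
        bxm, bfm, bxa, bfa = [], [], [], []
        for _ in range(B):
            take = rng.integers(0, n, size=n)
            cov_b = None if cov is None else cov[take]
            try:
                ma, mb, mc = _fit_fh_three(
                    x[take], f[take], y[take], cov_b, covariates, family
                )
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                continue
            bxm.append(ma.coef("exposure"))
            bfm.append(mb.coef("fh"))
            bxa.append(mc.coef("exposure"))
            bfa.append(mc.coef("fh"))
        bxm, bfm, bxa, bfa = map(np.asarray, (bxm, bfm, bxa, bfa))
    dx = bxm - bxa
    df = bfm - bfa
    with np.errstate(divide="ignore", invalid="ignore"):
        att = df / bfm - dx / bxm
    return dx, df, att


def freedman_test(
    table: pd.DataFrame,
    which: str = "fh",
    outcome_family: str = "continuous",
    exposure: str = "exposure",
    fh: str = "family_history",
    outcome: str = "outcome",
    covariates: list[str] | None = None,
):
    """Test equality of a marginal and adjusted regression coefficient.

    ``which`` selects the variable (``"exposure"`` or ``"fh"``) whose
    coefficient is compared between its marginal model and the joint
    model; both models are fitted on identical rows and the variance of
    the difference comes from their joint sandwich covariance. Returns
    ``(statistic, p)`` where the statistic is the z-score of the change.
    """
    if which not in ("exposure", "fh"):
        raise ValueError(f"which must be 'exposure' or 'fh', got {which!r}")
    x, f, y, cov, covariates = _prepare(table, exposure, fh, outcome, covariates)
    fits = _fit_fh_three(x, f, y, cov, covariates, outcome_family)
    se_dx, se_df, _ = _change_inference(fits)
    ma, mb, mc = fits
    if which == "exposure":
        change = ma.coef("exposure") - mc.coef("exposure")
        se = se_dx
    else:
        change = mb.coef("fh") - mc.coef("fh")
        se = se_df
    if not np.isfinite(se) or se <= 0:
        raise RuntimeError("degenerate variance for the coefficient change")
    return change / se, two_sided_p(change, se)


def classify_fh(report: FHChangeReport, alpha: float | None = None) -> str:
    """Scenario label from a family-history change report.

    The exposure plays the self role and family history the cross role:

    * ``no_association`` — neither marginal coefficient significant;
    * ``consistent_with_causation`` — the family-history coefficient
      attenuates to the null (significant change, nonsignificant
      adjusted value) while the exposure coefficient does not change;
    * ``consistent_with_familial_confounding`` — both coefficients
      decrease significantly when estimated together;
    * ``inconclusive`` otherwise.

    Unlike the within-pair classifier, no equal-extent condition is
    imposed for confounding: the exposure and the dichotomised
    family-history indicator live on different scales, so their
    attenuation proportions differ even under pure confounding.
    """
    a = report.alpha if alpha is None else alpha
    if not 0 < a < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {a}")
    sig = lambda p: np.isfinite(p) and p < a
    if not sig(report.p_exposure_marginal) and not sig(report.p_fh_marginal):
        return "no_association"
    if (
        sig(report.p_change_fh)
        and not sig(report.p_fh_adjusted)
        and not sig(report.p_change_exposure)
    ):
        return "consistent_with_causation"
    if sig(report.p_change_fh) and sig(report.p_change_exposure):
        return "consistent_with_familial_confounding"
    return "inconclusive"
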