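"""Shared machinery for coefficient-change inference.

Both coefficient-change procedures (the within-pair version on relative
pairs and the family-history version on unrelated individuals) fit a set
of nested regressions on the same rows and make inference about
differences between coefficients across models. Because the fits share
data, the estimators are correlated; this module computes their joint
covariance by stacking the estimating equations:

for GLM fits ``a`` and ``b`` with canonical links, score contributions
``psi_i = x_i (y_i - mu_i)`` and bread matrices ``A = X' W X`` (with
``W = dmu/deta``), the joint sandwich is

    Cov(theta_a, theta_b) = A_a^{-1} [ sum_c psi_a(c) psi_b(c)' ] A_b^{-1}

summed over independent clusters ``c`` (individuals, or pairs when both
orderings of a pair are stacked). Differences of coefficients and the
difference of attenuation proportions then get delta-method variances —
the analytic route attributed to Freedman-style coefficient-change
tests. A pair/individual-level nonparametric bootstrap is the
alternative inference route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "GLMFit",
    "fit_glm",
    "joint_sandwich",
    "classify_changes",
    "bootstrap_percentile_p",
    "two_sided_p",
    "CLASSIFICATION_LABELS",
]

CLASSIFICATION_LABELS = (
    "consistent_with_causation",
    "consistent_with_familial_confounding",
    "mixed",
    "no_association",
    "inconclusive",
)

FAMILIES = ("continuous", "binary")


@dataclass
class GLMFit:
    """A fitted regression with cluster-robust uncertainty."""

    names: list[str]
    params: np.ndarray
    cov: np.ndarray  # cluster-robust sandwich
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)  # dmu/deta per observation
    llf: float = np.nan

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        z = self.params / self.se
        return 2.0 * norm.sf(np.abs(z))

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def coef_p(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"outcome family must be one of {FAMILIES}, got {family!r}")


def fit_glm(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    family: str = "continuous",
    groups: np.ndarray | None = None,
) -> GLMFit:
    """Fit a linear or logistic regression with cluster-robust covariance.

    ``groups`` identifies independent clusters; observations within a
    cluster may be arbitrarily correlated. With ``groups=None`` each row
    is its own cluster (heteroskedasticity-robust).
    """
    _check_family(family)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix with columns {names} is rank deficient (collinear predictors)"
        )
    if family == "binary":
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))) or len(classes) < 2:
            raise ValueError("binary outcome must contain both classes coded 0/1")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:  # convergence failure
            raise RuntimeError(f"logistic fit failed to converge: {exc}") from exc
        mu = res.fittedvalues
        if np.any(mu > 1 - 1e-10) or np.any(mu < 1e-10):
            raise RuntimeError(
                "fitted probabilities saturate (quasi-separation); "
                "consider a penalised fit or rarer predictors"
            )
        weights = mu * (1.0 - mu)
        llf = float(res.llf)
    else:
        res = sm.OLS(y, X).fit()
        mu = res.fittedvalues
        weights = np.ones_like(mu)
        llf = float(res.llf)

    params = np.asarray(res.params, dtype=float)
    fit = GLMFit(
        names=list(names), params=params, cov=np.empty((0, 0)),
        X=X, y=y, mu=np.asarray(mu, dtype=float), weights=weights, llf=llf,
    )
    fit.cov = joint_sandwich([fit], groups=groups)[0][0]
    return fit


def _cluster_scores(fit: GLMFit, groups: np.ndarray | None) -> np.ndarray:
    """Per-cluster summed score contributions, (n_clusters, p)."""
    psi = fit.X * (fit.y - fit.mu)[:, None]
    if groups is None:
        return psi
    order = np.argsort(groups, kind="stable")
    sorted_groups = np.asarray(groups)[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1]])
    return np.add.reduceat(psi[order], boundaries, axis=0)


def joint_sandwich(
    fits: list[GLMFit], groups: np.ndarray | None = None
) -> list[list[np.ndarray]]:
    """Joint cluster-robust covariance across fits sharing the same rows.

    Returns a nested list ``cov[a][b]`` of covariance blocks between the
    parameter vectors of ``fits[a]`` and ``fits[b]``.
    """
    n_rows = {f.X.shape[0] for f in fits}
    if len(n_rows) != 1:
        raise ValueError("all fits must be estimated on the same rows")
    breads = [
        np.linalg.inv(f.X.T @ (f.X * f.weights[:, None])) for f in fits
    ]
    scores = [_cluster_scores(f, groups) for f in fits]
    blocks: list[list[np.ndarray]] = []
    for a, fa in enumerate(fits):
        row = []
        for b, fb in enumerate(fits):
            meat = scores[a].T @ scores[b]
            row.append(breads[a] @ meat @ breads[b].T)
        blocks.append(row)
    return blocks


def two_sided_p(estimate: float, se: float) -> float:
    from scipy.stats import norm

    if se <= 0 or not np.isfinite(se):
        return float("nan")
    return float(2.0 * norm.sf(abs(estimate) / se))


def bootstrap_percentile_p(samples: np.ndarray) -> float:
    """Two-sided sign-flip p-value from bootstrap replicates of a statistic.

    ``p = 2 * min(P*(theta <= 0), P*(theta >= 0))`` with a +1 continuity
    correction; the smallest attainable value is ``2 / (B + 1)``.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    b = len(samples)
    if b == 0:
        return float("nan")
    lo = (np.sum(samples <= 0.0) + 1.0) / (b + 1.0)
    hi = (np.sum(samples >= 0.0) + 1.0) / (b + 1.0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def classify_changes(
    *,
    p_marginal_self: float,
    p_marginal_cross: float,
    p_change_self: float,
    p_change_cross: float,
    p_adjusted_cross: float,
    p_attenuation_diff: float,
    alpha: float = 0.05,
) -> str:
    """Scenario classification from a pair of coefficient changes.

    ``self`` denotes the coefficient of the individual's own exposure
    (or of the exposure, in the family-history setting) and ``cross``
    the co-relative's exposure (or the family-history indicator).

    * ``no_association`` — neither marginal coefficient is significant.
    * ``consistent_with_causation`` — the cross coefficient attenuates
      to the null (significant change, nonsignificant adjusted value)
      while the self coefficient does not change.
    * ``consistent_with_familial_confounding`` — both coefficients
      attenuate, to statistically indistinguishable extents.
    * ``mixed`` — both attenuate, to different extents.
    * ``inconclusive`` — anything else.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    sig = lambda p: np.isfinite(p) and p < alpha
    if not sig(p_marginal_self) and not sig(p_marginal_cross):
        return "no_association"
    if sig(p_change_cross) and not sig(p_adjusted_cross) and not sig(p_change_self):
        return "consistent_with_causation"
    if sig(p_change_cross) and sig(p_change_self):
        if not sig(p_attenuation_diff):
            return "consistent_with_familial_confounding"
        return "mixed"
    return "inconclusive"
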