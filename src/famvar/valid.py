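"""The VALID model: variance in age-specific log incidence decomposition.

Under a multiplicative normal risk model, a standardized risk score with
case–control mean difference ``delta`` contributes ``delta**2`` to the
variance of age-specific log incidence, and induces a familial risk
ratio of ``FRR = exp(r * delta**2)`` in relatives whose scores are
correlated ``r`` (the unifying equation). With ``r = 1`` for MZ twins,
the total familial variance per age group is ``ln(FRR_MZ)`` and the best
achievable genetic risk discrimination is
``AUC_max = Phi(sqrt(ln(FRR_MZ) / 2))``.

This module implements OPERA standardization (odds per adjusted standard
deviation), the unifying equation and its inverse, the maximum-AUC
bound, and the decomposition of familial variance into named components
by age group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "StandardizedScore",
    "VarianceComponent",
    "DecompositionTable",
    "opera_standardize",
    "frr_from_score",
    "delta_from_frr",
    "max_auc",
    "auc_from_delta",
    "decompose",
    "load_example_components",
]

COMPONENT_COLUMNS = ["component", "age_group", "delta", "familial_fraction"]


@dataclass
class StandardizedScore:
    """A risk factor residualised on covariates and scaled to unit SD.

    Retains the linear-adjustment coefficients, the construction-sample
    mean of each covariate, and the residual SD so that new individuals
    can be scored on the same scale via :meth:`transform`.
    """

    values: np.ndarray
    adjustment_covariates: tuple[str, ...]
    coef: np.ndarray = field(repr=False)  # intercept first
    residual_sd: float = field(repr=False, default=1.0)

    def transform(self, raw, covariates=None) -> np.ndarray:
        """Score new individuals on the construction-sample scale."""
        raw = np.asarray(raw, dtype=float)
        design = _design_matrix(raw.shape[0], covariates, self.adjustment_covariates)
        return (raw - design @ self.coef) / self.residual_sd


def _as_covariate_frame(covariates, n: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n))
    if isinstance(covariates, pd.DataFrame):
        return covariates.reset_index(drop=True)
    return pd.DataFrame(np.asarray(covariates, dtype=float))


def _design_matrix(n: int, covariates, expected_names) -> np.ndarray:
    frame = _as_covariate_frame(covariates, n)
    names = tuple(str(c) for c in frame.columns)
    if names != tuple(expected_names):
        raise ValueError(
            f"covariate columns {names} do not match the construction sample "
            f"{tuple(expected_names)}"
        )
    return np.column_stack([np.ones(n), frame.to_numpy(dtype=float)]) if len(names) \
        else np.ones((n, 1))


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    bad = []
    for j in range(1, design.shape[1]):
        sub = design[:, : j + 1]
        if np.linalg.matrix_rank(sub) < j + 1:
            bad.append(names[j - 1])
    return bad


def opera_standardize(raw, covariates=None) -> StandardizedScore:
    """OPERA standardization: residualise on covariates, scale to unit SD.

    Fits an ordinary least-squares adjustment of ``raw`` on the covariates
    (with intercept), divides the residuals by their standard deviation,
    and retains the fit so that the same transformation can be applied to
    new individuals. The resulting score has mean 0 and SD 1 on the
    construction sample, and its logistic-regression effect size is an
    odds ratio per adjusted standard deviation.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    frame = _as_covariate_frame(covariates, n)
    names = [str(c) for c in frame.columns]
    design = np.column_stack([np.ones(n), frame.to_numpy(dtype=float)]) if names \
        else np.ones((n, 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, raw, rcond=None)
    resid = raw - design @ coef
    sd = float(resid.std(ddof=0))
    if sd == 0.0:
        raise ValueError("zero residual variance after adjustment")
    return StandardizedScore(
        values=resid / sd,
        adjustment_covariates=tuple(names),
        coef=coef,
        residual_sd=sd,
    )


def frr_from_score(delta: float, r: float) -> float:
    """Familial risk ratio induced by a standardized score.

    The unifying equation: a score with case–control mean difference
    ``delta`` and within-pair correlation ``r`` yields
    ``FRR = exp(r * delta**2)``.
    """
    if not np.isfinite(delta):
        raise ValueError(f"delta must be finite, got {delta}")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    return math.exp(r * delta * delta)


def delta_from_frr(frr: float, r: float) -> float:
    """Invert the unifying equation: ``delta = sqrt(ln(frr) / r)``."""
    if not np.isfinite(frr) or frr < 1:
        raise ValueError(f"frr must be >= 1, got {frr}")
    if not 0 < r <= 1:
        raise ValueError(f"r must lie in (0, 1], got {r}")
    return math.sqrt(math.log(frr) / r)


def max_auc(frr_mz: float) -> float:
    """Maximum achievable genetic risk discrimination.

    The MZ-twin familial risk ratio bounds the AUC of any genetic risk
    score: ``AUC_max = Phi(sqrt(ln(FRR_MZ) / 2))``.
    """
    if not np.isfinite(frr_mz) or frr_mz < 1:
        raise ValueError(f"frr_mz must be >= 1, got {frr_mz}")
    return float(norm.cdf(math.sqrt(math.log(frr_mz) / 2.0)))


def auc_from_delta(delta: float) -> float:
    """AUC of a normal score with case–control mean difference ``delta``.

    Cases and controls each have unit-SD normal scores separated by
    ``delta``, so ``AUC = Phi(delta / sqrt(2))``. Consistent with
    :func:`max_auc` through ``delta = sqrt(ln(FRR_MZ))`` at ``r = 1``.
    """
    if not np.isfinite(delta) or delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    return float(norm.cdf(delta / math.sqrt(2.0)))


@dataclass(frozen=True)
class VarianceComponent:
    """A named risk-score component at one age group.

    ``delta`` is the component's case–control mean difference at this
    age; ``familial_fraction`` the fraction of its variance contribution
    ``delta**2`` treated as familial; ``r_mz``/``r_dz`` the within-pair
    score correlations (carried as metadata).
    """

    name: str
    age_group: str
    delta: float
    familial_fraction: float
    r_mz: float = 1.0
    r_dz: float = 0.5

    def __post_init__(self) -> None:
        if self.delta < 0 or not np.isfinite(self.delta):
            raise ValueError(f"delta must be >= 0 (direction of risk), got {self.delta}")
        if not 0 <= self.familial_fraction <= 1:
            raise ValueError(
                f"familial_fraction must lie in [0, 1], got {self.familial_fraction}"
            )
        for r in (self.r_mz, self.r_dz):
            if abs(r) > 1:
                raise ValueError(f"|r| must be <= 1, got {r}")


@dataclass
class DecompositionTable:
    """Result of the age-specific familial variance decomposition.

    ``components`` is tidy (one row per component × age group) with
    familial and nonfamilial variance contributions; ``totals`` has one
    row per age group with the total familial variance ``ln(FRR_MZ)``,
    the summed explained familial variance, and the residual unexplained
    familial variance (floored at 0). Component order is preserved for
    stacked plotting.
    """

    components: pd.DataFrame
    totals: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table including the residual as a pseudo-component."""
        residual = self.totals[["age_group", "residual_familial"]].copy()
        residual.insert(0, "component", "unexplained_familial")
        residual = residual.rename(columns={"residual_familial": "familial_variance"})
        residual["nonfamilial_variance"] = 0.0
        return pd.concat(
            [self.components, residual], ignore_index=True
        )[["component", "age_group", "familial_variance", "nonfamilial_variance"]]


def _components_frame(components) -> pd.DataFrame:
    if isinstance(components, pd.DataFrame):
        missing = [c for c in COMPONENT_COLUMNS if c not in components.columns]
        if missing:
            raise ValueError(f"component table missing columns {missing}")
        # route through the dataclass for validation
        comps = [
            VarianceComponent(
                name=str(row.component),
                age_group=str(row.age_group),
                delta=float(row.delta),
                familial_fraction=float(row.familial_fraction),
                r_mz=float(getattr(row, "r_mz", 1.0)),
                r_dz=float(getattr(row, "r_dz", 0.5)),
            )
            for row in components.itertuples()
        ]
    else:
        comps = list(components)
    return pd.DataFrame(
        {
            "component": [c.name for c in comps],
            "age_group": [c.age_group for c in comps],
            "delta": [c.delta for c in comps],
            "familial_fraction": [c.familial_fraction for c in comps],
        }
    )


def decompose(components, frr_mz) -> DecompositionTable:
    """Decompose familial variance in log incidence by age group.

    Parameters
    ----------
    components
        Either a tidy DataFrame with columns ``component, age_group,
        delta, familial_fraction`` (optionally ``r_mz, r_dz``) or an
        iterable of :class:`VarianceComponent`. Every component must
        cover the same set of age groups.
    frr_mz
        Total MZ-twin familial risk ratio: a scalar (applied to every
        age group) or a mapping / Series keyed by age group. Each value
        must be >= 1; the total familial variance per age group is its
        natural log.

    Each component contributes ``familial_fraction * delta**2`` familial
    and ``(1 - familial_fraction) * delta**2`` nonfamilial variance,
    summed as if components were independent. A negative residual
    (components overlapping or correlated) is floored at 0 with a
    warning.
    """
    frame = _components_frame(components)
    age_groups = list(dict.fromkeys(frame["age_group"]))
    by_component = frame.groupby("component", sort=False)["age_group"].apply(set)
    for name, groups in by_component.items():
        if groups != set(age_groups):
            raise ValueError(
                f"component {name!r} does not cover the same age groups as the others"
            )

    if np.isscalar(frr_mz):
        frr_map = {g: float(frr_mz) for g in age_groups}
    else:
        frr_map = dict(pd.Series(frr_mz).items())
        missing = [g for g in age_groups if g not in frr_map]
        if missing:
            raise ValueError(f"frr_mz missing age groups {missing}")
    for g, f in frr_map.items():
        if f < 1:
            raise ValueError(f"total FRR_MZ must be >= 1, got {f} for age group {g!r}")

    frame = frame.assign(
        familial_variance=frame["familial_fraction"] * frame["delta"] ** 2,
        nonfamilial_variance=(1.0 - frame["familial_fraction"]) * frame["delta"] ** 2,
    )
    totals = []
    for g in age_groups:
        total = math.log(frr_map[g])
        explained = float(frame.loc[frame["age_group"] == g, "familial_variance"].sum())
        residual = total - explained
        if residual < 0:
            warnings.warn(
                f"explained familial variance {explained:.4g} exceeds total "
                f"{total:.4g} in age group {g!r}; residual floored at 0 "
                "(components may overlap or be correlated)",
                stacklevel=2,
            )
            residual = 0.0
        totals.append(
            {
                "age_group": g,
                "total_familial": total,
                "explained_familial": explained,
                "residual_familial": residual,
            }
        )
    return DecompositionTable(
        components=frame[
            ["component", "age_group", "familial_variance", "nonfamilial_variance"]
        ].copy(),
        totals=pd.DataFrame(totals),
    )


def load_example_components() -> tuple[pd.DataFrame, pd.Series]:
    """Packaged illustrative component table (breast-cancer-like).

    Returns ``(components, frr_mz)``: a component table in the schema
    accepted by :func:`decompose` and a Series of total MZ-twin familial
    risk ratios by age group. The numbers are illustrative — chosen to
    echo the qualitative pattern of strongly age-dependent familial
    variance with major genes dominant at young ages and polygenic and
    lifestyle factors more prominent at older ages — not estimates from
    any cohort.
    """
    with resources.files("famvar.data").joinpath("example_components.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    frr = table[["age_group", "frr_mz"]].drop_duplicates().set_index("age_group")["frr_mz"]
    return table.drop(columns="frr_mz"), frr
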