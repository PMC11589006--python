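"""Synthetic data generators with known ground truth.

Three families of generators are provided:

* twin/relative pairs under the multiplicative normal risk model
  (disease probability proportional to ``exp(delta * score)`` for a
  standardized score correlated within pairs),
* linear structural-equation scenarios (causal / confounded / reverse /
  null / mixed) for the coefficient-change methods, both as relative
  pairs and as unrelated probands with a family-history indicator,
* genotype panels with planted multi-variant risk regions, written as
  VCF plus a phenotype file, for the region scan.

All generators take an explicit integer seed and are byte-reproducible;
the true generating parameters are attached to each returned table under
``DataFrame.attrs``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RiskModelParams",
    "SimScenario",
    "GenotypePanelSpec",
    "simulate_twin_pairs",
    "simulate_pair_scenario",
    "simulate_fh_cohort",
    "simulate_genotype_panel",
    "simulate_panel_arrays",
    "empirical_frr",
    "pairs_to_wide",
]

SCENARIO_KINDS = ("causal", "confounded", "reverse", "null", "mixed")

PAIR_COLUMNS = ["pair_id", "relationship", "member", "exposure", "outcome"]


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class RiskModelParams:
    """Parameters of the multiplicative normal risk model.

    delta
        Case–control mean difference of the standardized risk score on
        the log-incidence scale (dimensionless risk gradient).
    r
        Within-pair correlation of the score, in [-1, 1] (1 for MZ
        twins and a fully heritable additive score, ~0.5 for DZ/siblings).
    baseline_incidence
        Marginal disease probability, in (0, 1).
    """

    delta: float
    r: float
    baseline_incidence: float
    n_pairs: int
    seed: int
    relationship: str = "MZ"

    def __post_init__(self) -> None:
        _check_finite("delta", self.delta)
        _check_finite("r", self.r)
        if abs(self.r) > 1:
            raise ValueError(f"|r| must be <= 1, got r={self.r}")
        if not 0 < self.baseline_incidence < 1:
            raise ValueError(
                f"baseline_incidence must lie in (0, 1), got {self.baseline_incidence}"
            )
        if self.n_pairs <= 0:
            raise ValueError(f"n_pairs must be positive, got {self.n_pairs}")


@dataclass(frozen=True)
class SimScenario:
    """A generative world for the coefficient-change methods.

    ``kind`` selects the structural model; only the parameters relevant
    to that kind may be nonzero:

    * ``null`` — exposure and outcome mutually independent (a within-pair
      exposure correlation ``rho_x`` is permitted: correlated exposures
      with no outcome link are still a null world).
    * ``causal`` — exposures bivariate normal with correlation ``rho_x``;
      each outcome depends only on its owner's exposure via ``beta_causal``.
    * ``confounded`` — a pair-shared standard-normal factor loads on
      exposure (``confounder_loading_x``) and outcome
      (``confounder_loading_y``); no direct exposure→outcome path.
    * ``reverse`` — a continuous outcome liability is generated first
      (within-pair correlation ``rho_x``) and drives the exposure via
      ``beta_causal``.
    * ``mixed`` — both the causal path and the shared confounder.
    """

    kind: str
    n_pairs: int
    seed: int
    beta_causal: float = 0.0
    confounder_loading_x: float = 0.0
    confounder_loading_y: float = 0.0
    rho_x: float = 0.0
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    relationship: str = "MZ"

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(
                f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}"
            )
        for name in ("beta_causal", "confounder_loading_x", "confounder_loading_y",
                     "rho_x", "noise_sd_x", "noise_sd_y"):
            _check_finite(name, getattr(self, name))
        if abs(self.rho_x) > 1:
            raise ValueError(f"|rho_x| must be <= 1, got {self.rho_x}")
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_pairs <= 0:
            raise ValueError(f"n_pairs must be positive, got {self.n_pairs}")
        loadings = (self.confounder_loading_x, self.confounder_loading_y)
        if self.kind in ("null", "causal", "reverse") and any(loadings):
            raise ValueError(
                f"confounder loadings must be zero in a {self.kind!r} scenario"
            )
        if self.kind == "null" and self.beta_causal != 0:
            raise ValueError("beta_causal must be zero in a null scenario")
        if self.kind in ("confounded", "mixed"):
            if self.rho_x != 0:
                raise ValueError(
                    f"rho_x must be zero in a {self.kind!r} scenario; the "
                    "within-pair exposure correlation is induced by the shared factor"
                )
            if self.kind == "confounded" and self.beta_causal != 0:
                raise ValueError("beta_causal must be zero in a confounded scenario")


@dataclass(frozen=True)
class GenotypePanelSpec:
    """Specification of a genotype panel with an optional planted region.

    Genotypes are 0/1/2 allele dosages with block-wise linkage
    disequilibrium (copy-with-mutation within blocks of
    ``ld_block_size`` consecutive variants). The phenotype is Bernoulli
    from a logistic model whose linear predictor sums the planted
    variants' per-allele log odds ratios over centred dosages, so the
    marginal prevalence is approximately ``prevalence``.
    """

    n_samples: int
    n_variants: int
    seed: int
    planted_region: tuple[int, int] | None = None
    causal_log_or: float | tuple[float, ...] = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 10
    mutation_rate: float = 0.1
    prevalence: float = 0.5
    chrom: str = "1"
    spacing_bp: int = 1000

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ValueError("n_samples and n_variants must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi < 0.99):
            raise ValueError(f"maf_range must lie within (0.01, 0.99), got {self.maf_range}")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.planted_region is not None:
            start, end = self.planted_region
            if not (0 <= start <= end < self.n_variants):
                raise ValueError(
                    f"planted_region {self.planted_region} outside [0, {self.n_variants})"
                )

    @property
    def causal_betas(self) -> np.ndarray:
        """Per-variant log odds ratios over the planted region."""
        if self.planted_region is None:
            return np.zeros(0)
        start, end = self.planted_region
        width = end - start + 1
        betas = np.broadcast_to(np.asarray(self.causal_log_or, float), (width,))
        return np.array(betas)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _pair_frame(x_a, x_b, y_a, y_b, relationship: str) -> pd.DataFrame:
    n = len(x_a)
    pair_id = np.arange(n)
    frame = pd.DataFrame(
        {
            "pair_id": np.concatenate([pair_id, pair_id]),
            "relationship": relationship,
            "member": np.repeat(["A", "B"], n),
            "exposure": np.concatenate([x_a, x_b]),
            "outcome": np.concatenate([y_a, y_b]),
        }
    )
    return frame.sort_values(["pair_id", "member"], ignore_index=True)


def simulate_twin_pairs(
    params: RiskModelParams, on_overflow: str = "error"
) -> pd.DataFrame:
    """Simulate relative pairs under the multiplicative normal risk model.

    Scores ``(X_A, X_B)`` are bivariate standard normal with correlation
    ``r``; each member's disease indicator is Bernoulli with probability
    ``p0 * exp(delta * X - delta**2 / 2)``, whose expectation over a
    standard-normal score is exactly ``p0`` (the lognormal mean cancels
    the ``exp(delta**2 / 2)`` factor), so the marginal incidence equals
    ``baseline_incidence`` by construction.

    The multiplicative model can assign probability above 1 to extreme
    tail scores. By default this is a hard error; ``on_overflow="clip"``
    instead truncates those probabilities at 1 with a warning —
    appropriate for large rare-disease simulations where the clipped
    excess mass is many orders of magnitude below Monte-Carlo error.

    Returns a long-format table (one row per individual) with columns
    ``pair_id, relationship, member, exposure, outcome`` where
    ``exposure`` is the standardized score and ``outcome`` the disease
    indicator. The generating parameters are stored in
    ``result.attrs["params"]``.
    """
    if on_overflow not in ("error", "clip"):
        raise ValueError(f"on_overflow must be 'error' or 'clip', got {on_overflow!r}")
    rng = _rng(params.seed)
    n, r, d, p0 = params.n_pairs, params.r, params.delta, params.baseline_incidence
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x_a = z1
    x_b = r * z1 + math.sqrt(1.0 - r * r) * z2
    prob_a = p0 * np.exp(d * x_a - d * d / 2.0)
    prob_b = p0 * np.exp(d * x_b - d * d / 2.0)
    worst = max(prob_a.max(initial=0.0), prob_b.max(initial=0.0))
    if worst > 1.0:
        if on_overflow == "error":
            raise ValueError(
                "disease probability exceeds 1 for a sampled score "
                f"(max {worst:.4g}) with delta={d}, baseline_incidence={p0}; "
                "reduce delta or the baseline incidence, or pass "
                "on_overflow='clip'"
            )
        n_over = int((prob_a > 1).sum() + (prob_b > 1).sum())
        warnings.warn(
            f"clipped disease probability at 1 for {n_over} of {2 * n} "
            f"individuals (max {worst:.4g})",
            stacklevel=2,
        )
        prob_a = np.minimum(prob_a, 1.0)
        prob_b = np.minimum(prob_b, 1.0)
    y_a = (rng.random(n) < prob_a).astype(np.int64)
    y_b = (rng.random(n) < prob_b).astype(np.int64)
    out = _pair_frame(x_a, x_b, y_a, y_b, params.relationship)
    out.attrs["params"] = asdict(params)
    return out


def simulate_pair_scenario(scenario: SimScenario) -> pd.DataFrame:
    """Simulate relative pairs under a linear structural-equation world.

    Exposure and outcome are continuous; see :class:`SimScenario` for the
    structural model selected by ``scenario.kind``. The true parameters
    are stored in ``result.attrs["scenario"]``.
    """
    rng = _rng(scenario.seed)
    n = scenario.n_pairs
    sx, sy = scenario.noise_sd_x, scenario.noise_sd_y
    beta = scenario.beta_causal
    lx, ly = scenario.confounder_loading_x, scenario.confounder_loading_y
    rho = scenario.rho_x

    def correlated_pair(rho_: float):
        u = rng.standard_normal(n)
        v = rng.standard_normal(n)
        return u, rho_ * u + math.sqrt(1.0 - rho_ * rho_) * v

    kind = scenario.kind
    if kind == "null":
        x_a, x_b = correlated_pair(rho)
        y_a = sy * rng.standard_normal(n)
        y_b = sy * rng.standard_normal(n)
    elif kind == "causal":
        x_a, x_b = correlated_pair(rho)
        y_a = beta * x_a + sy * rng.standard_normal(n)
        y_b = beta * x_b + sy * rng.standard_normal(n)
    elif kind == "reverse":
        # Outcome liability first; exposure is downstream of it.
        y_a, y_b = correlated_pair(rho)
        x_a = beta * y_a + sx * rng.standard_normal(n)
        x_b = beta * y_b + sx * rng.standard_normal(n)
    elif kind == "confounded":
        f = rng.standard_normal(n)
        x_a = lx * f + sx * rng.standard_normal(n)
        x_b = lx * f + sx * rng.standard_normal(n)
        y_a = ly * f + sy * rng.standard_normal(n)
        y_b = ly * f + sy * rng.standard_normal(n)
    else:  # mixed
        f = rng.standard_normal(n)
        x_a = lx * f + sx * rng.standard_normal(n)
        x_b = lx * f + sx * rng.standard_normal(n)
        y_a = beta * x_a + ly * f + sy * rng.standard_normal(n)
        y_b = beta * x_b + ly * f + sy * rng.standard_normal(n)

    out = _pair_frame(x_a, x_b, y_a, y_b, scenario.relationship)
    out.attrs["scenario"] = asdict(scenario)
    return out


def simulate_fh_cohort(
    n: int,
    kind: str,
    seed: int,
    fh_quantile: float = 0.8,
    **scenario_params,
) -> pd.DataFrame:
    """Simulate unrelated probands with a family-history indicator.

    Each proband has one latent first-degree relative generated under
    the same structural model (see :class:`SimScenario`); the relative's
    outcome, dichotomised at its ``fh_quantile`` sample quantile, defines
    the binary family-history flag. Only the proband's exposure and
    outcome are observed.

    Returns a table with columns ``id, exposure, family_history,
    outcome``; ground truth (including the relative's latent values'
    generating scenario) is in ``result.attrs``.
    """
    if not 0 < fh_quantile < 1:
        raise ValueError(f"fh_quantile must lie in (0, 1), got {fh_quantile}")
    scenario = SimScenario(kind=kind, n_pairs=n, seed=seed, **scenario_params)
    pairs = simulate_pair_scenario(scenario)
    wide = pairs_to_wide(pairs)
    threshold = float(np.quantile(wide["outcome_B"], fh_quantile))
    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "exposure": wide["exposure_A"].to_numpy(),
            "family_history": (wide["outcome_B"].to_numpy() > threshold).astype(np.int64),
            "outcome": wide["outcome_A"].to_numpy(),
        }
    )
    table.attrs["scenario"] = asdict(scenario)
    table.attrs["fh_quantile"] = fh_quantile
    table.attrs["fh_threshold"] = threshold
    return table


def pairs_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long pair table to one row per pair.

    Columns become ``exposure_A, exposure_B, outcome_A, outcome_B`` (plus
    any extra covariates, suffixed likewise). Pairs missing either member
    are dropped with a logged count.
    """
    value_cols = [c for c in table.columns if c not in ("pair_id", "relationship", "member")]
    wide = table.pivot(index="pair_id", columns="member", values=value_cols)
    wide.columns = [f"{col}_{member}" for col, member in wide.columns]
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(f"dropped {dropped} pairs with a missing member", stacklevel=2)
    rel = table.drop_duplicates("pair_id").set_index("pair_id")["relationship"]
    complete = complete.join(rel)
    return complete.reset_index()


def empirical_frr(table: pd.DataFrame) -> tuple[float, float]:
    """Estimate the familial risk ratio from simulated pairs.

    Uses both orderings of each pair: with ``c`` the probability both
    members are affected and ``p`` the marginal incidence, the estimator
    is ``P(relative affected | index affected) / P(affected) = c / p**2``.
    Returns ``(frr, se)`` with the standard error from the multivariate
    delta method over the trinomial pair-outcome counts.

    Raises ``ValueError`` when no pair is concordant affected (the
    estimator is 0 and its log-scale error undefined).
    """
    wide = pairs_to_wide(table[PAIR_COLUMNS])
    ya = wide["outcome_A"].to_numpy()
    yb = wide["outcome_B"].to_numpy()
    n = len(wide)
    c_hat = float(np.mean(ya * yb))
    p_hat = float(np.mean((ya + yb) / 2.0))
    if c_hat == 0.0 or p_hat == 0.0:
        raise ValueError("no concordant affected pairs; FRR estimator degenerate")
    frr = c_hat / p_hat**2
    # Delta method: FRR = c / p^2 over the joint distribution of
    # (1[both affected], (y_A + y_B)/2) across pairs.
    var_c = c_hat * (1.0 - c_hat) / n
    var_p = (p_hat * (1.0 - p_hat) / 2.0 + (c_hat - p_hat**2) / 2.0) / n
    cov_cp = c_hat * (1.0 - p_hat) / n
    g_c = 1.0 / p_hat**2
    g_p = -2.0 * c_hat / p_hat**3
    var_frr = g_c**2 * var_c + g_p**2 * var_p + 2.0 * g_c * g_p * cov_cp
    return frr, math.sqrt(max(var_frr, 0.0))


# ---------------------------------------------------------------------------
# genotype panels


def _simulate_genotypes(spec: GenotypePanelSpec, rng: np.random.Generator):
    """Dosage matrix (n_samples, n_variants) with block-wise LD."""
    n, m = spec.n_samples, spec.n_variants
    lo, hi = spec.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    geno = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.binomial(2, freqs[j], size=n).astype(np.int8)
        if j % spec.ld_block_size == 0:
            geno[:, j] = fresh
        else:
            keep = rng.random(n) >= spec.mutation_rate
            geno[:, j] = np.where(keep, geno[:, j - 1], fresh)
    return geno, freqs


def _genotype_rows(geno_col: np.ndarray) -> list[str]:
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    return [gt[int(g)] for g in geno_col]


def simulate_panel_arrays(spec: GenotypePanelSpec) -> dict:
    """Generate a genotype panel in memory.

    Returns a dict with keys ``genotypes`` (n_samples × n_variants int8
    dosages), ``freqs``, ``status`` (0/1 phenotype), ``samples``,
    ``positions`` (1-based bp) and ``chrom``. The phenotype is Bernoulli
    with ``logit(p) = logit(prevalence) + sum_j beta_j * (g_j - 2*f_j)``
    over the planted variants, so disease risk is multiplicative in the
    planted dosages.
    """
    rng = _rng(spec.seed)
    geno, freqs = _simulate_genotypes(spec, rng)
    n, m = geno.shape

    eta = np.full(n, math.log(spec.prevalence / (1.0 - spec.prevalence)))
    if spec.planted_region is not None:
        start, end = spec.planted_region
        betas = spec.causal_betas
        centred = geno[:, start : end + 1] - 2.0 * freqs[start : end + 1]
        eta = eta + centred @ betas
    prob = 1.0 / (1.0 + np.exp(-eta))
    if prob.max() > 0.999 or prob.min() < 0.001:
        warnings.warn(
            "planted effects saturate the disease probability for some samples",
            stacklevel=2,
        )
    status = (rng.random(n) < prob).astype(np.int64)
    return {
        "genotypes": geno,
        "freqs": freqs,
        "status": status,
        "samples": [f"S{i:05d}" for i in range(n)],
        "positions": (np.arange(m) + 1) * spec.spacing_bp,
        "chrom": spec.chrom,
    }


def simulate_genotype_panel(
    spec: GenotypePanelSpec,
    vcf_path: str | Path,
    pheno_path: str | Path,
) -> tuple[Path, Path]:
    """Write a genotype panel (VCF v4.2, GT only) and phenotype file.

    See :func:`simulate_panel_arrays` for the generative model. Returns
    the two paths written; the phenotype file is two tab-separated
    columns ``sample_id, status``.
    """
    panel = simulate_panel_arrays(spec)
    geno, status = panel["genotypes"], panel["status"]
    samples, positions = panel["samples"], panel["positions"]
    m = geno.shape[1]
    vcf_path, pheno_path = Path(vcf_path), Path(pheno_path)
    with vcf_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={spec.chrom},length={int(positions[-1]) + spec.spacing_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(m):
            row = [
                spec.chrom,
                str(int(positions[j])),
                f"var{j}",
                "A",
                "G",
                ".",
                "PASS",
                ".",
                "GT",
            ] + _genotype_rows(geno[:, j])
            fh.write("\t".join(row) + "\n")
    with pheno_path.open("w") as fh:
        for sample, s in zip(samples, status):
            fh.write(f"{sample}\t{int(s)}\n")
    return vcf_path, pheno_path
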