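"""Sliding-window multi-variant association scan.

For each window of ``k`` consecutive variants (advanced by ``step``), a
logistic regression of case status on the window's genotype dosages is
compared with the intercept-only null model fitted on the same samples.
The window's SONAR (signal-over-noise associated with risk) score is the
BIC-approximated log10 Bayes factor in favour of the window model:

    sonar = (BIC_null - BIC_window) / (2 * ln 10)

so ``sonar = 1`` means roughly 10:1 odds for the window model after the
complexity penalty. Windows above a threshold are merged into risk-region
calls. This scoring is an explicit approximation: it reproduces the
published sliding-window/log-odds idea, not any particular tool's
internals.

Windows are defined in variant-index space; genomic coordinates are
reported from the first and last variant of the window (1-based,
inclusive). Missing genotypes are mean-imputed per variant; variants
monomorphic in the analysed samples are dropped from a window's design.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from cyvcf2 import VCF

__all__ = [
    "WindowScore",
    "RegionCall",
    "load_genotypes",
    "load_phenotype",
    "scan",
    "scan_matrix",
    "call_regions",
    "write_windows",
    "write_regions_bed",
]

logger = logging.getLogger(__name__)

LOG10_FACTOR = 2.0 * math.log(10.0)

WINDOW_COLUMNS = ["chrom", "start", "end", "n_variants", "sonar"]
REGION_COLUMNS = ["chrom", "start", "end", "peak_sonar", "n_windows"]


@dataclass(frozen=True)
class WindowScore:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_variants: int
    sonar: float


@dataclass(frozen=True)
class RegionCall:
    chrom: str
    start: int
    end: int
    peak_sonar: float
    n_windows: int


def load_phenotype(path: str | Path) -> pd.Series:
    """Two-column phenotype file (sample_id TAB status 0/1) -> Series."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "status"],
                        dtype={"sample_id": str})
    if not set(table["status"].unique()) <= {0, 1}:
        raise ValueError("phenotype status must be coded 0/1")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids in phenotype file")
    return table.set_index("sample_id")["status"]


def load_genotypes(path: str | Path):
    """Read a VCF into a dosage matrix.

    Returns ``(dosages, variants, samples)`` where ``dosages`` is
    (n_samples, n_variants) float with missing genotypes as NaN and
    ``variants`` a DataFrame of chrom/pos/id.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for v in vcf:
        gt = np.asarray(v.gt_types, dtype=float)
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dose)
        meta.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}"))
    vcf.close()
    if not rows:
        raise ValueError(f"no variants found in {path}")
    dosages = np.vstack(rows).T
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id"])
    return dosages, variants, samples


def _window_loglik(y: np.ndarray, G: np.ndarray) -> float | None:
    """Log-likelihood of the window logistic model, or None on failure."""
    X = np.column_stack([np.ones(len(y)), G])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="lbfgs")
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            return None  # quasi-separation
        return float(res.llf)
    except (np.linalg.LinAlgError, ValueError):
        return None


def scan(
    vcf_path: str | Path,
    pheno_path: str | Path,
    k: int = 5,
    step: int = 1,
) -> pd.DataFrame:
    """Score every window of ``k`` consecutive variants.

    Samples present in both the VCF and the phenotype file are analysed
    (the intersection is logged). Returns a DataFrame with columns
    ``chrom, start, end, n_variants, sonar`` in genomic order; windows
    whose model cannot be fitted (unresolvable separation) are skipped
    with a warning.
    """
    dosages, variants, samples = load_genotypes(vcf_path)
    pheno = load_phenotype(pheno_path)
    common = [s for s in samples if s in pheno.index]
    if len(common) < len(samples) or len(common) < len(pheno):
        logger.info(
            "analysing %d samples in the intersection of VCF (%d) and phenotype (%d)",
            len(common), len(samples), len(pheno),
        )
    if not common:
        raise ValueError("no samples shared between VCF and phenotype file")
    take = [samples.index(s) for s in common]
    G = dosages[take]
    y = pheno.loc[common].to_numpy(float)
    return scan_matrix(
        G, y, positions=variants["pos"].to_numpy(), chrom=variants["chrom"].to_numpy(),
        k=k, step=step,
    )


def scan_matrix(
    G: np.ndarray,
    y: np.ndarray,
    positions: np.ndarray | None = None,
    chrom: np.ndarray | str = "1",
    k: int = 5,
    step: int = 1,
) -> pd.DataFrame:
    """Score windows on an in-memory dosage matrix.

    ``G`` is (n_samples, n_variants), possibly with NaN for missing
    genotypes (mean-imputed per variant); ``positions`` are 1-based bp
    coordinates (variant index + 1 when omitted). The file-based
    :func:`scan` wraps this.
    """
    if k < 1 or step < 1:
        raise ValueError(f"window size and step must be >= 1, got k={k}, step={step}")
    G = np.array(G, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    if positions is None:
        positions = np.arange(1, G.shape[1] + 1)
    chrom_arr = np.broadcast_to(np.asarray(chrom, dtype=object), (G.shape[1],))
    variants = pd.DataFrame({"chrom": chrom_arr, "pos": np.asarray(positions)})

    # per-variant mean imputation of missing genotypes
    if np.isnan(G).any():
        col_means = np.nanmean(G, axis=0)
        nan_rows, nan_cols = np.nonzero(np.isnan(G))
        G[nan_rows, nan_cols] = col_means[nan_cols]

    n = len(y)
    p1 = y.mean()
    llf_null = n * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1))
    bic_null = -2.0 * llf_null + math.log(n)

    polymorphic = G.std(axis=0) > 0
    m = G.shape[1]
    records = []
    for start_idx in range(0, m - k + 1, step):
        idx = np.arange(start_idx, start_idx + k)
        keep = idx[polymorphic[idx]]
        if len(keep) < len(idx):
            logger.info(
                "window %d-%d: scoring over %d polymorphic of %d variants",
                start_idx, start_idx + k - 1, len(keep), len(idx),
            )
        if len(keep) == 0:
            warnings.warn(
                f"window at variant index {start_idx} is entirely monomorphic; skipped",
                stacklevel=2,
            )
            continue
        llf = _window_loglik(y, G[:, keep])
        if llf is None:
            warnings.warn(
                f"window at variant index {start_idx} skipped (separation or "
                "non-convergence)",
                stacklevel=2,
            )
            continue
        bic_window = -2.0 * llf + (len(keep) + 1) * math.log(n)
        records.append(
            {
                "chrom": variants.loc[idx[0], "chrom"],
                "start": int(variants.loc[idx[0], "pos"]),
                "end": int(variants.loc[idx[-1], "pos"]),
                "n_variants": int(len(keep)),
                "sonar": (bic_null - bic_window) / LOG10_FACTOR,
            }
        )
    return pd.DataFrame(records, columns=WINDOW_COLUMNS)


def call_regions(scores: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Merge above-threshold windows into non-overlapping region calls.

    Windows with ``sonar >= threshold`` that overlap or abut (next start
    <= current end + 1) on the same chromosome are merged; the peak
    sonar and the number of contributing windows are recorded. Input
    must be sorted by chromosome and start position.
    """
    required = set(WINDOW_COLUMNS)
    if not required <= set(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    for _, chunk in scores.groupby("chrom", sort=False):
        if not chunk["start"].is_monotonic_increasing:
            raise ValueError("window scores must be sorted by position within chromosome")
    hits = scores[scores["sonar"] >= threshold]
    regions: list[RegionCall] = []
    current = None
    for row in hits.itertuples():
        if (
            current is not None
            and row.chrom == current["chrom"]
            and row.start <= current["end"] + 1
        ):
            current["end"] = max(current["end"], row.end)
            current["peak_sonar"] = max(current["peak_sonar"], row.sonar)
            current["n_windows"] += 1
        else:
            if current is not None:
                regions.append(current)
            current = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "peak_sonar": row.sonar,
                "n_windows": 1,
            }
    if current is not None:
        regions.append(current)
    return pd.DataFrame(regions, columns=REGION_COLUMNS)


def write_windows(scores: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> Path:
    """Write region calls as BED6 (half-open, 0-based starts).

    The BED score column maps sonar onto 0-1000 as
    ``round(1000 * min(sonar, 3) / 3)``.
    """
    path = Path(path)
    with path.open("w") as fh:
        for i, row in enumerate(regions.itertuples()):
            score = int(round(1000 * min(max(row.peak_sonar, 0.0), 3.0) / 3.0))
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\tregion_{i + 1}\t"
                f"{score}\t.\n"
            )
    return path
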