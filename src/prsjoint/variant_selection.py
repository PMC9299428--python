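"""Variant QC and clumping + thresholding for PRS construction.

Implements the PLINK-style C+T workflow on dosage data: MAF / HWE /
call-rate filters, composite-LD r^2 on dosages, greedy window-based
clumping (smallest p first, ties broken by chromosome/position), nested
p-value threshold grids, and exclusion of the MHC region
(chr6:28,477,797-33,448,354, 1-based inclusive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError, ConfigurationError, InputError, LDUndefinedError
from .panel import GenotypePanel

logger = logging.getLogger(__name__)

MHC_CHROM = "6"
MHC_START = 28_477_797
MHC_END = 33_448_354

SUMMARY_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P")


@dataclass
class ClumpConfig:
    """LD-clumping and thresholding settings (PLINK --clump conventions)."""

    r2_threshold: float = 0.001
    window_bp: int = 1_000_000
    p_cutoffs: tuple[float, ...] = (5e-4, 5e-5, 5e-6, 5e-7, 5e-8)

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold < 1.0):
            raise ConfigurationError("r2_threshold must be in (0,1)")
        if self.window_bp <= 0:
            raise ConfigurationError("window_bp must be positive")
        if list(self.p_cutoffs) != sorted(self.p_cutoffs, reverse=True):
            raise ConfigurationError("p_cutoffs must be strictly decreasing")
        if len(set(self.p_cutoffs)) != len(self.p_cutoffs):
            raise ConfigurationError("p_cutoffs must be strictly decreasing")

    def labels(self) -> list[str]:
        return [f"p<{c:g}" for c in self.p_cutoffs]


# ----------------------------------------------------------------------
# QC filters
# ----------------------------------------------------------------------

def hardy_weinberg_chi2(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    ``n_aa`` counts homozygotes for one allele, ``n_ab`` heterozygotes and
    ``n_bb`` the other homozygote.  Expected counts are p^2, 2pq, q^2 at the
    sample allele frequency; returns ``(statistic, upper-tail p)``.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise InputError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise InputError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def maf_hwe_missingness_filter(
    panel: GenotypePanel,
    maf_min: float = 0.02,
    hwe_p_min: float = 1e-7,
    call_rate_min: float = 0.95,
) -> GenotypePanel:
    """Retain variants with MAF > maf_min, HWE p > hwe_p_min and call rate
    >= call_rate_min (all inequalities per the published QC thresholds;
    MAF strictly greater).  Variant order is preserved; idempotent.
    """
    for name, v in {"maf_min": maf_min, "hwe_p_min": hwe_p_min, "call_rate_min": call_rate_min}.items():
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{name}={v} outside [0,1]")
    if panel.n_variants == 0:
        raise InputError("empty panel")

    maf = panel.observed_maf()
    call = panel.call_rate()
    hwe_p = np.ones(panel.n_variants)
    for j in range(panel.n_variants):
        n2, n1, n0 = panel.genotype_counts(j)
        if n2 + n1 + n0 > 0:
            hwe_p[j] = hardy_weinberg_chi2(n2, n1, n0)[1]
    keep = (maf > maf_min) & (hwe_p > hwe_p_min) & (call >= call_rate_min)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("QC filter removed %d of %d variants", dropped, panel.n_variants)
    return panel.subset_mask(keep)


# ----------------------------------------------------------------------
# LD
# ----------------------------------------------------------------------

def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are handled pairwise-complete.  Constant vectors raise
    :class:`LDUndefinedError` (clumping treats that as r^2 = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InputError("dosage vectors must share a length >= 2")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise LDUndefinedError("fewer than 2 pairwise-complete observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise LDUndefinedError("constant dosage vector has undefined LD")
    r = float(xc @ yc) / np.sqrt(sx * sy)
    return min(r * r, 1.0)


def _pairwise_r2(panel_col: np.ndarray, others: np.ndarray) -> np.ndarray:
    """r^2 of one dosage column against many, NaN-aware, vectorised."""
    x = panel_col.astype(float)
    Y = others.astype(float)
    if np.isnan(x).any() or np.isnan(Y).any():
        out = np.empty(Y.shape[1])
        for j in range(Y.shape[1]):
            try:
                out[j] = ld_r2(x, Y[:, j])
            except LDUndefinedError:
                out[j] = 0.0
        return out
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = float(xc @ xc)
    sy = np.einsum("ij,ij->j", Yc, Yc)
    num = xc @ Yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((sy > 0) & (sx > 0), (num * num) / (sx * sy), 0.0)
    return np.minimum(r2, 1.0)


# ----------------------------------------------------------------------
# clumping and thresholding
# ----------------------------------------------------------------------

def clump(stats: pd.DataFrame, panel: GenotypePanel, cfg: ClumpConfig | None = None) -> list[str]:
    """Greedy LD clumping; returns index-variant ids in selection order.

    Repeatedly takes the smallest-p unassigned variant as the index and
    assigns every unassigned variant on the same chromosome within
    ``window_bp`` whose dosage r^2 with the index reaches ``r2_threshold``.
    Ties in p are broken by (chrom, pos).  Variants in ``stats`` that are
    missing from the panel are dropped with a warning.
    """
    cfg = cfg or ClumpConfig()
    lookup = pd.Index(panel.variants["id"])
    col = lookup.get_indexer(stats["SNP"])
    present = col >= 0
    if not present.all():
        warnings.warn(
            f"{int((~present).sum())} summary-stat variants absent from the LD "
            "reference panel were dropped",
            stacklevel=2,
        )
    if not present.any():
        raise AlignmentError("no summary-stat variants present in the panel")
    st = stats.loc[present].reset_index(drop=True)
    col = col[present]

    order = np.lexsort(
        (st["BP"].to_numpy(), st["CHR"].astype(str).to_numpy(), st["P"].to_numpy())
    )
    chrom = st["CHR"].astype(str).to_numpy()
    pos = st["BP"].to_numpy()
    assigned = np.zeros(len(st), dtype=bool)
    result: list[str] = []
    kept_rows: list[int] = []

    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        result.append(st.at[i, "SNP"])
        kept_rows.append(i)
        near = (
            ~assigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= cfg.window_bp)
        )
        cand = np.flatnonzero(near)
        if cand.size:
            r2 = _pairwise_r2(panel.dosages[:, col[i]], panel.dosages[:, col[cand]])
            assigned[cand[r2 >= cfg.r2_threshold]] = True

    _assert_clump_independence(st.iloc[kept_rows], panel, col[kept_rows], cfg)
    return result


def _assert_clump_independence(
    kept: pd.DataFrame, panel: GenotypePanel, cols: np.ndarray, cfg: ClumpConfig
) -> None:
    """Post-hoc invariant: no two survivors within the window share r^2 >= threshold."""
    chrom = kept["CHR"].astype(str).to_numpy()
    pos = kept["BP"].to_numpy()
    for a in range(len(kept)):
        near = np.flatnonzero(
            (chrom == chrom[a]) & (np.abs(pos - pos[a]) <= cfg.window_bp)
        )
        near = near[near > a]
        if near.size:
            r2 = _pairwise_r2(panel.dosages[:, cols[a]], panel.dosages[:, cols[near]])
            if (r2 >= cfg.r2_threshold).any():
                raise AssertionError("clump survivors violate the r^2 independence invariant")


def apply_thresholds(
    clumped_stats: pd.DataFrame, cfg: ClumpConfig | None = None
) -> dict[float, list[str]]:
    """Per-cutoff retained variant ids (strictly ``P < cutoff``); nested by design."""
    cfg = cfg or ClumpConfig()
    out: dict[float, list[str]] = {}
    for c in cfg.p_cutoffs:
        out[c] = clumped_stats.loc[clumped_stats["P"] < c, "SNP"].tolist()
    return out


def exclude_mhc(
    stats: pd.DataFrame,
    mhc_chrom: str = MHC_CHROM,
    mhc_start: int = MHC_START,
    mhc_end: int = MHC_END,
) -> pd.DataFrame:
    """Drop variants inside the MHC window (1-based inclusive bounds)."""
    if mhc_start > mhc_end:
        raise ConfigurationError("mhc_start > mhc_end")
    chrom = stats["CHR"].astype(str).str.removeprefix("chr")
    target = str(mhc_chrom).removeprefix("chr")
    inside = (chrom == target) & (stats["BP"] >= mhc_start) & (stats["BP"] <= mhc_end)
    return stats.loc[~inside].reset_index(drop=True)


def mhc_mask(stats: pd.DataFrame) -> np.ndarray:
    """Boolean mask of variants inside the default MHC window."""
    chrom = stats["CHR"].astype(str).str.removeprefix("chr")
    return (
        (chrom == MHC_CHROM) & (stats["BP"] >= MHC_START) & (stats["BP"] <= MHC_END)
    ).to_numpy()


# ----------------------------------------------------------------------
# allele harmonisation
# ----------------------------------------------------------------------

def harmonize_weights(stats: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Align summary-stat effect alleles with the panel's counted allele.

    If the stats' A1/A2 are swapped relative to the panel, the beta sign is
    flipped; allele pairs that do not match either way are dropped with a
    warning.  Same-strand files are assumed (no strand flipping).
    """
    pv = panel.variants.set_index("id")
    merged = stats.merge(
        pv[["a1", "a2"]], left_on="SNP", right_index=True, how="inner"
    )
    if len(merged) < len(stats):
        warnings.warn(
            f"{len(stats) - len(merged)} weight variants absent from panel were dropped",
            stacklevel=2,
        )
    same = (merged["A1"] == merged["a1"]) & (merged["A2"] == merged["a2"])
    swapped = (merged["A1"] == merged["a2"]) & (merged["A2"] == merged["a1"])
    bad = ~(same | swapped)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} weight variants with mismatched allele pairs were dropped",
            stacklevel=2,
        )
    out = merged.loc[~bad].copy()
    out.loc[swapped[~bad].to_numpy(), "BETA"] *= -1.0
    out["A1"] = out["a1"]
    out["A2"] = out["a2"]
    return out.drop(columns=["a1", "a2"]).reset_index(drop=True)
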