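"""In-memory containers for genotype dosages and per-individual risk scores.

The dosage matrix is individuals x variants with values in [0, 2]
(hard-called dosages are exactly 0/1/2); missing entries are NaN, so the
matrix is kept in float32.  Variant metadata travels alongside the matrix
in a DataFrame with one row per column of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError

#: required columns of the variant metadata table
VARIANT_COLUMNS = ("id", "chrom", "pos", "a1", "a2", "maf")


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant metadata and individual identifiers.

    Parameters
    ----------
    individual_ids:
        Array of unique individual identifiers (length n).
    variants:
        DataFrame with columns ``id, chrom, pos, a1, a2, maf``; ``a1`` is the
        counted (effect) allele of the dosage column.
    dosages:
        ``(n_individuals, n_variants)`` float array, NaN marks a missing call.
    """

    individual_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.individual_ids), len(self.variants)):
            raise AlignmentError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.variants)} variants"
            )
        if self.variants["id"].duplicated().any():
            raise AlignmentError("variant ids are not unique")
        if len(np.unique(self.individual_ids)) != len(self.individual_ids):
            raise AlignmentError("individual ids are not unique")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column_index(self, variant_ids) -> np.ndarray:
        """Positions of ``variant_ids`` in the panel; raises if any are absent."""
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(list(variant_ids))
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise AlignmentError(f"variants absent from panel: {missing[:5]}...")
        return idx

    def dosage_for(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.column_index([variant_id])[0]]

    def subset_variants(self, variant_ids) -> "GenotypePanel":
        idx = self.column_index(variant_ids)
        return GenotypePanel(
            individual_ids=self.individual_ids,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_mask(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            individual_ids=self.individual_ids,
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    # -- per-variant QC statistics --------------------------------------
    def observed_maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per variant (missing ignored)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def allele_frequency(self) -> np.ndarray:
        """Counted-allele frequency per variant (not folded to minor)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """Hard-call genotype counts (n_AA, n_Aa, n_aa) for column ``j``."""
        col = self.dosages[:, j]
        col = col[~np.isnan(col)]
        g = np.rint(col).astype(int)
        return int(np.sum(g == 2)), int(np.sum(g == 1)), int(np.sum(g == 0))


@dataclass
class PRSVector:
    """Raw and standardised polygenic risk scores for one p-value threshold."""

    individual_ids: np.ndarray
    raw: np.ndarray
    n_variants_used: int
    threshold_label: str
    standardized: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != self.individual_ids.shape:
            raise AlignmentError("raw score length does not match individual ids")

    def with_standardized(self, z: np.ndarray) -> "PRSVector":
        return replace(self, standardized=np.asarray(z, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"IID": self.individual_ids, "RAW": self.raw})
        if self.standardized is not None:
            out["Z"] = self.standardized
        out["K"] = self.n_variants_used
        out["THRESHOLD"] = self.threshold_label
        return out
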