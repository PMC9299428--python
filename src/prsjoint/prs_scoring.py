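"""Per-individual polygenic risk scores, standardisation and risk groups.

The score is the unnormalised weighted allele count
``PRS_i = sum_k X_ik * beta_hat_k`` (no division by the number of SNPs).
Standardisation is to mean 0 / SD 1 over a reference population (the whole
cohort by default).  Genetic-risk groups follow the quartile convention:
bottom quartile = low, quartiles 2-3 = intermediate, top quartile = high;
deciles use ten equal-probability bins.  Quantiles are type-7 (linear
interpolation) and individuals exactly at a cut point go to the lower group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateScoreError, InputError
from .panel import GenotypePanel, PRSVector

RISK_GROUPS = ("low", "intermediate", "high")


def score(panel: GenotypePanel, weights: pd.DataFrame, threshold_label: str = "") -> PRSVector:
    """Weighted dosage sum over the weight variants.

    ``weights`` must already be harmonised to the panel's counted alleles
    (see :func:`prsjoint.variant_selection.harmonize_weights`).  Missing
    dosages are mean-imputed (2 x empirical allele frequency).
    """
    if len(weights) == 0:
        raise InputError("PRS requires at least one weight variant")
    sub = panel.subset_variants(weights["SNP"])
    dos = sub.dosages.astype(float)
    if np.isnan(dos).any():
        fill = 2.0 * np.nan_to_num(np.nanmean(dos, axis=0) / 2.0, nan=0.0)
        dos = np.where(np.isnan(dos), fill, dos)
    raw = dos @ weights["BETA"].to_numpy(dtype=float)
    return PRSVector(
        individual_ids=panel.individual_ids,
        raw=raw,
        n_variants_used=len(weights),
        threshold_label=threshold_label,
    )


def standardize(prs: PRSVector, reference_ids=None) -> PRSVector:
    """Z-score the raw PRS against a reference population.

    The reference defaults to the entire score population (the convention
    used for the published scores); the mean/SD (sample SD, ddof=1) are
    computed on the reference and applied to everyone.
    """
    if reference_ids is None:
        ref = np.ones(len(prs.raw), dtype=bool)
    else:
        ref = np.isin(prs.individual_ids, np.asarray(list(reference_ids)))
        if not ref.any():
            raise InputError("reference population is empty")
    mu = prs.raw[ref].mean()
    sd = prs.raw[ref].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateScoreError("constant PRS cannot be standardized")
    return prs.with_standardized((prs.raw - mu) / sd)


def _scores_of(prs) -> np.ndarray:
    if isinstance(prs, PRSVector):
        return prs.standardized if prs.standardized is not None else prs.raw
    return np.asarray(prs, dtype=float)


def assign_risk_groups(prs) -> np.ndarray:
    """Quartile-based low / intermediate / high labels.

    Cut points are the 25th and 75th type-7 percentiles; scores exactly at
    a cut point fall into the lower group.  With fewer than 4 individuals
    the quartiles are undefined and an error is raised; fully tied scores
    all land in "low" with a warning.
    """
    x = _scores_of(prs)
    if len(x) < 4:
        raise InputError("risk groups require at least 4 individuals")
    q25, q75 = np.quantile(x, [0.25, 0.75])  # type-7 linear interpolation
    if q25 == q75 and np.all(x == x[0]):
        warnings.warn("all scores tied; everyone assigned to the low group", stacklevel=2)
    out = np.full(len(x), "intermediate", dtype=object)
    out[x <= q25] = "low"
    out[x > q75] = "high"
    return out


def assign_deciles(prs) -> np.ndarray:
    """Decile labels 1..10 with the same quantile/tie conventions."""
    x = _scores_of(prs)
    if len(x) < 10:
        raise InputError("deciles require at least 10 individuals")
    cuts = np.quantile(x, np.arange(0.1, 1.0, 0.1))
    # score exactly at a cut goes to the lower decile
    return 1 + np.sum(x[:, None] > cuts[None, :], axis=1)


def risk_group_frame(prs: PRSVector) -> pd.DataFrame:
    """Tidy per-individual table: IID, RAW, Z, GROUP, DECILE."""
    out = prs.to_frame()
    out["GROUP"] = assign_risk_groups(prs)
    out["DECILE"] = assign_deciles(prs)
    return out
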