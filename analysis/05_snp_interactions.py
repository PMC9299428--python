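#!/usr/bin/env python
"""Per-SNP lifestyle-interaction scan over the selected PRS variants.

For each variant in the selected score, fits the logistic model with a
dosage-by-lifestyle product term (unfavorable-lifestyle indicator) on the
test split and reports the product-term Wald p, sorted ascending.

Output: results/snp_lifestyle_scan.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, demo_config, write_table

from prsjoint import (
    build_covariates,
    derive_profile,
    io,
    snp_lifestyle_scan,
    split_cohort,
)
from prsjoint.panel import GenotypePanel


def main() -> None:
    cfg = demo_config()
    cohort = io.read_cohort(DATA_DIR / "cohort.csv")
    panel = io.read_panel(DATA_DIR / "dosages.raw", DATA_DIR / "variants.tsv")
    weights = pd.read_csv(DATA_DIR / "selected_weights.tsv", sep="\t")

    profile = derive_profile(cohort, cfg.lifestyle)
    split = split_cohort(cohort["iid"].to_numpy(), cfg.train_fraction, cfg.split_seed)
    test = ~np.isin(cohort["iid"].to_numpy(), split.train_ids)
    idx3 = profile["index_3"].to_numpy(float)
    ok = test & ~np.isnan(idx3)

    sub = panel.subset_variants(weights["SNP"])
    sub = GenotypePanel(
        individual_ids=sub.individual_ids[ok],
        variants=sub.variants,
        dosages=sub.dosages[ok],
    )
    scan = snp_lifestyle_scan(
        sub,
        (idx3[ok] <= 1).astype(float),
        cohort["status"].to_numpy(float)[ok],
        build_covariates(cohort).loc[ok].reset_index(drop=True),
    )
    path = write_table(scan, "snp_lifestyle_scan.tsv")
    nominal = int((scan["p"] < 0.05).sum())
    print(f"scanned {len(scan)} variants; {nominal} with nominal p<0.05 -> {path}")


if __name__ == "__main__":
    main()
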