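#!/usr/bin/env python
"""Derive lifestyle indicators and estimate their associations with disease.

Reads the demo cohort, derives the five indicators and the three-factor
index, reports indicator prevalences (results/lifestyle_prevalence.tsv)
and covariate-adjusted per-factor and per-category odds ratios on the 80%
test split (results/lifestyle_assoc.tsv).
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
    fit_logistic,
    io,
    split_cohort,
)


def main() -> None:
    cfg = demo_config()
    cohort = io.read_cohort(DATA_DIR / "cohort.csv")
    profile = derive_profile(cohort, cfg.lifestyle)

    prev = pd.DataFrame(
        {
            "factor": profile.columns[:5],
            "prevalence": [profile[c].mean() for c in profile.columns[:5]],
            "n_missing": [int(profile[c].isna().sum()) for c in profile.columns[:5]],
        }
    )
    write_table(prev, "lifestyle_prevalence.tsv")
    print(prev.to_string(index=False))

    split = split_cohort(cohort["iid"].to_numpy(), cfg.train_fraction, cfg.split_seed)
    test = ~np.isin(cohort["iid"].to_numpy(), split.train_ids)
    covs = build_covariates(cohort).loc[test].reset_index(drop=True)
    y = cohort["status"].to_numpy(float)[test]

    rows = []
    for factor in profile.columns[:5]:
        X = covs.copy()
        X["factor"] = profile[factor].to_numpy(float)[test]
        t = fit_logistic(X, y).table().set_index("term").loc["factor"]
        rows.append({"term": factor, "or": t["estimate"], "ci_low": t["ci_low"],
                     "ci_high": t["ci_high"], "p": t["p"]})

    cat = profile["category"].to_numpy(object)[test]
    for level in ("moderate", "unfavorable"):
        X = covs.copy()
        X["moderate"] = (cat == "moderate").astype(float)
        X["unfavorable"] = (cat == "unfavorable").astype(float)
        t = fit_logistic(X, y).table().set_index("term").loc[level]
        rows.append({"term": f"{level}_vs_favorable", "or": t["estimate"],
                     "ci_low": t["ci_low"], "ci_high": t["ci_high"], "p": t["p"]})

    table = pd.DataFrame(rows)
    path = write_table(table, "lifestyle_assoc.tsv")
    print(table.to_string(index=False))
    print(f"-> {path}")


if __name__ == "__main__":
    main()
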