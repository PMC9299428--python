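#!/usr/bin/env python
"""QC, clump and threshold the discovery statistics; score and select the PRS.

Reads the inputs written by 01_simulate.py, applies MAF/HWE/call-rate
filters, LD-clumps against the dosage panel (r^2 0.001, 1 Mb window),
builds the five candidate scores (p < 5e-4 ... 5e-8), standardises them
over the whole cohort, and selects the best threshold on the 20% training
split by covariate-adjusted association (AUC as tie-break).

Outputs: results/prs_selection.tsv (the audit table) and per-individual
scores for the chosen threshold in scratch/demo/scores.tsv.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, demo_config, write_table

from prsjoint import (
    apply_thresholds,
    build_covariates,
    clump,
    harmonize_weights,
    io,
    maf_hwe_missingness_filter,
    risk_group_frame,
    score,
    select_best_prs,
    split_cohort,
    standardize,
)


def main() -> None:
    cfg = demo_config()
    panel = io.read_panel(DATA_DIR / "dosages.raw", DATA_DIR / "variants.tsv")
    stats = io.read_summary_stats(DATA_DIR / "summary_stats.tsv")
    cohort = io.read_cohort(DATA_DIR / "cohort.csv")

    panel = maf_hwe_missingness_filter(panel, cfg.maf_min, cfg.hwe_p_min, cfg.call_rate_min)
    stats = harmonize_weights(stats, panel)
    kept = clump(stats, panel, cfg.clump)
    clumped = stats[stats["SNP"].isin(kept)].reset_index(drop=True)
    grids = apply_thresholds(clumped, cfg.clump)
    print(f"QC kept {panel.n_variants} variants; clumping kept {len(clumped)} index variants")
    for c, ids in grids.items():
        print(f"  p<{c:g}: {len(ids)} variants")

    candidates, weights = {}, {}
    for cutoff, label in zip(cfg.clump.p_cutoffs, cfg.clump.labels()):
        if not grids[cutoff]:
            continue
        w = clumped[clumped["SNP"].isin(grids[cutoff])]
        candidates[label] = standardize(score(panel, w, threshold_label=label))
        weights[label] = w

    split = split_cohort(cohort["iid"].to_numpy(), cfg.train_fraction, cfg.split_seed)
    in_train = np.isin(cohort["iid"].to_numpy(), split.train_ids)
    covs = build_covariates(cohort)
    best, table = select_best_prs(
        cohort["status"].to_numpy(float)[in_train],
        {lab: prs.standardized[in_train] for lab, prs in candidates.items()},
        covs.loc[in_train],
    )
    table["n_variants"] = [len(weights[lab]) for lab in table["threshold"]]
    path = write_table(table, "prs_selection.tsv")
    print(f"selected threshold: {best} ({len(weights[best])} variants); table -> {path}")

    frame = risk_group_frame(candidates[best])
    io.write_scores(frame, DATA_DIR / "scores.tsv", seed=cfg.sim.seed)
    weights[best].to_csv(DATA_DIR / "selected_weights.tsv", sep="\t", index=False)
    print(f"scores for {len(frame)} individuals -> {DATA_DIR / 'scores.tsv'}")


if __name__ == "__main__":
    main()
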