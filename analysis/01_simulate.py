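#!/usr/bin/env python
"""Simulate the demo cohort and write every pipeline input to scratch/demo.

Outputs: discovery summary statistics (TSV), dosage panel (.raw + variant
table), cohort table (CSV: outcomes, covariates, raw lifestyle fields) and
the generative ground truth (JSON).  A Table-1-style summary of the cohort
goes to results/cohort_summary.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, SEED, demo_config, write_table

from prsjoint import cohort_summary, io, simulate_all


def main() -> None:
    cfg = demo_config()
    bundle = simulate_all(cfg.sim)

    DATA_DIR.mkdir(parents=True, exist_ok=True)
    io.write_summary_stats(bundle.summary_stats, DATA_DIR / "summary_stats.tsv")
    io.write_panel(bundle.panel, DATA_DIR / "dosages.raw", DATA_DIR / "variants.tsv", seed=SEED)
    io.write_cohort(bundle.cohort, DATA_DIR / "cohort.csv")
    io.write_ground_truth(bundle.truth, DATA_DIR / "ground_truth.json", seed=SEED)

    summary = cohort_summary(bundle.cohort)
    path = write_table(summary.table(), "cohort_summary.tsv")

    print(f"simulated {bundle.panel.n_individuals} individuals x {bundle.panel.n_variants} variants")
    print(f"cases: {summary.counts['cases']} ({summary.percent('case_percent')}%), "
          f"incident {summary.counts['followup_onset']} "
          f"({summary.percent('incident_case_percent')}%)")
    print(f"true OR per PRS SD: {bundle.truth.true_or_per_sd}")
    print(f"wrote inputs to {DATA_DIR} and summary to {path}")


if __name__ == "__main__":
    main()
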