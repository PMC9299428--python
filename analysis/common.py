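"""Shared configuration for the numbered analysis drivers.

The demo cohort (20,000 individuals, 2,000 variants) is simulated once by
``01_simulate.py`` into ``scratch/demo/`` (raw inputs; not tracked) and the
drivers write their small result tables under ``results/``.
"""

from pathlib import Path

from prsjoint import ClumpConfig, PipelineConfig, SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "demo"
RESULTS_DIR = ROOT / "results"

SEED = 20220706


def demo_config() -> PipelineConfig:
    return PipelineConfig(
        sim=SimulationConfig(n_individuals=20_000, n_variants=2_000, seed=SEED),
        clump=ClumpConfig(),
    )


def write_table(df, name: str) -> Path:
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    path = RESULTS_DIR / name
    with open(path, "w") as fh:
        fh.write(f"# prsjoint analysis seed={SEED}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return path
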