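import numpy as np
import pandas as pd
import pytest

from prsjoint import SimulationConfig, simulate_all
from prsjoint.panel import GenotypePanel


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # elevated prevalence keeps small-cohort fits well-conditioned
    return SimulationConfig(
        n_individuals=4_000,
        n_variants=300,
        block_size=10,
        n_causal=20,
        baseline_prevalence=0.02,
        baseline_hazard=4e-3,
        seed=20220706,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_all(small_config)


def make_panel(dosages, chrom=None, pos=None, ids=None, maf=None) -> GenotypePanel:
    """Hand-rolled panel for unit tests."""
    dosages = np.asarray(dosages, dtype=np.float32)
    n, m = dosages.shape
    ids = ids or [f"v{j}" for j in range(m)]
    chrom = chrom or ["1"] * m
    pos = pos if pos is not None else (np.arange(m) * 10_000 + 1)
    with np.errstate(invalid="ignore"):
        emp = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": ["A"] * m,
            "a2": ["G"] * m,
            "maf": maf if maf is not None else np.minimum(emp, 1 - emp),
        }
    )
    return GenotypePanel(
        individual_ids=np.array([f"i{k}" for k in range(n)]),
        variants=variants,
        dosages=dosages,
    )


def make_stats(ids, p, chrom=None, pos=None, beta=None) -> pd.DataFrame:
    m = len(ids)
    return pd.DataFrame(
        {
            "SNP": ids,
            "CHR": chrom or ["1"] * m,
            "BP": pos if pos is not None else (np.arange(m) * 10_000 + 1),
            "A1": ["A"] * m,
            "A2": ["G"] * m,
            "BETA": beta if beta is not None else np.ones(m) * 0.1,
            "SE": np.ones(m) * 0.02,
            "P": p,
        }
    )
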