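"""Plain-text readers and writers for the pipeline's file formats.

* summary statistics: tab-separated ``SNP CHR BP A1 A2 BETA SE P``;
* dosages: PLINK ``.raw``-style TSV (``FID IID`` then one ``<snp>_<A1>``
  column per variant, dosage counted for A1) plus a companion variant
  table (``SNP CHR BP A1 A2 MAF``) carrying the metadata ``.raw`` lacks;
* cohort: CSV with the column dictionary documented in the README;
* ground truth: JSON.

Every writer puts a ``# prsjoint ... seed=<seed>`` header line first so
each artefact records its provenance; readers skip ``#`` comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .synthetic_cohort import GroundTruth

_FLOAT_FMT = "%.10g"


def _write_with_header(df: pd.DataFrame, path, kind: str, seed, sep: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# prsjoint {kind} seed={seed}\n")
        df.to_csv(fh, sep=sep, index=False, float_format=_FLOAT_FMT)


def write_summary_stats(stats: pd.DataFrame, path, seed=None) -> None:
    seed = stats.attrs.get("seed", seed)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# prsjoint summary-stats seed={seed}\n")
        fh.write(
            f"# discovery_n={stats.attrs.get('discovery_n', 'NA')} "
            f"case_fraction={stats.attrs.get('case_fraction', 'NA')}\n"
        )
        stats.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str})
    return df


def write_panel(panel: GenotypePanel, raw_path, variants_path, seed=None) -> None:
    cols = {
        f"{vid}_{a1}": panel.dosages[:, j]
        for j, (vid, a1) in enumerate(zip(panel.variants["id"], panel.variants["a1"]))
    }
    raw = pd.DataFrame({"FID": panel.individual_ids, "IID": panel.individual_ids, **cols})
    _write_with_header(raw, raw_path, "dosages", seed, sep="\t")

    var = panel.variants.rename(
        columns={"id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2", "maf": "MAF"}
    )
    _write_with_header(var, variants_path, "variants", seed, sep="\t")


def read_panel(raw_path, variants_path) -> GenotypePanel:
    raw = pd.read_csv(raw_path, sep="\t", comment="#")
    var = pd.read_csv(variants_path, sep="\t", comment="#", dtype={"CHR": str})
    dose_cols = [c for c in raw.columns if c not in ("FID", "IID")]
    ids_in_header = [c.rsplit("_", 1)[0] for c in dose_cols]
    variants = var.rename(
        columns={"SNP": "id", "CHR": "chrom", "BP": "pos", "A1": "a1", "A2": "a2", "MAF": "maf"}
    )
    order = pd.Index(ids_in_header).get_indexer(variants["id"])
    dosages = raw[dose_cols].to_numpy(dtype=np.float32)[:, order]
    return GenotypePanel(
        individual_ids=raw["IID"].astype(str).to_numpy(),
        variants=variants,
        dosages=dosages,
    )


def write_cohort(cohort: pd.DataFrame, path, seed=None) -> None:
    seed = cohort.attrs.get("seed", seed)
    _write_with_header(cohort, path, "cohort", seed, sep=",")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ground_truth(truth: GroundTruth, path, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"seed": seed, **truth.to_dict()}
    path.write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_scores(frame: pd.DataFrame, path, seed=None) -> None:
    _write_with_header(frame, path, "scores", seed, sep="\t")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
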