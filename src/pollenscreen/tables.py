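"""Tab-delimited output helpers with provenance headers.

Every table written by the pipeline carries a comment line recording the
tool version, a hash of the run configuration and the seed, so outputs are
traceable to the run that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .expr_model import ExpressionDataset, ProbeAnnotation


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps({k: repr(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance_line(config: Mapping[str, Any] | None = None, seed: int | None = None) -> str:
    h = config_hash(config) if config else "none"
    return f"# pollenscreen v{__version__} | config_hash={h} | seed={seed}"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        handle.write(provenance_line(config, seed) + "\n")
        df.to_csv(handle, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_gene_list(genes, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(sorted(genes)) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_expression_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    calls_path: str | Path,
    design_path: str | Path,
) -> None:
    """Write a dataset in exactly the format the readers consume."""
    dataset.intensity.rename_axis("probe_id").to_csv(matrix_path, sep="\t")
    dataset.calls.rename_axis("probe_id").to_csv(calls_path, sep="\t")
    rows = [
        {"sample": s, "tissue": t, "replicate": r, "role": dataset.design.roles[t]}
        for s, t, r in dataset.design.samples
    ]
    pd.DataFrame(rows).to_csv(design_path, sep="\t", index=False)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.rename_axis("probe_id").to_csv(path, sep="\t")
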