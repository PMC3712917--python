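"""TSV readers and writers for the pipeline's table dialects.

All stage inputs and outputs are plain tab-separated text: a counts table
(protein_id plus one column per run), a run design (run_id, condition,
replicate), a gene x array expression matrix, an adjacent-gene-pair table
in genome order, and a long-format metabolite peak table.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_counts",
    "read_design",
    "read_expression",
    "read_pairs",
    "read_metabolite_table",
    "write_tsv",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "protein_id" not in df.columns:
        raise ValueError(f"{path}: counts table needs a 'protein_id' column")
    return df.set_index("protein_id")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"run_id", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: design needs columns {sorted(required)}")
    return df.set_index("run_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: expression matrix needs a 'gene_id' column")
    return df.set_index("gene_id")


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"upstream_gene", "downstream_gene", "prediction_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pair table needs columns {sorted(required)}")
    return df


def read_metabolite_table(path: str | Path) -> pd.DataFrame:
    from .metabolites import REQUIRED_COLUMNS

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metabolite table is missing columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
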