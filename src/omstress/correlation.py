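"""Transcript-protein fold-change correlation.

Matches per-gene log2 protein ratios with log2 transcript ratios and
quantifies their agreement as the squared Pearson correlation (R²),
stratified the way integrated-omics studies usually report it: starting
from the significant proteins (direction 1), from the significant genes
(direction 2), or requiring significance on both sides (direction 3), each
optionally filtered at 1.5-fold and 2-fold cutoffs. Genes whose transcript
and protein move significantly in opposite directions are reported
separately as discordant pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "match_pairs",
    "r_squared",
    "correlation_grid",
    "discordant_pairs",
    "GridCell",
]


def match_pairs(
    protein_records: pd.DataFrame, gene_records: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join protein and transcript results on gene identifier.

    Both inputs need a ``gene_id`` column (or index), a ``log2_ratio`` and
    a boolean ``significant`` column. Returns one row per matched gene with
    columns ``protein_log2_ratio``, ``transcript_log2_ratio``,
    ``protein_significant``, ``transcript_significant``; unmatched counts
    are attached as ``frame.attrs``.
    """
    def _prep(df: pd.DataFrame, side: str) -> pd.DataFrame:
        d = df.copy()
        if "gene_id" in d.columns:
            d = d.set_index("gene_id")
        if d.index.duplicated().any():
            dup = d.index[d.index.duplicated()][0]
            raise ValueError(f"duplicate identifier {dup!r} in {side} table")
        return pd.DataFrame(
            {
                f"{side}_log2_ratio": d["log2_ratio"].astype(float),
                f"{side}_significant": d["significant"].astype(bool),
            }
        )

    prot = _prep(protein_records, "protein")
    gene = _prep(gene_records, "transcript")
    pairs = prot.join(gene, how="inner")
    pairs.attrs["n_protein_unmatched"] = int(len(prot) - len(pairs))
    pairs.attrs["n_transcript_unmatched"] = int(len(gene) - len(pairs))
    return pairs


def r_squared(pairs: pd.DataFrame, method: str = "pearson") -> float | None:
    """Squared correlation between protein and transcript log2 ratios.

    Returns None (undefined) when fewer than 3 pairs remain or either
    variable is constant — never 0, which would be a real (absence of)
    correlation claim.
    """
    x = pairs["protein_log2_ratio"].to_numpy(dtype=float)
    y = pairs["transcript_log2_ratio"].to_numpy(dtype=float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r * r)


@dataclass
class GridCell:
    label: str
    n: int
    r2: float | None


def _fold_ok(values: pd.Series, fold: float | None) -> pd.Series:
    if fold is None:
        return pd.Series(True, index=values.index)
    return values.abs() >= math.log2(fold)


def correlation_grid(
    pairs: pd.DataFrame,
    fold_thresholds: tuple[float, ...] = (1.5, 2.0),
    method: str = "pearson",
) -> dict[str, GridCell]:
    """Directional, threshold-stratified R² grid.

    Cell labels follow the integrated-omics convention: S = significant,
    P = protein, A = array (transcript); the arrow points from the list
    that seeds the comparison to the side it is correlated against. E.g.
    ``SP2.0->A``: significant proteins with at least a 2-fold change,
    correlated against their transcripts regardless of transcript
    significance; ``SA1.5->SP`` seeds from significant 1.5-fold genes and
    keeps only significant proteins; ``SP<->SA`` requires significance on
    both sides (direction 3, symmetric), with fold filters applied to both
    sides at matching levels.
    """
    folds: list[float | None] = [None, *fold_thresholds]

    def tag(side: str, fold: float | None) -> str:
        return f"S{side}" + (f"{fold}" if fold is not None else "")

    cells: dict[str, GridCell] = {}

    def add(label: str, mask: pd.Series) -> None:
        sub = pairs[mask]
        cells[label] = GridCell(label=label, n=int(len(sub)), r2=r_squared(sub, method))

    for fold in folds:
        # direction 1: seed from significant proteins
        seed = pairs["protein_significant"] & _fold_ok(pairs["protein_log2_ratio"], fold)
        add(f"{tag('P', fold)}->A", seed)
        add(f"{tag('P', fold)}->SA", seed & pairs["transcript_significant"])
        # direction 2: seed from significant transcripts
        seed = pairs["transcript_significant"] & _fold_ok(
            pairs["transcript_log2_ratio"], fold
        )
        add(f"{tag('A', fold)}->P", seed)
        add(f"{tag('A', fold)}->SP", seed & pairs["protein_significant"])
        # direction 3: significance and fold on both sides
        both = (
            pairs["protein_significant"]
            & pairs["transcript_significant"]
            & _fold_ok(pairs["protein_log2_ratio"], fold)
            & _fold_ok(pairs["transcript_log2_ratio"], fold)
        )
        add(f"{tag('P', fold)}<->{tag('A', fold)}", both)
    # the unfiltered direction-3 cell: every matched pair
    add("P<->A", pd.Series(True, index=pairs.index))
    return cells


def grid_to_frame(cells: dict[str, GridCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cell": c.label, "n": c.n, "r_squared": c.r2} for c in cells.values()]
    )


def discordant_pairs(pairs: pd.DataFrame, fold: float = 1.5) -> pd.DataFrame:
    """Genes whose transcript and protein change significantly in opposite directions.

    Both measures must be significant, both |log2 ratios| at least
    log2(fold), and the signs opposite.
    """
    thr = math.log2(fold)
    mask = (
        pairs["protein_significant"]
        & pairs["transcript_significant"]
        & (pairs["protein_log2_ratio"].abs() >= thr)
        & (pairs["transcript_log2_ratio"].abs() >= thr)
        & (np.sign(pairs["protein_log2_ratio"]) != np.sign(pairs["transcript_log2_ratio"]))
        & (pairs["protein_log2_ratio"] != 0)
        & (pairs["transcript_log2_ratio"] != 0)
    )
    return pairs[mask]
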