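"""Spectral-count differential protein abundance.

Label-free shotgun proteomics quantifies a protein by its spectrum count
(SpC): the number of tandem mass spectra matched to its tryptic peptides.
This module implements the classical SpC comparison workflow for a
two-condition, replicated design:

1. add a pseudocount of 1 to every cell (so absent proteins are testable),
2. scale each run so all run totals equal the mean adjusted total,
3. pool replicate runs within each condition,
4. test each protein with a two-cell likelihood-ratio (G) statistic against
   chi-squared with one degree of freedom,
5. call a protein UP or DOWN only if the chi-squared p-value is below 0.05,
   the false-discovery criterion p_j <= q*j/t holds, and every treatment
   replicate lies strictly on the same side of every control replicate.

Everything else is NULL. The same machinery run on the two replicates of a
single condition gives an empirical estimate of null discoveries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizedCounts",
    "normalize_counts",
    "pool_by_condition",
    "g_test",
    "select_differential",
    "estimate_null_discoveries",
    "run_proteomics_diff",
    "validate_design",
]

TREATMENT = "treatment"
CONTROL = "control"


@dataclass
class NormalizedCounts:
    """Pseudocounted, depth-equalized spectrum counts.

    ``values`` is proteins x runs; ``scale_factors`` maps each run to the
    factor (mean adjusted total / run adjusted total) applied to it. After
    construction every column of ``values`` sums to the same mean adjusted
    total.
    """

    values: pd.DataFrame
    scale_factors: pd.Series

    @property
    def run_total(self) -> float:
        return float(self.values.iloc[:, 0].sum())


def validate_design(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Check that a run design matches a counts table.

    ``design`` needs columns ``condition`` and ``replicate`` indexed by
    run id (or with a ``run_id`` column). Returns the design indexed by
    run id, restricted and ordered to the count table's columns.
    """
    d = design.copy()
    if "run_id" in d.columns:
        d = d.set_index("run_id")
    missing = [r for r in counts.columns if r not in d.index]
    if missing:
        raise ValueError(f"design is missing runs: {missing}")
    d = d.loc[list(counts.columns)]
    conditions = set(d["condition"])
    if conditions != {TREATMENT, CONTROL}:
        raise ValueError(
            f"design must label runs with exactly the conditions "
            f"{{{TREATMENT!r}, {CONTROL!r}}}, got {sorted(conditions)}"
        )
    return d


def normalize_counts(counts: pd.DataFrame) -> NormalizedCounts:
    """Pseudocount and depth-normalize a protein x run SpC table.

    Each cell is incremented by 1; each run is then rescaled so its
    adjusted total equals the mean adjusted total across runs. The
    pseudocount guarantees strictly positive values everywhere, so
    downstream log-ratios and G statistics are always defined.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty spectrum count table")
    if counts.shape[1] < 2:
        raise ValueError("need at least two runs to normalize")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative spectrum counts")
    adjusted = counts.astype(float) + 1.0
    totals = adjusted.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"run {bad!r} has no proteins")
    scale = totals.mean() / totals
    return NormalizedCounts(values=adjusted * scale, scale_factors=scale)


def pool_by_condition(
    norm: NormalizedCounts, design: pd.DataFrame
) -> pd.DataFrame:
    """Sum normalized values over each condition's runs.

    Returns a per-protein frame with ``pooled_treatment``,
    ``pooled_control`` and ``log2_ratio`` (treatment over control). With a
    balanced design the two condition totals are equal by construction;
    unbalanced designs are allowed but the G-test expecteds then weight by
    the observed totals.
    """
    design = validate_design(norm.values, design)
    treat_runs = design.index[design["condition"] == TREATMENT]
    ctrl_runs = design.index[design["condition"] == CONTROL]
    if len(treat_runs) != len(ctrl_runs):
        import warnings

        warnings.warn(
            "unequal replicate counts per condition: condition totals "
            "differ and G-test expecteds fall back to totals weighting",
            stacklevel=2,
        )
    pooled_t = norm.values[treat_runs].sum(axis=1)
    pooled_c = norm.values[ctrl_runs].sum(axis=1)
    return pd.DataFrame(
        {
            "pooled_treatment": pooled_t,
            "pooled_control": pooled_c,
            "log2_ratio": np.log2(pooled_t / pooled_c),
        }
    )


def g_test(pooled_t, pooled_c, total_t, total_c):
    """Two-cell G statistic and chi-squared(1) upper-tail p-value.

    The observed cells are one protein's pooled counts in each condition;
    expecteds split the protein's total in proportion to the condition
    totals, e_t = (o_t + o_c) * total_t / (total_t + total_c). Under equal
    condition totals (the situation depth normalization creates) this is
    the simple mean-expected form. Accepts scalars or arrays.

    G = 2 * [o_t ln(o_t/e_t) + o_c ln(o_c/e_c)], compared to chi2(1).
    """
    o_t = np.asarray(pooled_t, dtype=float)
    o_c = np.asarray(pooled_c, dtype=float)
    if np.any(o_t <= 0) or np.any(o_c <= 0) or total_t <= 0 or total_c <= 0:
        raise ValueError("G-test requires strictly positive pooled values and totals")
    grand = total_t + total_c
    e_t = (o_t + o_c) * total_t / grand
    e_c = (o_t + o_c) * total_c / grand
    g = 2.0 * (o_t * np.log(o_t / e_t) + o_c * np.log(o_c / e_c))
    # clip tiny negative round-off at the null
    g = np.maximum(g, 0.0)
    p = stats.chi2.sf(g, df=1)
    if np.ndim(pooled_t) == 0 and np.ndim(pooled_c) == 0:
        return float(g), float(p)
    return g, p


def _replicate_consistent(
    values: pd.DataFrame, design: pd.DataFrame, mode: str = "per_replicate"
) -> pd.Series:
    """Strict separation of treatment and control normalized values.

    ``per_replicate`` (default): every treatment run strictly above every
    control run, or every one strictly below; ties fail. ``pooled``: the
    pooled sums differ (a sign check), the degenerate form used when each
    side has one run.
    """
    treat = values[design.index[design["condition"] == TREATMENT]]
    ctrl = values[design.index[design["condition"] == CONTROL]]
    if mode == "pooled" or (treat.shape[1] == 1 and ctrl.shape[1] == 1):
        return treat.sum(axis=1) != ctrl.sum(axis=1)
    if mode != "per_replicate":
        raise ValueError(f"unknown replicate consistency mode {mode!r}")
    up = treat.min(axis=1) > ctrl.max(axis=1)
    down = treat.max(axis=1) < ctrl.min(axis=1)
    return up | down


def select_differential(
    pooled: pd.DataFrame,
    norm: NormalizedCounts,
    design: pd.DataFrame,
    q: float = 0.05,
    bh_mode: Literal["literal", "step_up"] = "literal",
    consistency_mode: str = "per_replicate",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank proteins, apply the FDR criterion and set UP/DOWN/NULL status.

    Ranks j are assigned by ascending p (ties broken by protein id). In
    ``literal`` mode a protein passes iff its own inequality p_j <= q*j/t
    holds, with t the number of identified proteins; ``step_up`` is the
    standard Benjamini-Hochberg procedure (every rank up to the largest
    passing one is accepted), which dominates the literal rule. Status is
    UP/DOWN only when the chi-squared p-value is < ``alpha``, the FDR rule
    passes, and replicate separation holds; the direction is the sign of
    the log2 ratio.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    design = validate_design(norm.values, design)
    total_t = float(
        norm.values[design.index[design["condition"] == TREATMENT]].sum().sum()
    )
    total_c = float(
        norm.values[design.index[design["condition"] == CONTROL]].sum().sum()
    )
    g, p = g_test(
        pooled["pooled_treatment"].to_numpy(),
        pooled["pooled_control"].to_numpy(),
        total_t,
        total_c,
    )
    rec = pooled.copy()
    rec["g_stat"] = g
    rec["p_value"] = p
    # deterministic tie-break: sort by id first, then stable-sort by p
    rec = rec.sort_index(kind="mergesort").sort_values("p_value", kind="mergesort")
    t = len(rec)
    rec["rank"] = np.arange(1, t + 1)
    rec["bh_threshold"] = q * rec["rank"] / t
    if bh_mode == "literal":
        bh_pass = rec["p_value"] <= rec["bh_threshold"]
    elif bh_mode == "step_up":
        bh_pass = pd.Series(
            multipletests(rec["p_value"].to_numpy(), alpha=q, method="fdr_bh")[0],
            index=rec.index,
        )
    else:
        raise ValueError(f"unknown bh_mode {bh_mode!r}")
    rec["replicate_consistent"] = _replicate_consistent(
        norm.values, design, consistency_mode
    ).reindex(rec.index)
    selected = (rec["p_value"] < alpha) & bh_pass & rec["replicate_consistent"]
    status = np.where(
        selected & (rec["log2_ratio"] > 0),
        "UP",
        np.where(selected & (rec["log2_ratio"] < 0), "DOWN", "NULL"),
    )
    rec["status"] = status
    return rec


def estimate_null_discoveries(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    condition: str,
    q: float = 0.05,
    bh_mode: Literal["literal", "step_up"] = "literal",
) -> int:
    """Within-condition replicate-vs-replicate discovery count.

    Relabels the two replicates of ``condition`` as pseudo treatment and
    control and runs the full pipeline on them. Because each pseudo
    condition holds a single run, replicate consistency degenerates to a
    sign check. The flagged count estimates the null discovery rate of the
    between-condition comparison.
    """
    design = validate_design(counts, design)
    runs = design.index[design["condition"] == condition]
    if len(runs) != 2:
        raise ValueError(
            f"condition {condition!r} must have exactly 2 replicates, has {len(runs)}"
        )
    sub = counts[list(runs)]
    pseudo = pd.DataFrame(
        {"condition": [TREATMENT, CONTROL], "replicate": [1, 1]}, index=runs
    )
    norm = normalize_counts(sub)
    pooled = pool_by_condition(norm, pseudo)
    rec = select_differential(pooled, norm, pseudo, q=q, bh_mode=bh_mode)
    return int((rec["status"] != "NULL").sum())


@dataclass
class ProteomicsResult:
    records: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_proteomics_diff(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    q: float = 0.05,
    bh_mode: Literal["literal", "step_up"] = "literal",
    consistency_mode: str = "per_replicate",
) -> ProteomicsResult:
    """End-to-end SpC differential analysis.

    Composes normalization, pooling, testing and selection, and summarizes
    the non-NULL calls overall and at the conventional 1.5-fold
    (|log2| >= log2 1.5) and 2-fold (|log2| >= 1) cutoffs.
    """
    design = validate_design(counts, design)
    norm = normalize_counts(counts)
    pooled = pool_by_condition(norm, design)
    rec = select_differential(
        pooled, norm, design, q=q, bh_mode=bh_mode, consistency_mode=consistency_mode
    )
    called = rec[rec["status"] != "NULL"]
    lr = called["log2_ratio"].abs()
    summary = {
        "n_proteins": int(len(rec)),
        "n_up": int((rec["status"] == "UP").sum()),
        "n_down": int((rec["status"] == "DOWN").sum()),
        "n_differential": int(len(called)),
        "n_fold_1.5": int((lr >= math.log2(1.5)).sum()),
        "n_fold_2.0": int((lr >= 1.0).sum()),
    }
    return ProteomicsResult(records=rec, summary=summary)
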