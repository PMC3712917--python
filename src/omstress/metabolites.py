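"""Internal-standard metabolite response scoring.

GC-MS peak areas are only comparable across samples after correcting for
extraction, derivatization and injection differences. A spiked internal
standard (sorbitol in the bacterial ethanol-stress assay this package
models) captures those sample-level factors: dividing each metabolite's
peak area by the internal-standard area of its sample, and by the fresh
mass extracted, yields a relative response per gram that is invariant to
any whole-sample rescaling.

Treatment effects are then scored per metabolite and time point as the
ratio of mean treatment response over mean control response, with a
classical two-sided Student t-test (equal variances; Welch behind a flag)
on the replicate responses, significant at P <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normalize_responses", "compare_conditions"]

TREATMENT = "treatment"
CONTROL = "control"

REQUIRED_COLUMNS = (
    "metabolite_id",
    "sample_id",
    "condition",
    "time_point",
    "replicate",
    "peak_area",
    "internal_standard_area",
    "sample_mass",
)


def normalize_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Peak area over internal-standard area over sample mass.

    Adds a ``response`` column. Raises on any sample whose
    internal-standard area is missing or non-positive (the normalization
    would be undefined).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metabolite table is missing columns: {missing}")
    is_area = table["internal_standard_area"]
    bad = table.loc[~(is_area > 0), "sample_id"]
    if len(bad):
        raise ValueError(
            f"non-positive internal standard area in sample {bad.iloc[0]!r}"
        )
    out = table.copy()
    out["response"] = (
        out["peak_area"] / out["internal_standard_area"] / out["sample_mass"]
    )
    return out


def compare_conditions(
    responses: pd.DataFrame,
    time_point: float | None = None,
    alpha: float = 0.05,
    fold: float = 1.5,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-metabolite treatment/control ratios and t-tests.

    For each metabolite (and each time point, unless one is given) the
    record carries the ratio of mean normalized responses (treatment over
    control), the two-sided t-test p-value on the replicate responses —
    classical equal-variance Student by default, so with two replicates a
    side the test has 2 degrees of freedom — a significance flag at
    ``alpha`` and a fold flag at ``fold`` in either direction. A zero
    control mean leaves the ratio (and flags) missing.
    """
    if "response" not in responses.columns:
        raise ValueError("run normalize_responses first (no 'response' column)")
    tps = (
        [time_point]
        if time_point is not None
        else sorted(responses["time_point"].unique())
    )
    rows = []
    for tp in tps:
        sub = responses[responses["time_point"] == tp]
        for mid, grp in sub.groupby("metabolite_id", sort=True):
            t_vals = grp.loc[grp["condition"] == TREATMENT, "response"].to_numpy()
            c_vals = grp.loc[grp["condition"] == CONTROL, "response"].to_numpy()
            if len(t_vals) < 2 or len(c_vals) < 2:
                raise ValueError(
                    f"metabolite {mid!r} at t={tp}: need >=2 replicates per condition"
                )
            c_mean = c_vals.mean()
            ratio = t_vals.mean() / c_mean if c_mean != 0 else np.nan
            p = float(stats.ttest_ind(t_vals, c_vals, equal_var=not welch).pvalue)
            rows.append(
                {
                    "metabolite_id": mid,
                    "time_point": tp,
                    "mean_ratio": ratio,
                    "p_value": p,
                    "significant": bool(p <= alpha) if np.isfinite(ratio) else False,
                    "fold_flag": bool(ratio >= fold or ratio <= 1.0 / fold)
                    if np.isfinite(ratio)
                    else False,
                }
            )
    return pd.DataFrame(rows)
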