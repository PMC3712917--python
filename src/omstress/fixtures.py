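"""Packaged reference data.

The package ships one small fixture: the 61 proteins of the ethanol-stress
study that passed the differential criteria with at least a 2-fold change,
with their log2 protein and transcript ratios (10 h treatment over 6 h
control), the associated p-values, and a 0/1 transcript-significance
index. It serves as a worked example for the correlation stage and as a
stable regression anchor.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_protein_array_ratios"]

_FIXTURE = "zm4_ethanol_protein_array_ratios.tsv"
_SHA256 = "332924e3ec8794c86435653e30318990feff6a3037ed092551e7315234998aa4"


def load_protein_array_ratios() -> pd.DataFrame:
    """Load the 61-protein ratio table, verifying its checksum.

    Columns: locus_tag, product, proteomics_log2_ratio,
    proteomics_p_value, array_log2_ratio, array_p_value,
    significance_index.
    """
    ref = resources.files("omstress.data").joinpath(_FIXTURE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _SHA256:
        raise RuntimeError(
            f"fixture {_FIXTURE} is corrupted (sha256 {digest[:12]}..., "
            f"expected {_SHA256[:12]}...)"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw), sep="\t")
    if len(df) != 61:
        raise RuntimeError(f"fixture must hold 61 records, found {len(df)}")
    return df
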