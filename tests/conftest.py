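import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from omstress.simulate import SimulationConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_counts():
    """4 proteins x 4 runs; adjusted (count+1) column totals 80/120/100/100."""
    counts = pd.DataFrame(
        {
            "T1": [7, 30, 20, 19],
            "T2": [29, 40, 27, 20],
            "C1": [24, 30, 22, 20],
            "C2": [24, 30, 22, 20],
        },
        index=pd.Index(["pA", "pB", "pC", "pD"], name="protein_id"),
    )
    assert list((counts + 1).sum()) == [80, 120, 100, 100]
    return counts


@pytest.fixture
def design22():
    return pd.DataFrame(
        {
            "condition": ["treatment", "treatment", "control", "control"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["T1", "T2", "C1", "C2"], name="run_id"),
    )


@pytest.fixture
def tiny_sim_config():
    """Scaled-down generator config for fast pipeline/CLI round trips."""
    return SimulationConfig(
        seed=7, n_proteins=120, depth=4000.0, n_genes=150, n_metabolites=10
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
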