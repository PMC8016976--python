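import numpy as np
import pandas as pd
import pytest

from macrogrn import synthetic_data as sd
from macrogrn.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down study: 3 strains, 8 TFs, 120 genes."""
    return sd.SimulationParams(seed=11, n_tfs=8, n_genes=120, n_strains=3)


@pytest.fixture(scope="session")
def small_truth(small_params):
    return sd.generate_ground_truth(small_params)


@pytest.fixture(scope="session")
def small_bundle(small_truth, small_params):
    return sd.simulate_bundle(small_truth, small_params)


@pytest.fixture()
def toy_expression():
    """2 strains x 2 replicates, 4 genes with known strain means."""
    values = pd.DataFrame(
        {
            "A_r1": [20.0, 4.0, 0.0, 7.0],
            "A_r2": [20.0, 4.0, 0.0, 7.0],
            "B_r1": [5.0, 12.0, 0.0, 7.0],
            "B_r2": [5.0, 12.0, 0.0, 7.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    mapping = {"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B"}
    return ExpressionMatrix(values, mapping)
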