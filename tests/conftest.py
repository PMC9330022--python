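import numpy as np
import pandas as pd
import pytest

from plastisweep.design import make_design
from plastisweep.simulate import CountMatrix, CountSimParams, simulate_counts


@pytest.fixture(scope="session")
def liver_design():
    return make_design(tissues=("liver",), n_reps=3)


@pytest.fixture(scope="session")
def small_counts(liver_design):
    """500-feature NB matrix over one tissue with planted effects."""
    params = CountSimParams(
        n_features=500, frac_en=0.1, frac_br=0.1, frac_int=0.05,
        effect_log2fc=2.0, dispersion=0.05, seed=11,
    )
    return simulate_counts(params, liver_design)


@pytest.fixture(scope="session")
def null_counts(liver_design):
    """No planted effects: everything NULL."""
    params = CountSimParams(
        n_features=400, frac_en=0, frac_br=0, frac_int=0,
        dispersion=0.05, seed=12,
    )
    return simulate_counts(params, liver_design)


def toy_count_matrix(counts: np.ndarray, design: pd.DataFrame) -> CountMatrix:
    features = [f"f{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        pd.DataFrame(counts, index=features, columns=list(design["sample_id"])), design
    )
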