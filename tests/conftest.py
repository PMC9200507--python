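import numpy as np
import pandas as pd
import pytest

from mmaselect import DataTable, SearchConfig, SyntheticSpec, generate
from mmaselect.preprocess import impute_missing, normalize


@pytest.fixture
def tiny_numeric_table() -> DataTable:
    """Six rows, two numeric features, balanced classes."""
    frame = pd.DataFrame(
        {"a": [0.0, 0.1, 0.2, 1.0, 1.1, 1.2], "b": [5.0, 4.0, 6.0, 5.0, 4.0, 6.0]}
    )
    labels = np.array([0, 0, 0, 1, 1, 1])
    return DataTable(frame, ("numeric", "numeric"), labels, ("0", "1"))


@pytest.fixture
def mixed_table() -> DataTable:
    """Numeric + categorical features with a missing cell of each kind."""
    frame = pd.DataFrame(
        {
            "age": [21.0, np.nan, 50.0, 81.0, 30.0, 44.0],
            "smoker": ["yes", "no", None, "no", "yes", "no"],
        }
    )
    labels = np.array([0, 1, 0, 1, 0, 1])
    return DataTable(frame, ("numeric", "categorical"), labels, ("0", "1"))


@pytest.fixture(scope="session")
def planted_table():
    """n=300 table with 3 strongly informative and 5 noise features,
    imputed and normalized, plus its ground truth."""
    spec = SyntheticSpec(
        n_rows=300, n_informative=3, n_noise=5, effect_size=1.5, seed=11
    )
    table, truth = generate(spec)
    return normalize(impute_missing(table)), truth


@pytest.fixture(scope="session")
def small_search_config() -> SearchConfig:
    return SearchConfig(seed=5, restarts=3, max_iter=60, inner_cv_folds=5)
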