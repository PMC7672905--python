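import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def small_data(rng):
    """A small random nutrient matrix and response with no structure."""
    X = rng.standard_normal((25, 5))
    G = rng.standard_normal(25)
    return X, G


@pytest.fixture
def model1_data():
    """One seeded draw from the single-peak generating model."""
    from lcn2g import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(model=1, n=100, d=10, r=0.1, seed=42))


@pytest.fixture
def csv_pair(tmp_path, rng):
    """Matched nutrient/expression CSV files with 6 samples, 5 shared."""
    ids = [f"S{i}" for i in range(1, 7)]
    X = pd.DataFrame(
        rng.standard_normal((6, 3)), index=ids, columns=["protein", "carb", "fat"]
    )
    E = pd.DataFrame(
        rng.standard_normal((2, 5)),
        index=["geneA", "geneB"],
        columns=ids[:5],  # S6 missing from expression
    )
    nutrient_file = tmp_path / "nutrients.csv"
    expression_file = tmp_path / "expression.csv"
    X.to_csv(nutrient_file)
    E.to_csv(expression_file)
    return nutrient_file, expression_file
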