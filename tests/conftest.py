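import numpy as np
import pandas as pd
import pytest

from fersig.io import ExpressionMatrix
from fersig.simulate import SimConfig, simulate_bulk_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the reference bulk study design (n=300, delta/sigma=2)."""
    return simulate_bulk_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study design for fast end-to-end runs."""
    return SimConfig(
        n_samples=120,
        n_genes=800,
        n_cells=300,
        icb_n_samples=80,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_expression():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.0, 8.0, size=(20, 12))
    return ExpressionMatrix(pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(12)],
    ))
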