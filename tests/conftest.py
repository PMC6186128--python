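import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from bclr import ExpressionMatrix, default_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_expression(rng, n_genes=5, n_conditions=8):
    return ExpressionMatrix(
        [f"g{i + 1}" for i in range(n_genes)],
        [f"C{i + 1}" for i in range(n_conditions)],
        rng.normal(size=(n_genes, n_conditions)),
    )


@pytest.fixture
def small_expr(rng):
    return random_expression(rng)


@pytest.fixture(scope="session")
def scenario():
    """Default desk-scale scenario: 100 genes, 200 conditions, noise 0.5."""
    return default_scenario(seed=2024)


@pytest.fixture(scope="session")
def scenario30():
    """30-gene scenario for stability-curve experiments."""
    return default_scenario(
        seed=2024, n_regulators=5, n_targets=25, density=0.15, n_conditions=200
    )
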