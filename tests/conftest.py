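import numpy as np
import pytest

from promotercalc import load_default_tables, simulate_ground_truth
from promotercalc.energy_model import EnergyModelParams, default_normalizers


@pytest.fixture(scope="session")
def tables():
    return load_default_tables()


@pytest.fixture(scope="session")
def truth_params(tables):
    """Canonical-motif synthetic ground truth used across the suite."""
    return simulate_ground_truth(seed=1, tables=tables)


@pytest.fixture(scope="session")
def zero_params(tables):
    return EnergyModelParams.zeros(tables)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
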