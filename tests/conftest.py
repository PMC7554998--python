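import numpy as np
import pytest

import polyfh
from polyfh.model import GenotypeMatrix


@pytest.fixture(scope="session")
def weights():
    """The shipped 11-SNP placeholder weight table."""
    return polyfh.default_weights()


@pytest.fixture(scope="session")
def sim_config():
    return polyfh.SimulationConfig.default(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_matrix(weights, dosage, prefix="S"):
    """GenotypeMatrix over the full panel from a raw dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    ids = [f"{prefix}{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(ids, weights.rsids, dosage)


def random_dosages(weights, n, rng, missing_rate=0.0):
    d = rng.integers(0, 3, size=(n, len(weights))).astype(float)
    if missing_rate:
        d[rng.random(d.shape) < missing_rate] = np.nan
    return d
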