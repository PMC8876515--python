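import numpy as np
import pandas as pd
import pytest

from mrkit.summary_io import InstrumentSet, load_table1_fixture


def make_instruments(bx, sx, by, sy, snp_ids=None) -> InstrumentSet:
    """Build an InstrumentSet directly from effect arrays."""
    bx = np.asarray(bx, float)
    j = bx.size
    if snp_ids is None:
        snp_ids = [f"rs{i:04d}" for i in range(j)]
    table = pd.DataFrame({
        "snp_id": snp_ids,
        "beta_exposure": bx,
        "se_exposure": np.asarray(sx, float),
        "beta_outcome": np.asarray(by, float),
        "se_outcome": np.asarray(sy, float),
        "eaf": np.full(j, 0.3),
        "action": "kept_as_is",
    })
    return InstrumentSet(table=table)


def random_instruments(rng, j=20, theta=0.3) -> InstrumentSet:
    """A random but well-behaved instrument set with causal slope theta."""
    bx = rng.uniform(0.01, 0.05, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.002, 0.005, j)
    sy = rng.uniform(0.01, 0.05, j)
    by = theta * bx + rng.normal(0, sy)
    return make_instruments(bx, sx, by, sy)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
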