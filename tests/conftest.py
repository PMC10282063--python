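import numpy as np
import pandas as pd
import pytest

from ropbo import data as bundled
from ropbo.catalyst_space import ARENE, LINKER, Fragment
from ropbo.surrogate import GPConfig


@pytest.fixture(scope="session")
def literature():
    """The bundled 56-record re-keyed literature stand-in."""
    return bundled.load_literature_dataset()


@pytest.fixture(scope="session")
def fragment_tables():
    return bundled.load_fragment_tables()


@pytest.fixture(scope="session")
def registry():
    return bundled.load_registry()


@pytest.fixture(scope="session")
def table1():
    return bundled.load_table1()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_gp():
    """Low-restart GP config to keep unit tests quick."""
    return GPConfig(n_restarts=1, seed=0)


def make_fragments(n, family, steps=1):
    prefix = "A" if family == ARENE else "BC"
    return [
        Fragment(id=f"{prefix}{i}", family=family, synthetic_steps=steps)
        for i in range(n)
    ]


@pytest.fixture
def toy_linear_frame(rng):
    """10-row frame with known pairwise correlation structure."""
    x = rng.standard_normal(10)
    return pd.DataFrame(
        {
            "a": x,
            "b": 0.999 * x + 0.001 * rng.standard_normal(10),
            "c": rng.standard_normal(10),
        }
    )
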