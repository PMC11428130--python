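import numpy as np
import pytest

from tmcdiff.config import Config
from tmcdiff.fixtures import make_toy_complex
from tmcdiff.gvp import DenoiserGVP


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale network/schedule for fast tests."""
    return Config(n_layers=2, scalar_width=24, vector_channels=6, steps=40,
                  batch_size=4)


@pytest.fixture(scope="session")
def small_model(small_config):
    return DenoiserGVP(small_config, seed=0)


@pytest.fixture()
def hexa_mono():
    """Octahedral complex with six distinct monodentate ligands."""
    return make_toy_complex(
        "Fe", ["aqua", "ammine", "chloro", "cyano", "carbonyl", "methyl"],
        "octahedral", seed=1,
    )


@pytest.fixture()
def two_tridentate():
    """Octahedral complex built from exactly two tridentate ligands."""
    return make_toy_complex(
        "Co", ["triphos", "triphos_methyl"], "octahedral", seed=2,
    )


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
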