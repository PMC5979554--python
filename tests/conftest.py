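import numpy as np
import pytest

from adhdock.fixtures import make_toy_complex
from adhdock.model_io import load_forcefield


@pytest.fixture(scope="session")
def table():
    return load_forcefield("ad4")


@pytest.fixture(scope="session")
def toy():
    """Default toy complex: 6-atom ligand, 2 torsions, 38-atom pocket."""
    return make_toy_complex(7)


@pytest.fixture(scope="session")
def toy_rigid():
    """Rigid-ligand complex (T = 0)."""
    return make_toy_complex(11, n_torsions=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
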