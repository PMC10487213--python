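import numpy as np
import pytest

from greensolv import datasets
from greensolv.hsp import HSPTriple, SoluteSphere


@pytest.fixture(scope="session")
def solvents():
    return datasets.load_solvents()


@pytest.fixture(scope="session")
def red_matrix():
    return datasets.load_red_matrix()


@pytest.fixture(scope="session")
def relsol_table():
    return datasets.load_relative_solubility()


@pytest.fixture(scope="session")
def fatty_acid_profiles():
    return datasets.load_fatty_acid_profiles()


@pytest.fixture
def lipid_sphere():
    """A lipid-like solute sphere used by forward/inverse round trips."""
    return SoluteSphere(name="lipid", center=HSPTriple(17.0, 3.0, 5.0), r_spher=8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
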