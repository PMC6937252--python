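import numpy as np
import pytest

from pcp import load_element_table, make_toy_system


@pytest.fixture(scope="session")
def element_table():
    return load_element_table()


@pytest.fixture(scope="session")
def hydrogen(element_table):
    return element_table["H"]


@pytest.fixture(scope="session")
def oxygen(element_table):
    return element_table["O"]


@pytest.fixture()
def toy3():
    """A feasible 3-atom heteronuclear toy system."""
    return make_toy_system(3, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def write_xyz_text(tmp_path, text, name="mol.xyz"):
    p = tmp_path / name
    p.write_text(text)
    return p
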