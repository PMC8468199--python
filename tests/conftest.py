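import numpy as np
import pytest

from pharmscreen.chem import Molecule3D


@pytest.fixture(scope="session")
def ethanol():
    return Molecule3D.from_smiles("CCO", "ethanol", seed=11)


@pytest.fixture(scope="session")
def benzene():
    return Molecule3D.from_smiles("c1ccccc1", "benzene", seed=11)


@pytest.fixture(scope="session")
def methane():
    return Molecule3D.from_smiles("C", "methane", seed=11)


@pytest.fixture(scope="session")
def water():
    return Molecule3D.from_smiles("O", "water", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
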