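import numpy as np
import pytest

from rigidpmf import synthetic_data as sd
from rigidpmf.dilution_stability import DilutionSchedule


@pytest.fixture(scope="session")
def schedule():
    return DilutionSchedule()  # -0.1 -> -6.0 in 0.1 steps


@pytest.fixture()
def toy_monomer():
    pdb, truth = sd.toy_structure(n_res=6, kind="monomer")
    return pdb, truth


@pytest.fixture()
def toy_dimer():
    pdb, truth = sd.toy_structure(n_res=6, kind="dimer")
    return pdb, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20170814)
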