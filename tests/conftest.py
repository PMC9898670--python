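import numpy as np
import pytest

from helixfit import sequence_tools as st
from helixfit import scattering as sc
from helixfit.helix_builder import build_linear_triple_helix

TABLE_SEQUENCES = {
    "MBL-C": "Ac-(POG)4-QG-(POG)5-NH2",
    "MBL-N": "Ac-(POG)4-EPGQGLRG-(POG)3-NH2",
    "MBL-E": "Ac-(POG)5-EOGQGLRG-(POG)3-NH2",
    "MBL-12": "Ac-(POG)5-EPGQGLRG-(POG)5-NH2",
    "(POG)10": "Ac-(POG)10-NH2",
    "(POG)13": "Ac-(POG)13-NH2",
    "(PPG)10": "(PPG)10",
    "G>A": "Ac-(POG)4-POA-(POG)5-NH2",
    "T3-785": "Ac-(POG)3-ITGARGLAGPOG-(POG)3-NH2",
}


@pytest.fixture(scope="session")
def pog10_chain():
    return st.parse_peptide(TABLE_SEQUENCES["(POG)10"], "(POG)10")


@pytest.fixture(scope="session")
def pog10_model(pog10_chain):
    return build_linear_triple_helix(pog10_chain)


@pytest.fixture(scope="session")
def pog10_dry(pog10_model):
    return sc.coarse_grain(pog10_model)


@pytest.fixture(scope="session")
def pog10_hydrated(pog10_chain, pog10_dry):
    return sc.add_hydration(pog10_dry, st.trimer_mass(pog10_chain))


@pytest.fixture(scope="session")
def random_sphere_model():
    rng = np.random.default_rng(0)
    return sc.SphereModel(rng.uniform(0, 3, (200, 3)), 0.3,
                          np.zeros(200, dtype=bool))
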