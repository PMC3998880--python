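import numpy as np
import pytest

from encom.contacts import InteractionMatrix, build_contact_model
from encom.enm_core import ModelKind, ParameterSet, compute_modes
from encom.fixtures import ToySpec, make_structure


@pytest.fixture(scope="session")
def eps_default():
    return InteractionMatrix.default()


@pytest.fixture(scope="session")
def eps_ones():
    return InteractionMatrix.nonspecific()


@pytest.fixture(scope="session")
def helix5():
    return make_structure(ToySpec("ideal_helix", 5))


@pytest.fixture(scope="session")
def helix8():
    return make_structure(ToySpec("ideal_helix", 8))


@pytest.fixture(scope="session")
def helix8_contacts(helix8, eps_default):
    return build_contact_model(helix8, eps_default)


@pytest.fixture(scope="session")
def encom_params():
    return ParameterSet(model_kind=ModelKind.ENCOM)


@pytest.fixture(scope="session")
def helix8_decomp(helix8, encom_params, helix8_contacts):
    return compute_modes(helix8, encom_params, helix8_contacts)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    from scipy.spatial.transform import Rotation
    return Rotation.from_quat(q).as_matrix()
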