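import numpy as np
import pytest

from interdigit import Bilayer, FixtureSpec
from interdigit.synth import make_flat_lattice, make_gaussian_bilayer


@pytest.fixture(scope="session")
def flat_spec():
    return FixtureSpec(lipids_per_leaflet=16, n_sn1=4, n_sn2=4,
                       sigma=0.0, delta=0.0, gap=3.0, n_frames=1, seed=0)


@pytest.fixture(scope="session")
def flat_system(flat_spec):
    return Bilayer.from_spec(flat_spec, kind="flat")


@pytest.fixture(scope="session")
def gauss_spec():
    return FixtureSpec(lipids_per_leaflet=16, n_sn1=4, n_sn2=4,
                       sigma=2.0, delta=2.0, n_frames=3, seed=11)


@pytest.fixture(scope="session")
def gauss_system(gauss_spec):
    return Bilayer.from_spec(gauss_spec, kind="gaussian")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
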