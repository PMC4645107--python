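import numpy as np
import pytest

from hiphase import defaults
from hiphase.atomdata import load_atom_model
from hiphase.beam import BeamModel, SpatialProfile, TemporalProfile


@pytest.fixture(scope="session")
def gd_atom():
    return load_atom_model(None, "Gd", 8.48)


@pytest.fixture(scope="session")
def c_atom():
    return load_atom_model(None, "C", 8.48)


def make_beam(attenuation=1.0, spatial=None, gate_fs=None):
    return BeamModel(
        photon_energy_keV=8.48,
        pulse_energy_mJ=1.6,
        optics_transmission=0.30,
        attenuation=attenuation,
        spatial=spatial or SpatialProfile.gaussian(0.2),
        temporal=TemporalProfile(duration_fs=40.0, gate_fs=gate_fs),
    )


@pytest.fixture(scope="session")
def hf_beam():
    return make_beam(1.0)


@pytest.fixture(scope="session")
def lf_beam():
    return make_beam(defaults.LF_ATTENUATION)


@pytest.fixture(scope="session")
def dg_hf_beam():
    return make_beam(1.0, SpatialProfile.double_gaussian())


@pytest.fixture(scope="session")
def dg_lf_beam():
    return make_beam(defaults.LF_ATTENUATION, SpatialProfile.double_gaussian())


@pytest.fixture(scope="session")
def flat_top_40fs():
    return TemporalProfile(duration_fs=40.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
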