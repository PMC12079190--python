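import dataclasses

import numpy as np
import pytest

from fusact import (
    AcquisitionParams,
    StimulusProtocol,
    make_default_protocol,
    make_phantom,
)
from fusact.params import MotionModel


@pytest.fixture(scope="session")
def default_protocol():
    return make_default_protocol()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture
def short_protocol():
    """Just over one Doppler block, for fast simulator tests."""
    return StimulusProtocol(
        baseline_duration=0.3, onsets=(0.3,), durations=(0.2,), total_duration=0.6
    )


@pytest.fixture
def no_motion():
    return MotionModel(kind="none")


@pytest.fixture
def coherent_vessel_scene():
    """One vessel, no tissue, no noise, no speckle: the analytic Doppler
    configuration (pure carrier exp(i 2 pi f_d t))."""
    scene = make_phantom(
        grid_shape=(24, 24), n_vessels=1, effect_size=0.0, seed=5,
        noise_sigma=0.0, speckle_correlation=None,
    )
    return dataclasses.replace(
        scene, tissue_amplitude=np.zeros(scene.grid_shape)
    )


@pytest.fixture
def tissue_only_scene():
    return make_phantom(
        grid_shape=(24, 24), n_vessels=0, effect_size=0.0, seed=2, noise_sigma=0.0
    )
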