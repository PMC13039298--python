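import numpy as np
import pytest

from focidyn import AcquisitionGeometry, MotionModel, SimulationConfig


@pytest.fixture
def unit_geometry():
    """1 µm/px, 1 min/frame: pixel and physical units coincide."""
    return AcquisitionGeometry(
        pixel_size=1.0, frame_interval=1.0, n_frames=10, field_shape=(64, 64)
    )


@pytest.fixture
def default_geometry():
    return AcquisitionGeometry()


@pytest.fixture
def brownian_config():
    return SimulationConfig(
        n_nuclei=1,
        foci_per_nucleus=20,
        nucleus_radius=8.0,
        geometry=AcquisitionGeometry(field_shape=(256, 256)),
        motion=MotionModel(kind="brownian", diffusion_coefficient=0.005),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
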