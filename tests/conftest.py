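import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_atlas():
    from fmriboot import make_grid_atlas

    return make_grid_atlas((12, 12, 12), n_regions=8, voxel_size_mm=2.0)


@pytest.fixture
def single_blob_field(small_atlas):
    from fmriboot import make_effect_field

    return make_effect_field(
        small_atlas.shape, blob_centers=[(6, 6, 6)], blob_peak_d=0.8,
        blob_sigma_mm=5.0, voxel_size_mm=small_atlas.voxel_size_mm)
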