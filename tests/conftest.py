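import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from compoundeye import oda3d, synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_eye():
    """A 200-lens noise-free desk-scale eye with ground truth (coarse voxels)."""
    spec = synthetic.SyntheticEyeSpec(
        n_lenses=200, cap_radius=170.0, cap_solid_angle=2.5,
        base_diameter=16.0, azimuthal_gradient=0.0, equatorial_band_shrink=0.0,
        noise_sd=0.0, voxel_size=2.0, seed=42,
    )
    volume, truth = synthetic.generate_synthetic_eye(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def small_eye_record(small_eye):
    """Detection output for the small eye."""
    _, volume, _ = small_eye
    return oda3d.detect_eye(volume, subject_id="fixture")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
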