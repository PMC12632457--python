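import numpy as np
import pytest

from perinuc.synthetic import SyntheticScene, render_nucleus_stack

# a scene whose spot sits exactly at a voxel center (nucleus center chosen on
# the voxel-center raster, spot at scaled depth 1 = the center itself)
VOXEL_CENTER = ((32 + 0.5) * 0.1065, (32 + 0.5) * 0.1065, (20 + 0.5) * 0.26)


@pytest.fixture(scope="session")
def centered_noiseless():
    """Noiseless scene with the spot exactly at a voxel center."""
    scene = SyntheticScene(
        nucleus_center=VOXEL_CENTER,
        spot_scaled_depth=1.0,
        spot_direction=(1.0, 0.0, 0.0),
        poisson_noise=False,
        read_noise_sd=0.0,
        seed=7,
    )
    stack, truth = render_nucleus_stack(scene)
    return scene, stack, truth


@pytest.fixture(scope="session")
def noiseless_sphere_14():
    """Noiseless 1.4 µm sphere with an off-center spot."""
    scene = SyntheticScene(
        nucleus_radii=(1.4, 1.4, 1.4),
        spot_scaled_depth=0.4,
        spot_direction=(1.0, 0.5, 0.25),
        poisson_noise=False,
        read_noise_sd=0.0,
        seed=3,
    )
    stack, truth = render_nucleus_stack(scene)
    return scene, stack, truth


@pytest.fixture(scope="session")
def noisy_default():
    """Default noisy scene (Poisson + read noise)."""
    scene = SyntheticScene(spot_scaled_depth=0.3, seed=12)
    stack, truth = render_nucleus_stack(scene)
    return scene, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
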