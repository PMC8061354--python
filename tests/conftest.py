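import numpy as np
import pytest

from pulmovox.phantom import PhantomConfig, generate_lung_phantom


def small_config(**overrides) -> PhantomConfig:
    """An 80³ isotropic phantom that generates in ~1 s.

    Scaled-down geometry (smaller airway, one lateral per lobe, reduced
    particle load) so unit tests stay fast; the default-sized phantom is
    exercised by the acceptance tests.
    """
    kwargs = dict(
        volume_shape=(80, 80, 80),
        voxel_size=(1.0, 1.0, 1.0),
        root_radius=4.0,
        wall_thickness=1.5,
        branch_length=14.0,
        n_generations=2,
        laterals_per_lobe=1,
        acinar_distance=10.0,
        total_particle_volume=80.0,
        boundary_margin=1,
        noise_sd=6.0,
        seed=3,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    cfg = small_config()
    structure, fluor, truth = generate_lung_phantom(cfg)
    return cfg, structure, fluor, truth


@pytest.fixture(scope="session")
def small_phantom_noiseless():
    cfg = small_config(noise_sd=0.0, seed=7)
    structure, fluor, truth = generate_lung_phantom(cfg)
    return cfg, structure, fluor, truth


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size study-condition phantom (200³, anisotropic voxels)."""
    cfg = PhantomConfig(seed=1)
    structure, fluor, truth = generate_lung_phantom(cfg)
    return cfg, structure, fluor, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
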