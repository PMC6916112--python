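import numpy as np
import pytest

from orbitcut import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom: same tissue layout, ~8x fewer voxels than default."""
    return PhantomSpec(
        shape=(32, 64, 64),
        spacing=(1.0, 0.5, 0.5),
        muscle_total_cm3=0.5,
        fat_cm3=0.4,
        noise_sigma=0.0,
        rng_seed=7,
        cavity_semiaxes=(11.0, 10.0, 10.0),
        shell_thickness=2.0,
        sphere_radius=3.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_noisy_phantom(small_spec):
    import dataclasses
    spec = dataclasses.replace(small_spec, noise_sigma=10.0)
    return generate_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
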