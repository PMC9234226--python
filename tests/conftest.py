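import numpy as np
import pytest

from fracseg.io import LabelMap, Volume3D
from fracseg.phantom import (ContrastConfig, OrganGeometry, PhantomConfig,
                             VariationConfig, generate_patient)


def small_phantom_config(seed: int = 0, **overrides) -> PhantomConfig:
    """A fast phantom on a 48x48x16 grid with organs scaled to fit."""
    kwargs = dict(
        grid_shape=(48, 48, 16),
        n_fractions=3,
        organ_geometry=OrganGeometry(
            ctv_semiaxes=(6.0, 5.0, 4.0),
            bladder_semiaxes=(8.0, 7.0, 4.0),
            rectum_radius=3.0, rectum_curvature=2.0),
        variation=VariationConfig(deformation_magnitude=1.0,
                                  deformation_spacing=8.0),
        contrast=ContrastConfig(bias_field_spacing=16.0),
        seed=seed)
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_series():
    return generate_patient(small_phantom_config(seed=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_volume(rng):
    return Volume3D(rng.normal(size=(16, 16, 16)).astype(np.float32),
                    spacing_mm=(0.86, 0.86, 1.0), origin_mm=(1.0, -2.0, 3.0))


@pytest.fixture()
def random_labelmap(rng):
    return LabelMap(rng.integers(0, 4, size=(16, 16, 16)).astype(np.int16),
                    spacing_mm=(0.86, 0.86, 1.0))
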