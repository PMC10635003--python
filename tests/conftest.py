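import numpy as np
import pytest

from vemseg.models import ModelConfig
from vemseg.sampling import SamplerConfig
from vemseg.synthdata import SynthSpec, generate_volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_spec(**overrides) -> SynthSpec:
    """A fast desk-size spec (32 x 96 x 96, three clean spheres)."""
    kwargs = dict(
        shape=(32, 96, 96),
        n_nuclei=3,
        nucleolus_per_nucleus=(1, 2),
        nucleus_radius_range=(10.0, 14.0),
        nucleolus_radius_range=(2.5, 4.0),
        intensity_levels=(0.2, 0.6, 0.9),
        noise_sd=0.03,
        texture_scale=3.0,
        seed=11,
    )
    kwargs.update(overrides)
    return SynthSpec(**kwargs)


@pytest.fixture(scope="session")
def small_volume():
    """Small annotated volume shared across read-only tests."""
    return generate_volume(small_spec())


@pytest.fixture(scope="session")
def clean_volume():
    """Noise-free variant: structures are exactly their configured gray level."""
    return generate_volume(small_spec(noise_sd=0.0, texture_scale=0.0, seed=5))


@pytest.fixture
def tiny_sampler():
    return SamplerConfig(
        context_size=64, out_size=32, foreground_fraction=0.99, augment=False,
        rng_seed=0,
    )


@pytest.fixture
def tiny_model_cfg():
    return ModelConfig(arch="resunet", base_width=4, depth=2)
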