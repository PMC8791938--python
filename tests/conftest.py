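import pytest
from hypothesis import HealthCheck, settings

from octlayers import (
    PhantomConfig,
    generate_bscan,
    healthy_config,
    segment_bscan,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def flat_config(**overrides) -> PhantomConfig:
    """A degenerate phantom: flat layers, no fovea, no noise."""
    overrides.setdefault("undulation_amplitude", 0.0)
    overrides.setdefault("fovea_depth", 0.0)
    overrides.setdefault("speckle_level", 0.0)
    return PhantomConfig(**overrides)


def criterion_phantom_config(seed: int = 7, **overrides) -> PhantomConfig:
    """The standard noisy healthy study phantom: speckle 0.2, one
    vessel shadow, a posterior vitreous face line."""
    overrides.setdefault("speckle_level", 0.2)
    overrides.setdefault("vessel_shadows", ((170, 8, 0.35),))
    overrides.setdefault("pvf_offset", 25.0)
    return healthy_config(rng_seed=seed, **overrides)


@pytest.fixture(scope="session")
def flat_phantom():
    return generate_bscan(flat_config(rng_seed=3))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_bscan(criterion_phantom_config(seed=7))


@pytest.fixture(scope="session")
def noisy_segmentation(noisy_phantom):
    bscan, _truth = noisy_phantom
    return segment_bscan(bscan)


@pytest.fixture(scope="session")
def flat_segmentation(flat_phantom):
    bscan, _truth = flat_phantom
    return segment_bscan(bscan)
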