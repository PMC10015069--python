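import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from swarmcount import ModelConfig, MosquitoCounter, SynthConfig, sample_images


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """Narrow-width model that keeps forward/backward passes fast while
    preserving the full architecture (3 branches, SE on the 7x7 one)."""
    return ModelConfig(fen_layers=7, fen_channels=(4, 4, 6, 6, 6, 6, 6),
                       branch_channels=(6, 5, 4), se_reduction=2)


@pytest.fixture(scope="session")
def tiny_model(tiny_config) -> MosquitoCounter:
    return MosquitoCounter(tiny_config, seed=3)


@pytest.fixture(scope="session")
def small_images():
    """Eight small synthetic swarm images with moderate counts."""
    base = SynthConfig(image_size=(64, 96), count_range=(3, 12))
    return sample_images(8, seed=7, base_config=base)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
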