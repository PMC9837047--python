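import numpy as np
import pytest

from bodymaps.mask import build_manikin_mask
from bodymaps.simulate import (
    GeneratorConfig,
    build_component_templates,
    generate_study,
    sample_cohort_latents,
)


@pytest.fixture(scope="session")
def mask():
    return build_manikin_mask(120, 44)


@pytest.fixture(scope="session")
def templates(mask):
    return build_component_templates(mask)


@pytest.fixture(scope="session")
def small_config():
    """Small cohort for fast structural tests."""
    return GeneratorConfig(n_subjects=40)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config, seed=123)


@pytest.fixture(scope="session")
def default_latents():
    return sample_cohort_latents(GeneratorConfig(), np.random.default_rng(7))
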