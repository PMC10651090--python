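import logging

import numpy as np
import pytest

from melanotherm import ImageGenParams, ThermalGenParams, generate_image

logging.getLogger("melanotherm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def spotted_image():
    """One rendered frame at 22% coverage with ground truth."""
    return generate_image(ImageGenParams(target_proportion=0.22, seed=3))


@pytest.fixture(scope="session")
def null_cohort_params():
    """Study-shaped cohort with no injected effects."""
    return ThermalGenParams(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
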