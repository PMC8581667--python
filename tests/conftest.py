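import numpy as np
import pytest

from nestprofiler.simulate import default_image_spec, generate_image_stack


@pytest.fixture(scope="session")
def default_slide():
    """One canonical synthetic slide with its ground truth (seed 3)."""
    spec = default_image_spec(seed=3)
    stack, truth = generate_image_stack(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
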