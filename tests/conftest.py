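import warnings

import numpy as np
import pytest

import goalglam as gg

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def value_world():
    """Ten synthetic value-experiment participants with known parameters."""
    rng = np.random.default_rng(5)
    params = [gg.default_params("value", rng) for _ in range(10)]
    datasets = gg.generate_dataset(gg.ValueDesign(), params, rng)
    return {"params": params, "datasets": datasets}


@pytest.fixture(scope="session")
def perceptual_world():
    """Six synthetic perceptual-experiment participants."""
    rng = np.random.default_rng(3)
    params = [gg.default_params("perceptual", rng) for _ in range(6)]
    datasets = gg.generate_dataset(gg.PerceptualDesign(), params, rng)
    return {"params": params, "datasets": datasets}


@pytest.fixture()
def std_params():
    """A realistic parameter point for the value task (ms time base)."""
    return gg.GlamParams(nu=5e-4, gamma=0.3, sigma=0.01, tau=1.0)
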