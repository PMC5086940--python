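import warnings

import numpy as np
import pytest

from rawkit.reference_model import build_reference
from rawkit.synthetic_data import GeneratorConfig, generate_panel

# the pipeline emits informational warnings (bin merges, edge scores); tests
# that assert on warnings catch them explicitly
warnings.filterwarnings("ignore", category=UserWarning)

FIXED_QUERY = dict(noise_scale=1.0, gc_coef=1.0, fraglen_coef=1.0, brightness=0.0)


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(n_probes=2400, n_reference_samples=14, seed=11)


@pytest.fixture(scope="session")
def panel(gen_config):
    return generate_panel(gen_config)


@pytest.fixture(scope="session")
def model(panel):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_reference(panel.samples, panel.sexes, panel.annotation)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
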