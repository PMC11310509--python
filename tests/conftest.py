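import numpy as np
import pytest

from retina_atlas.io import NormState, normalize
from retina_atlas.synthetic import AtlasConfig, generate_atlas


@pytest.fixture(scope="session")
def small_config():
    """Compact atlas for unit tests (fast; not the demo defaults)."""
    return AtlasConfig(n_cells=4000, seed=11)


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return generate_atlas(small_config)


@pytest.fixture(scope="session")
def small_log_expr(small_atlas):
    return normalize(small_atlas.counts, NormState.LOG1P_CPM)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
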