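import numpy as np
import pytest
from hypothesis import settings

from slowchange import MorphConfig
from slowchange import pipeline
from slowchange.scene import demo_spec

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Three-feature scene on a small canvas (fast to render, same structure
    as a full-size stimulus)."""
    return demo_spec(n_features=3, size=96)


@pytest.fixture(scope="session")
def small_cset(small_spec):
    return pipeline.scene_composite_set(
        small_spec, 1, pipeline.color_pair("purple-orange")
    )


@pytest.fixture()
def default_config():
    return MorphConfig(seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240209)
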