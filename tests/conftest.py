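import numpy as np
import pytest

from rnlcolour import build_study, default_visual_system, write_fixture_set


@pytest.fixture(scope="session")
def vs():
    """The packaged example visual system (zebra finch-like)."""
    return default_visual_system()


@pytest.fixture(scope="session")
def study():
    """One deterministic synthetic run of the full experiment."""
    return build_study(seed=7)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A written-out synthetic data set plus pipeline config."""
    root = tmp_path_factory.mktemp("synthdata")
    cfg = write_fixture_set(root, seed=7)
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
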