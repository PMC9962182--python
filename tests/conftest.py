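import numpy as np
import pytest

import fallgcn as fg


@pytest.fixture(scope="session")
def default_graph():
    return fg.build_default_graph()


@pytest.fixture(scope="session")
def tiny_graph():
    """Two-node skeleton for fast gradient and shape checks."""
    return fg.SkeletonGraph(("a", "b"), frozenset({(0, 1)}), 0)


@pytest.fixture(scope="session")
def small_sequences():
    """Two synthetic subjects, one trial each: enough windows for splits."""
    cfg = fg.SyntheticConfig(subjects=2, trials=2, seed=7)
    return fg.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_windows(small_sequences):
    return fg.segment_many(small_sequences, 2.0, 0.5, drop_background=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
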