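import numpy as np
import pytest

from cellgraphkit import synth


@pytest.fixture(scope="session")
def small_clustered():
    """600 cells, 3 clusters, clear structure; (counts, labels)."""
    spec = synth.SynthSpec(
        n_cells=600, n_genes=300, cluster_props=(0.4, 0.3, 0.3), seed=0
    )
    return synth.make_clustered_counts(spec)


@pytest.fixture(scope="session")
def tiny_counts():
    """Deterministic 10 x 5 integer matrix with zeros."""
    rng = np.random.default_rng(42)
    return rng.integers(0, 6, size=(10, 5)).astype(np.int64)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
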