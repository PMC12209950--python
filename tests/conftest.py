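import numpy as np
import pytest

from moimech.graphs import AttributedGraph


def random_graph(rng: np.random.Generator, n_max: int = 12, n_feat: int = 4) -> AttributedGraph:
    """Small random undirected graph with standard-normal features."""
    n = int(rng.integers(1, n_max + 1))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < 0.4
    edges = list(zip(iu[0][present].tolist(), iu[1][present].tolist()))
    X = rng.normal(size=(n, n_feat))
    return AttributedGraph([f"n{i}" for i in range(n)], edges, X=X)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
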