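import numpy as np
import pytest

import gexgan as gg


@pytest.fixture(scope="session")
def tiny_bundle():
    return gg.make_fixture("tiny")


@pytest.fixture(scope="session")
def small_bundle():
    return gg.make_fixture("small")


@pytest.fixture(scope="session")
def tiny_normalized(tiny_bundle):
    """Tiny fixture normalized to [0,1] and restricted to its training split."""
    X = gg.apply_normalizer(tiny_bundle.X_raw, tiny_bundle.normalizer, clip=True)
    idx = tiny_bundle.train_idx
    Xtr = gg.ExpressionMatrix(X.values[idx], X.gene_ids,
                              [X.sample_ids[i] for i in idx], X.space_tag)
    return Xtr, tiny_bundle.C.subset(idx)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def path_graph(n=3, directed=False):
    ids = [f"g{i}" for i in range(n)]
    src = np.arange(n - 1)
    tgt = np.arange(1, n)
    return gg.GeneGraph(ids, src, tgt, np.ones(n - 1), directed=directed, signed=False)


def empty_graph(n):
    ids = [f"g{i}" for i in range(n)]
    z = np.array([], dtype=np.intp)
    return gg.GeneGraph(ids, z, z, np.array([]), directed=False, signed=False)
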