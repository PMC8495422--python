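"""Shared fixtures: toy graphs, a small synthetic bundle, fixture norms.

The norms TSVs under ``tests/data`` are *synthetic* fixture ratings written
for these tests (plausible values on the right scales), not the published
rating norms.
"""

from pathlib import Path

import numpy as np
import pytest

import lexprop as lp

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def norms_files() -> dict[str, Path]:
    return {dim: DATA / f"synthetic_norms_{dim}.tsv" for dim in lp.DIMENSIONS}


@pytest.fixture(scope="session")
def conc_norms(norms_files) -> lp.NormsTable:
    return lp.NormsTable.from_tsv(norms_files["CONC"])


@pytest.fixture(scope="session")
def small_bundle() -> lp.SyntheticBundle:
    """Desk-sized synthetic bundle shared across tests (2 groups)."""
    spec = lp.SyntheticSpec(
        vocab_size=300,
        n_groups=2,
        docs_per_group=300,
        doc_length=30,
        tau=0.1,
        group_shift=0.1,
        rng_seed=3,
    )
    return lp.generate_bundle(spec)


@pytest.fixture()
def toy_graph():
    """Deterministic 20-node kNN graph over random embeddings."""
    rng = np.random.default_rng(0)
    words = [f"n{i:02d}" for i in range(20)]
    emb = lp.EmbeddingSet(words=words, matrix=rng.normal(size=(20, 8)))
    graph = lp.build_knn_graph(emb, lp.GraphConfig(n_neighbors=5))
    return lp.to_transition_matrix(graph)


@pytest.fixture()
def two_cluster_graph():
    """8 nodes in two tight clusters, weakly bridged; nodes h* near the
    high pole, l* near the low pole."""
    n = 8
    words = [f"h{i}" for i in range(4)] + [f"l{i}" for i in range(4)]
    W = np.zeros((n, n))
    for i in range(4):
        for j in range(4):
            if i != j:
                W[i, j] = 1.0
                W[i + 4, j + 4] = 1.0
    W[3, 4] = W[4, 3] = 0.05  # weak bridge
    from scipy import sparse

    graph = lp.LexicalGraph(
        nodes=words,
        weights=sparse.csr_matrix(W),
        config=lp.GraphConfig(n_neighbors=4),
    )
    return lp.to_transition_matrix(graph)
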