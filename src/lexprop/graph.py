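"""Weighted k-nearest-neighbour lexical graph and its transition matrix.

Each word is linked to its ``n_neighbors`` most cosine-similar words; edge
weights are a nonnegative kernel of the cosine, and row-normalising the
weight matrix yields the row-stochastic transition matrix the random walker
moves on.  Construction is fully deterministic: ties in cosine are broken by
lexicographic word order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .embeddings import EmbeddingSet

__all__ = ["GraphConfig", "LexicalGraph", "TransitionMatrix",
           "build_knn_graph", "to_transition_matrix"]

_KERNELS = ("clipped-cosine", "shifted-cosine")


@dataclass(frozen=True)
class GraphConfig:
    """kNN graph construction parameters.

    ``n_neighbors=25`` follows established practice for corpus lexical
    graphs of this kind.  The default kernel clips negative cosines to zero
    so that edge weights lie in [0, 1]; ``shifted-cosine`` maps cosine
    affinely onto [0, 1] instead.  ``symmetrize`` takes the union of the
    directed kNN edges (cosine is symmetric, so no weight conflict arises).
    """

    n_neighbors: int = 25
    weight_kernel: str = "clipped-cosine"
    symmetrize: bool = True
    restrict_to: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.weight_kernel not in _KERNELS:
            raise ValueError(f"weight_kernel must be one of {_KERNELS}")


@dataclass
class LexicalGraph:
    """Sparse weighted graph over an ordered word list.

    ``isolated`` lists words dropped because every candidate edge had kernel
    weight zero; they receive no propagation score downstream.
    """

    nodes: list[str]
    weights: sparse.csr_matrix
    config: GraphConfig
    isolated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.index = {w: i for i, w in enumerate(self.nodes)}


@dataclass
class TransitionMatrix:
    """Row-stochastic move probabilities over the graph's nodes."""

    nodes: list[str]
    P: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.index = {w: i for i, w in enumerate(self.nodes)}
        rows = np.asarray(self.P.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")


def _kernel(sim: np.ndarray, kind: str) -> np.ndarray:
    if kind == "clipped-cosine":
        return np.maximum(sim, 0.0)
    return (sim + 1.0) / 2.0


def build_knn_graph(embeddings: EmbeddingSet, config: GraphConfig | None = None) -> LexicalGraph:
    """Link every word to its ``n_neighbors`` nearest words by cosine.

    Neighbour lists are computed against the full (possibly restricted)
    vocabulary; equal cosines are resolved lexicographically.  Requesting
    ``n_neighbors >= |V|`` yields the complete graph.
    """
    config = config or GraphConfig()
    words = embeddings.words
    if config.restrict_to is not None:
        words = [w for w in words if w in config.restrict_to]
        if not words:
            raise ValueError("restrict_to shares no words with the embedding vocabulary")
    if len(words) < 2:
        raise ValueError("graph construction needs at least 2 words")

    mat = np.stack([embeddings.vector(w) for w in words])
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    if (norms == 0).any():
        bad = [w for w, n in zip(words, norms.ravel()) if n == 0]
        raise ValueError(f"zero vectors for words: {bad[:5]}")
    unit = mat / norms

    n = len(words)
    k = min(config.n_neighbors, n - 1)
    # Lexicographic rank as deterministic tie-break on equal cosine.
    lex_rank = np.argsort(np.argsort(words))

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    chunk = 1024
    for start in range(0, n, chunk):
        block = unit[start : start + chunk] @ unit.T  # (b, n)
        for bi in range(block.shape[0]):
            i = start + bi
            sim = block[bi]
            order = np.lexsort((lex_rank, -sim))
            order = order[order != i][:k]
            w = _kernel(np.clip(sim[order], -1.0, 1.0), config.weight_kernel)
            keep = w > 0
            rows.append(np.full(int(keep.sum()), i))
            cols.append(order[keep])
            vals.append(w[keep])

    W = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    if config.symmetrize:
        W = W.maximum(W.T)
    W.setdiag(0.0)
    W.eliminate_zeros()

    degree = np.asarray(W.sum(axis=1)).ravel()
    isolated_idx = np.flatnonzero(degree == 0)
    isolated = [words[i] for i in isolated_idx]
    if isolated:
        keep_idx = np.flatnonzero(degree > 0)
        W = W[keep_idx][:, keep_idx].tocsr()
        words = [words[i] for i in keep_idx]

    return LexicalGraph(nodes=words, weights=W, config=config, isolated=isolated)


def to_transition_matrix(graph: LexicalGraph) -> TransitionMatrix:
    """Row-normalise edge weights into move probabilities."""
    W = graph.weights.tocsr().astype(float)
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    dead = np.flatnonzero(rowsum == 0)
    if dead.size:
        names = [graph.nodes[i] for i in dead[:10]]
        raise ValueError(f"cannot normalise rows of isolated nodes: {names}")
    inv = sparse.diags(1.0 / rowsum)
    P = (inv @ W).tocsr()
    # Guard against floating-point drift so downstream code can rely on
    # exact stochasticity at 1e-12.
    rows = np.asarray(P.sum(axis=1)).ravel()
    P = (sparse.diags(1.0 / rows) @ P).tocsr()
    return TransitionMatrix(nodes=list(graph.nodes), P=P)
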