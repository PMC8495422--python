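"""Per-sub-corpus word vectors.

Two trainers share one contract (same vocabulary rule, same
:class:`EmbeddingSet` output):

``train_embeddings``
    A seeded skip-gram-with-negative-sampling trainer (optionally
    subword-aware through hashed character n-grams), suitable for real
    corpora.  Stochastic gradient descent makes it reproducible for a fixed
    seed but only approximately stable across corpus perturbations.

``reference_embeddings``
    A deterministic count-based trainer — positive pointwise mutual
    information co-occurrence within a window, factorised by truncated SVD.
    Bit-reproducible, hand-checkable on toy corpora, and the trainer used
    throughout the test-suite and synthetic recovery benchmarks.

Both produce vectors whose cosine similarity expresses distributional
semantic similarity, the raw material of the lexical graph.
"""

from __future__ import annotations

import hashlib
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .corpus import SubCorpus

__all__ = [
    "EmbeddingConfig",
    "EmbeddingSet",
    "cosine",
    "train_embeddings",
    "reference_embeddings",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters shared by both trainers.

    ``dim`` defaults to 300, the customary dimensionality for corpus-trained
    static embeddings.  ``subword_ngrams`` (a (min, max) length range) only
    affects the skip-gram trainer; ``None`` disables subword features.
    """

    dim: int = 300
    window: int = 5
    epochs: int = 5
    min_count: int = 1
    subword_ngrams: tuple[int, int] | None = None
    n_subword_buckets: int = 50_000
    negative: int = 5
    learning_rate: float = 0.025
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class EmbeddingSet:
    """Ordered vocabulary plus a dense ``(n_words, dim)`` vector matrix."""

    words: list[str]
    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index = {w: i for i, w in enumerate(self.words)}
        if self.matrix.shape[0] != len(self.words):
            raise ValueError("vector matrix does not match vocabulary size")

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def vector(self, word: str) -> np.ndarray:
        return self.matrix[self.index[word]]

    def similarity(self, w1: str, w2: str) -> float:
        return cosine(self.vector(w1), self.vector(w2))

    # -- word2vec-style text interchange ------------------------------------

    def save_text(self, path: str | Path) -> None:
        """Write in word2vec text format: header ``n dim``, then rows."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.words)} {self.dim}\n")
            for w, row in zip(self.words, self.matrix):
                fh.write(w + " " + " ".join(f"{x:.6g}" for x in row) + "\n")

    @classmethod
    def load_text(cls, path: str | Path, provenance: dict | None = None) -> "EmbeddingSet":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            words: list[str] = []
            mat = np.empty((n, dim))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                mat[i] = [float(x) for x in parts[1 : dim + 1]]
        if len(words) != n:
            raise ValueError(f"embedding file {path}: expected {n} rows, got {len(words)}")
        return cls(words=words, matrix=mat, provenance=provenance or {"source": str(path)})


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1].  Errors on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("cosine requires vectors of equal length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine is undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _config_hash(config: EmbeddingConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]


def _vocabulary(subcorpus: SubCorpus, min_count: int) -> list[str]:
    vocab = sorted(w for w, c in subcorpus.counts.items() if c >= min_count)
    if len(vocab) < 2:
        raise ValueError(
            f"sub-corpus {subcorpus.label!r} has fewer than 2 distinct words "
            f"with count >= {min_count}; cannot train embeddings"
        )
    return vocab


# ---------------------------------------------------------------------------
# Deterministic reference trainer: windowed PPMI + truncated SVD
# ---------------------------------------------------------------------------

def _cooccurrence(
    documents: list[list[str]], index: dict[str, int], window: int
) -> sparse.csr_matrix:
    """Symmetric within-window co-occurrence counts (order-free across docs)."""
    n = len(index)
    rows: list[int] = []
    cols: list[int] = []
    for doc in documents:
        ids = [index[t] for t in doc if t in index]
        L = len(ids)
        for i, wi in enumerate(ids):
            for j in range(i + 1, min(i + 1 + window, L)):
                rows.append(wi)
                cols.append(ids[j])
    data = np.ones(len(rows))
    m = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
    m = m + m.T  # symmetrise: count each pair in both directions
    return m.tocsr()


def _ppmi(counts: sparse.csr_matrix) -> np.ndarray:
    """Positive PMI: max(0, log p(i,j) / (p(i) p(j))), dense."""
    total = counts.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    c = np.asarray(counts.todense(), dtype=float)
    row = c.sum(axis=1, keepdims=True)
    col = c.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(c * total / (row * col))
    pmi[~np.isfinite(pmi)] = 0.0
    np.maximum(pmi, 0.0, out=pmi)
    return pmi


def reference_embeddings(subcorpus: SubCorpus, config: EmbeddingConfig) -> EmbeddingSet:
    """Deterministic PPMI-SVD embeddings (the test-oracle trainer).

    The PPMI matrix is factorised with a full (deterministic) SVD and the top
    ``dim`` left singular vectors are scaled by the square roots of their
    singular values.  If ``dim`` exceeds the matrix rank the missing
    components are zero and a warning is issued.  Words whose PPMI row is
    entirely zero would otherwise receive a zero vector; they are given a
    deterministic unit fallback vector so that cosine stays defined.
    """
    vocab = _vocabulary(subcorpus, config.min_count)
    index = {w: i for i, w in enumerate(vocab)}
    ppmi = _ppmi(_cooccurrence(subcorpus.documents, index, config.window))

    # Deterministic full SVD; PPMI is symmetric so this is an eigendecomposition.
    u, s, _ = np.linalg.svd(ppmi, hermitian=True)
    k = min(config.dim, len(s))
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    if config.dim > rank:
        warnings.warn(
            f"requested dim={config.dim} exceeds PPMI rank {rank}; "
            "extra components are zero-padded",
            stacklevel=2,
        )
    mat = np.zeros((len(vocab), config.dim))
    mat[:, :k] = u[:, :k] * np.sqrt(s[:k])
    # Sign convention: make the largest-magnitude entry of each component
    # positive, so the factorisation is unique and bit-reproducible.
    for j in range(k):
        col = mat[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            mat[:, j] = -col

    zero = np.linalg.norm(mat, axis=1) == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} word(s) have an all-zero PPMI profile; "
            "assigned deterministic fallback vectors",
            stacklevel=2,
        )
        for i in np.flatnonzero(zero):
            h = int(hashlib.sha256(vocab[i].encode()).hexdigest(), 16)
            mat[i, h % config.dim] = 1e-8

    return EmbeddingSet(
        words=vocab,
        matrix=mat,
        provenance={
            "subcorpus": subcorpus.label,
            "trainer": "ppmi-svd",
            "config_hash": _config_hash(config),
            "config": repr(config),
        },
    )


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling (optionally subword-aware)
# ---------------------------------------------------------------------------

def _char_ngrams(word: str, lo: int, hi: int) -> list[str]:
    padded = f"<{word}>"
    out = []
    for n in range(lo, hi + 1):
        out.extend(padded[i : i + n] for i in range(len(padded) - n + 1))
    return out


def _hash_bucket(ngram: str, n_buckets: int) -> int:
    return int(hashlib.md5(ngram.encode()).hexdigest(), 16) % n_buckets


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(subcorpus: SubCorpus, config: EmbeddingConfig) -> EmbeddingSet:
    """Skip-gram negative-sampling trainer, seeded and reproducible.

    When ``config.subword_ngrams`` is set, each input vector is the mean of
    the word's own vector and its hashed character-n-gram vectors, so that
    morphologically related words share representation mass — useful on the
    small, noisy corpora this package targets.
    """
    vocab = _vocabulary(subcorpus, config.min_count)
    index = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(config.rng_seed)

    # Subword feature table: word id -> list of feature ids (word itself first).
    use_subword = config.subword_ngrams is not None
    if use_subword:
        lo, hi = config.subword_ngrams
        feats = [
            [i] + [V + _hash_bucket(g, config.n_subword_buckets)
                   for g in _char_ngrams(w, lo, hi)]
            for i, w in enumerate(vocab)
        ]
        n_in = V + config.n_subword_buckets
    else:
        feats = [[i] for i in range(V)]
        n_in = V

    w_in = (rng.random((n_in, config.dim)) - 0.5) / config.dim
    w_out = np.zeros((V, config.dim))

    # Negative-sampling table ∝ unigram^0.75.
    counts = np.array([subcorpus.counts[w] for w in vocab], dtype=float)
    neg_p = counts**0.75
    neg_p /= neg_p.sum()

    # Materialise (center, context) pairs once; cheap for desk-scale corpora.
    centers: list[int] = []
    contexts: list[int] = []
    for doc in subcorpus.documents:
        ids = [index[t] for t in doc if t in index]
        for i, c in enumerate(ids):
            for j in range(max(0, i - config.window), min(len(ids), i + config.window + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    if not centers:
        raise ValueError("no training pairs; documents too short for the window")
    centers_a = np.array(centers)
    contexts_a = np.array(contexts)

    n_pairs = len(centers_a)
    batch = 1024
    for epoch in range(config.epochs):
        lr = config.learning_rate * (1.0 - epoch / max(1, config.epochs))
        lr = max(lr, config.learning_rate * 0.1)
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sel = order[start : start + batch]
            c_ids = centers_a[sel]
            pos = contexts_a[sel]
            B = len(sel)
            neg = rng.choice(V, size=(B, config.negative), p=neg_p)

            if use_subword:
                h = np.stack([w_in[feats[i]].mean(axis=0) for i in c_ids])
            else:
                h = w_in[c_ids]

            targets = np.concatenate([pos[:, None], neg], axis=1)  # (B, 1+k)
            labels = np.zeros((B, 1 + config.negative))
            labels[:, 0] = 1.0
            out_vecs = w_out[targets]  # (B, 1+k, dim)
            scores = _sigmoid(np.einsum("bkd,bd->bk", out_vecs, h))
            g = (scores - labels) * lr  # (B, 1+k)

            grad_h = np.einsum("bk,bkd->bd", g, out_vecs)
            grad_out = g[:, :, None] * h[:, None, :]
            np.add.at(w_out, targets, -grad_out)
            if use_subword:
                for b, ci in enumerate(c_ids):
                    f = feats[ci]
                    w_in[f] -= grad_h[b] / len(f)
            else:
                np.add.at(w_in, c_ids, -grad_h)

    if use_subword:
        mat = np.stack([w_in[f].mean(axis=0) for f in feats])
    else:
        mat = w_in[:V].copy()

    zero = np.linalg.norm(mat, axis=1) == 0
    if zero.any():  # pragma: no cover - essentially impossible after init
        mat[zero] = 1e-8

    return EmbeddingSet(
        words=vocab,
        matrix=mat,
        provenance={
            "subcorpus": subcorpus.label,
            "trainer": "sgns-subword" if use_subword else "sgns",
            "config_hash": _config_hash(config),
            "config": repr(config),
        },
    )
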