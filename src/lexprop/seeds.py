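"""Seed-word selection against norms tables.

For each psycholinguistic dimension the walker needs two anchor pole sets:
the most extremely rated candidate words at either end of the norms scale.
Candidates must (1) occur at least ``min_count`` times in every sub-corpus
being compared, (2) be representative of the corpus content (top topic-model
words), (3) be content words, and (4) appear in the norms table; the 20
highest- and 20 lowest-rated survivors form the two poles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .corpus import FUNCTION_WORDS, CorpusCollection, shared_words

__all__ = [
    "DIMENSIONS",
    "NormsTable",
    "TopicModelConfig",
    "SeedSelectionConfig",
    "SeedSet",
    "topic_top_words",
    "select_seeds",
    "normalize_rating",
]

#: The five psycholinguistic dimensions handled throughout the package:
#: concreteness, imageability, familiarity, age of acquisition, semantic size.
DIMENSIONS = ("CONC", "IMAG", "FAM", "AoA", "SIZE")


@dataclass
class NormsTable:
    """Subjective word ratings for one dimension on a bounded scale.

    Typical scales are 1-5 (crowd-sourced concreteness norms) and 1-7
    (Glasgow-style norms for the other dimensions).
    """

    dimension: str
    entries: dict[str, float]
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        bad = {w: r for w, r in self.entries.items()
               if not (self.scale_min <= r <= self.scale_max)}
        if bad:
            raise ValueError(f"ratings outside [{self.scale_min}, {self.scale_max}]: {bad}")

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path, dimension: str | None = None) -> "NormsTable":
        """Read ``word<TAB>rating<TAB>scale_min<TAB>scale_max`` rows.

        A leading comment line ``# dimension=<NAME>`` may carry the dimension;
        otherwise pass it explicitly.
        """
        entries: dict[str, float] = {}
        smin = smax = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "dimension=" in line and dimension is None:
                        dimension = line.split("dimension=")[1].strip()
                    continue
                word, rating, lo, hi = line.split("\t")
                entries[word] = float(rating)
                smin, smax = float(lo), float(hi)
        if dimension is None or smin is None:
            raise ValueError(f"norms file {path} lacks dimension or scale info")
        return cls(dimension=dimension, entries=entries, scale_min=smin, scale_max=smax)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# dimension={self.dimension}\n")
            for w in sorted(self.entries):
                fh.write(f"{w}\t{self.entries[w]:.6g}\t{self.scale_min:g}\t{self.scale_max:g}\n")


@dataclass(frozen=True)
class TopicModelConfig:
    """LDA settings for extracting corpus-representative words."""

    n_topics: int = 20
    n_top_words: int = 1000
    n_iterations: int = 100
    rng_seed: int = 0


@dataclass(frozen=True)
class SeedSelectionConfig:
    min_count: int = 10
    n_per_pole: int = 20
    function_word_stoplist: frozenset[str] = FUNCTION_WORDS

    def __post_init__(self) -> None:
        if self.n_per_pole < 1:
            raise ValueError("n_per_pole must be >= 1")


@dataclass
class SeedSet:
    """Two disjoint pole word lists for one dimension, with their ratings."""

    dimension: str
    high_pole: list[str]
    low_pole: list[str]
    high_ratings: dict[str, float] = field(default_factory=dict)
    low_ratings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.high_pole) & set(self.low_pole):
            raise ValueError("seed poles must be disjoint")

    def swapped(self) -> "SeedSet":
        """The same seed set with the poles exchanged."""
        return SeedSet(
            dimension=self.dimension,
            high_pole=list(self.low_pole),
            low_pole=list(self.high_pole),
            high_ratings=dict(self.low_ratings),
            low_ratings=dict(self.high_ratings),
        )


def topic_top_words(collection: CorpusCollection, config: TopicModelConfig | None = None) -> list[str]:
    """Rank the pooled vocabulary by aggregate topic relevance via LDA.

    Topics are fitted on the pooled document-term matrix; each word's score
    is sum_t P(word|topic_t) * P(topic_t), with topic weights estimated from
    the corpus-wide topic proportions.  Deterministic for a fixed seed.
    """
    from sklearn.decomposition import LatentDirichletAllocation

    config = config or TopicModelConfig()
    docs = collection.pooled_documents()
    docs = [d for d in docs if d]
    if not docs:
        raise ValueError("topic modeling requires a non-empty pooled corpus")

    vocab = sorted({w for d in docs for w in d})
    index = {w: i for i, w in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for di, doc in enumerate(docs):
        seen: dict[int, int] = {}
        for t in doc:
            seen[index[t]] = seen.get(index[t], 0) + 1
        for wi, c in seen.items():
            rows.append(di)
            cols.append(wi)
            vals.append(c)
    X = sparse.coo_matrix((vals, (rows, cols)), shape=(len(docs), len(vocab))).tocsr()

    n_topics = min(config.n_topics, len(docs), len(vocab))
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        max_iter=config.n_iterations,
        random_state=config.rng_seed,
    )
    doc_topic = lda.fit_transform(X)
    lengths = np.asarray(X.sum(axis=1)).ravel()
    p_topic = (doc_topic * lengths[:, None]).sum(axis=0)
    p_topic /= p_topic.sum()
    word_topic = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    relevance = p_topic @ word_topic  # sum_t P(w|t) P(t)

    if config.n_top_words > len(vocab):
        import warnings

        warnings.warn(
            f"vocabulary ({len(vocab)}) smaller than n_top_words "
            f"({config.n_top_words}); returning the full ranked vocabulary",
            stacklevel=2,
        )
    order = np.lexsort((vocab, -relevance))
    return [vocab[i] for i in order[: config.n_top_words]]


def select_seeds(
    collection: CorpusCollection,
    norms: NormsTable,
    topic_words: list[str] | None,
    config: SeedSelectionConfig | None = None,
) -> SeedSet:
    """Four-stage seed selection; errors report the pool size after each stage.

    Stages: frequency filter (count >= min_count in every sub-corpus) ->
    topic-representative filter -> content-word filter -> norms coverage.
    The ``n_per_pole`` highest- and lowest-rated survivors form the poles,
    ties broken lexicographically.
    """
    config = config or SeedSelectionConfig()
    stage_sizes: list[tuple[str, int]] = []

    pool = set(shared_words(collection, config.min_count))
    stage_sizes.append((f"count>={config.min_count} in every sub-corpus", len(pool)))
    if topic_words is not None:
        pool &= set(topic_words)
        stage_sizes.append(("topic-representative words", len(pool)))
    pool -= config.function_word_stoplist
    stage_sizes.append(("content words (stoplist removed)", len(pool)))
    pool &= set(norms.entries)
    stage_sizes.append((f"covered by {norms.dimension} norms", len(pool)))

    if len(pool) < 2 * config.n_per_pole:
        detail = "; ".join(f"{name}: {n}" for name, n in stage_sizes)
        raise ValueError(
            f"candidate pool too small for 2x{config.n_per_pole} seeds ({detail})"
        )

    # Sort descending by rating, lexicographic on ties.
    ranked = sorted(pool, key=lambda w: (-norms.entries[w], w))
    high = ranked[: config.n_per_pole]
    low = sorted(ranked[-config.n_per_pole :], key=lambda w: (norms.entries[w], w))
    return SeedSet(
        dimension=norms.dimension,
        high_pole=high,
        low_pole=low,
        high_ratings={w: norms.entries[w] for w in high},
        low_ratings={w: norms.entries[w] for w in low},
    )


def normalize_rating(rating: float, norms: NormsTable) -> float:
    """Map a raw rating onto [0, 1] by dividing by the scale maximum.

    This is the rating/scale_max convention (a 6.3 on a 7-point scale becomes
    0.90), not min-max scaling, so comparisons with propagation scores use
    the same convention as published score tables.
    """
    if not (norms.scale_min <= rating <= norms.scale_max):
        raise ValueError(
            f"rating {rating} outside scale [{norms.scale_min}, {norms.scale_max}]"
        )
    return rating / norms.scale_max
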