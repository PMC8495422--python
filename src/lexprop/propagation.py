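"""Random-walk label propagation and per-word polarity scoring.

A walker on the transition matrix restarts at one seed pole with probability
``1 - beta`` each step.  The long-run landing mass of the walk is the fixed
point of

    p  <-  beta * p P + (1 - beta) * s,

with ``s`` uniform over the pole's seeds.  Running the walk once from the
high-rated pole (mass ``c``) and once from the low-rated pole (mass ``a``),
each word's score is ``c / (c + a)`` — 1 means all affinity to the high pole,
0 all affinity to the low pole.  A bootstrap over random seed subsets removes
the influence of any single seed word, and the corpus-level score is the mean
word score over the shared target words.

Two solvers are provided: the deterministic fixed-point iteration
(:func:`propagate`, the production path) and a Monte-Carlo walker
(:func:`monte_carlo_propagate`) that simulates the walks explicitly and
converges to the same distribution — retained as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import TransitionMatrix
from .seeds import SeedSet

__all__ = [
    "WalkConfig",
    "LandingDistribution",
    "WordScoreTable",
    "propagate",
    "monte_carlo_propagate",
    "polarity_score",
    "score_dimension",
    "corpus_score",
    "word_mean_across_groups",
]


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk and bootstrap parameters.

    ``beta`` is the probability of continuing the walk (so ``1 - beta`` is
    the restart probability); 0.9 gives an expected excursion length of 10
    steps, long enough to diffuse beyond immediate neighbours while staying
    anchored to the pole.  ``n_subsets``/``subset_fraction`` control the
    seed bootstrap; ``mc_*`` parameters apply to the Monte-Carlo solver only.
    """

    beta: float = 0.9
    tol: float = 1e-6
    max_iter: int = 1000
    n_subsets: int = 50
    subset_fraction: float = 0.7
    mc_n_walks: int = 100
    mc_walk_length: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie strictly between 0 and 1")
        if not 0.0 < self.subset_fraction <= 1.0:
            raise ValueError("subset_fraction must lie in (0, 1]")


@dataclass
class LandingDistribution:
    """Probability mass over graph nodes for one seed pole."""

    nodes: list[str]
    mass: np.ndarray
    pole: str

    def __post_init__(self) -> None:
        if (self.mass < 0).any():
            raise ValueError("landing mass must be nonnegative")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("landing mass must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.mass.tolist()))

    def __getitem__(self, word: str) -> float:
        return float(self.mass[self.nodes.index(word)])


@dataclass
class WordScoreTable:
    """Per-word scores in [0, 1] for one (dimension, sub-corpus) pair.

    Words that could not be scored (isolated graph nodes) are simply absent;
    ``unsupported`` lists words whose landing mass was zero from both poles
    (their score defaults to the neutral 0.5).
    """

    dimension: str
    label: str
    scores: dict[str, float]
    unsupported: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {w: s for w, s in self.scores.items() if not (0.0 <= s <= 1.0)}
        if bad:
            raise ValueError(f"scores outside [0, 1]: {bad}")

    def __contains__(self, word: str) -> bool:
        return word in self.scores

    def __getitem__(self, word: str) -> float:
        return self.scores[word]

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        """Write ``word<TAB>dimension<TAB>group<TAB>score`` rows (sorted)."""
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("word\tdimension\tgroup\tscore\n")
            for w in sorted(self.scores):
                fh.write(f"{w}\t{self.dimension}\t{self.label}\t{self.scores[w]:.8f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WordScoreTable":
        scores: dict[str, float] = {}
        dimension = label = None
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            while header.startswith("#"):
                header = fh.readline()
            if not header.startswith("word\t"):
                raise ValueError(f"{path} is not a word-score TSV")
            for line in fh:
                w, dim, grp, s = line.rstrip("\n").split("\t")
                dimension, label = dim, grp
                if s != "":
                    scores[w] = float(s)
        if dimension is None:
            raise ValueError(f"empty score table: {path}")
        return cls(dimension=dimension, label=label, scores=scores)


def _seed_vector(P: TransitionMatrix, pole_seeds: list[str]) -> np.ndarray:
    if not pole_seeds:
        raise ValueError("seed pole is empty")
    missing = [w for w in pole_seeds if w not in P.index]
    if missing:
        raise ValueError(f"seeds absent from the graph: {missing}")
    s = np.zeros(len(P.nodes))
    for w in pole_seeds:
        s[P.index[w]] += 1.0
    return s / s.sum()


def propagate(
    P: TransitionMatrix, pole_seeds: list[str], config: WalkConfig | None = None
) -> LandingDistribution:
    """Deterministic fixed point of the restart walk from one seed pole."""
    config = config or WalkConfig()
    s = _seed_vector(P, pole_seeds)
    p = s.copy()
    for _ in range(config.max_iter):
        new = config.beta * (p @ P.P) + (1.0 - config.beta) * s
        residual = float(np.max(np.abs(new - p)))
        p = new
        if residual < config.tol:
            break
    else:
        raise RuntimeError(
            f"propagation did not converge in {config.max_iter} iterations "
            f"(residual {residual:.3e} > tol {config.tol:.1e})"
        )
    p = np.maximum(p, 0.0)
    p /= p.sum()
    return LandingDistribution(nodes=list(P.nodes), mass=p, pole=",".join(pole_seeds[:3]))


def monte_carlo_propagate(
    P: TransitionMatrix,
    pole_seeds: list[str],
    config: WalkConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LandingDistribution:
    """Simulate the restart walks explicitly and count traversed words.

    ``mc_n_walks`` walks of ``mc_walk_length`` steps are started from each
    seed; every state the walker traverses (including restarts) is counted.
    The empirical visit frequency converges to the :func:`propagate` fixed
    point as the number of recorded steps grows.
    """
    config = config or WalkConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    s = _seed_vector(P, pole_seeds)
    seed_ids = np.flatnonzero(s > 0)
    n = len(P.nodes)

    n_walkers = config.mc_n_walks * len(seed_ids)
    cur = np.repeat(seed_ids, config.mc_n_walks)

    # Row-wise cumulative transition probabilities for inverse-CDF sampling.
    P_dense = np.asarray(P.P.todense())
    cum = np.cumsum(P_dense, axis=1)
    cum[:, -1] = 1.0

    visits = np.zeros(n)
    visits += np.bincount(cur, minlength=n)
    for _ in range(config.mc_walk_length):
        u = rng.random(n_walkers)
        restart = rng.random(n_walkers) < (1.0 - config.beta)
        nxt = np.empty(n_walkers, dtype=np.int64)
        for node in np.unique(cur):
            idx = np.flatnonzero(cur == node)
            nxt[idx] = np.searchsorted(cum[node], u[idx], side="right")
        if restart.any():
            nxt[restart] = rng.choice(seed_ids, size=int(restart.sum()))
        cur = nxt
        visits += np.bincount(cur, minlength=n)

    mass = visits / visits.sum()
    return LandingDistribution(nodes=list(P.nodes), mass=mass, pole=",".join(pole_seeds[:3]))


def polarity_score(c: float, a: float) -> float:
    """Per-word score ``c / (c + a)`` in [0, 1].

    ``c`` is the landing mass from the high-rated pole, ``a`` from the
    low-rated pole.  When both masses are zero the word carries no evidence
    and the neutral score 0.5 is returned.
    """
    if c < 0 or a < 0:
        raise ValueError("landing masses must be nonnegative")
    if c + a == 0:
        return 0.5
    return c / (c + a)


def _polarity_vector(c: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tot = c + a
    unsupported = tot == 0
    out = np.full(len(c), 0.5)
    nz = ~unsupported
    out[nz] = c[nz] / tot[nz]
    return out, unsupported


def score_dimension(
    P: TransitionMatrix, seeds: SeedSet, config: WalkConfig | None = None
) -> WordScoreTable:
    """Bootstrap-averaged per-word scores for one dimension.

    For each of ``n_subsets`` rounds, each pole is independently subsampled
    to ``ceil(subset_fraction * pole size)`` seeds without replacement, the
    two landing distributions are solved deterministically, and the
    per-word polarity scores are averaged across rounds.
    """
    config = config or WalkConfig()
    high = [w for w in seeds.high_pole if w in P.index]
    low = [w for w in seeds.low_pole if w in P.index]
    if not high or not low:
        missing_h = [w for w in seeds.high_pole if w not in P.index]
        missing_l = [w for w in seeds.low_pole if w not in P.index]
        raise ValueError(
            f"a seed pole is empty after graph intersection "
            f"(missing high: {missing_h}; missing low: {missing_l})"
        )

    rng = np.random.default_rng(config.rng_seed)
    n = len(P.nodes)
    acc = np.zeros(n)
    unsupported = np.zeros(n, dtype=bool)
    for _ in range(config.n_subsets):
        kh = math.ceil(config.subset_fraction * len(high))
        kl = math.ceil(config.subset_fraction * len(low))
        sub_h = list(rng.choice(high, size=kh, replace=False)) if kh < len(high) else list(high)
        sub_l = list(rng.choice(low, size=kl, replace=False)) if kl < len(low) else list(low)
        c = propagate(P, sub_h, config).mass
        a = propagate(P, sub_l, config).mass
        sc, unsup = _polarity_vector(c, a)
        acc += sc
        unsupported |= unsup
    acc /= config.n_subsets

    return WordScoreTable(
        dimension=seeds.dimension,
        label="",
        scores={w: float(acc[i]) for i, w in enumerate(P.nodes)},
        unsupported=[P.nodes[i] for i in np.flatnonzero(unsupported)],
        provenance={
            "beta": config.beta,
            "n_subsets": config.n_subsets,
            "subset_fraction": config.subset_fraction,
            "rng_seed": config.rng_seed,
            "n_high": len(high),
            "n_low": len(low),
        },
    )


def corpus_score(
    table: WordScoreTable,
    target_words: set[str] | list[str],
    return_missing: bool = False,
) -> float | tuple[float, int]:
    """Unweighted mean word score over the target words present in the table.

    Target words with no score (e.g. isolated graph nodes) are excluded from
    the mean; pass ``return_missing=True`` to get their count as well.
    """
    targets = set(target_words)
    present = [table.scores[w] for w in targets if w in table.scores]
    if not present:
        raise ValueError("no target word has a score in this table")
    mean = float(np.mean(present))
    if return_missing:
        return mean, len(targets) - len(present)
    return mean


def word_mean_across_groups(tables: list[WordScoreTable], word: str) -> float:
    """Mean of one word's scores across all group tables (all must cover it)."""
    missing = [t.label for t in tables if word not in t.scores]
    if missing:
        raise ValueError(f"word {word!r} unscored in groups: {missing}")
    return float(np.mean([t.scores[word] for t in tables]))
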