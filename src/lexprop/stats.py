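"""Statistics for comparing scores across groups and dimensions.

Covers: Spearman validity correlations against human norm ratings, pairwise
Euclidean/Manhattan distances between the five-dimension score vectors of
the groups, cross-dimension correlation with hierarchical clustering, a
conjugate Bayesian linear regression of higher-level on lower-level word
scores, and the static mean-of-norms baseline the dynamic method improves
on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .corpus import FUNCTION_WORDS, SubCorpus
from .propagation import WordScoreTable
from .seeds import NormsTable

__all__ = [
    "spearman",
    "DistanceMatrix",
    "group_distances",
    "dimension_correlations",
    "Dendrogram",
    "cluster_dimensions",
    "plot_correlation_heatmap",
    "RegressionSummary",
    "bayesian_regression",
    "StaticScore",
    "static_lpp_score",
]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties, t-approximation p).

    Raises on constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman is undefined for a constant sequence")
    rho, p = sp_stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean and Manhattan distances between group score vectors."""

    labels: list[str]
    euclidean: pd.DataFrame
    manhattan: pd.DataFrame


def group_distances(corpus_scores: pd.DataFrame) -> DistanceMatrix:
    """Distances between the per-group dimension-score vectors.

    ``corpus_scores`` is a groups x dimensions frame (one row per group);
    any missing entry is an error because the distance would silently change
    meaning.
    """
    if corpus_scores.isna().any().any():
        bad = corpus_scores.isna().any(axis=1)
        raise ValueError(f"missing dimension scores for groups: {list(corpus_scores.index[bad])}")
    labels = list(corpus_scores.index)
    X = corpus_scores.to_numpy(dtype=float)
    eu = squareform(pdist(X, metric="euclidean"))
    ma = squareform(pdist(X, metric="cityblock"))
    return DistanceMatrix(
        labels=labels,
        euclidean=pd.DataFrame(eu, index=labels, columns=labels),
        manhattan=pd.DataFrame(ma, index=labels, columns=labels),
    )


def dimension_correlations(
    word_scores: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations among dimensions over per-word aggregated scores.

    ``word_scores`` is a words x dimensions frame.  Returns the symmetric
    correlation matrix and the matching two-sided p-value matrix (p = 0 on
    the diagonal).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if len(word_scores) < 3:
        raise ValueError("need at least 3 common words")
    dims = list(word_scores.columns)
    k = len(dims)
    corr = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = word_scores.iloc[:, i].to_numpy(dtype=float)
            y = word_scores.iloc[:, j].to_numpy(dtype=float)
            if method == "spearman":
                r, p = spearman(x, y)
            else:
                r, p = sp_stats.pearsonr(x, y)
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(corr, index=dims, columns=dims),
        pd.DataFrame(pval, index=dims, columns=dims),
    )


@dataclass
class Dendrogram:
    """Agglomerative merge tree over dimension labels.

    ``merges`` is the scipy linkage matrix; heights are 1 - r distances.
    """

    labels: list[str]
    merges: np.ndarray

    def merge_list(self) -> list[dict]:
        """Merges as JSON-friendly dicts with member leaves and heights."""
        n = len(self.labels)
        members: dict[int, list[str]] = {i: [self.labels[i]] for i in range(n)}
        out = []
        for step, (a, b, h, _cnt) in enumerate(self.merges):
            ai, bi = int(a), int(b)
            merged = sorted(members[ai] + members[bi])
            members[n + step] = merged
            out.append({"height": float(h), "members": merged})
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.merges)

        def rec(node, parent_h: float) -> str:
            length = max(parent_h - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def cluster_dimensions(corr: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Hierarchical clustering of dimensions at distance d = 1 - r."""
    mat = corr.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-9):
        raise ValueError("correlation matrix must have a unit diagonal")
    d = 1.0 - mat
    np.fill_diagonal(d, 0.0)
    np.maximum(d, 0.0, out=d)
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    return Dendrogram(labels=list(corr.columns), merges=Z)


def plot_correlation_heatmap(corr: pd.DataFrame, path: str, linkage: str = "complete") -> None:
    """Optional PNG heatmap of the dimension correlation matrix, ordered by
    the dendrogram's leaf order.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dendro = cluster_dimensions(corr, linkage=linkage)
    order = hierarchy.leaves_list(dendro.merges)
    labels = [corr.columns[i] for i in order]
    mat = corr.to_numpy()[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_yticks(range(len(labels)), labels)
    fig.colorbar(im, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class CoefficientSummary(NamedTuple):
    name: str
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class RegressionSummary:
    """Posterior coefficient summaries of one Bayesian linear regression."""

    response: str
    coefficients: list[CoefficientSummary]
    n_obs: int
    sigma2_mean: float

    def coefficient(self, name: str) -> CoefficientSummary:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)


def bayesian_regression(
    predictors: pd.DataFrame,
    response: pd.Series,
    response_label: str | None = None,
    prior_scale: float = 1e3,
    prior_a: float = 1e-3,
    prior_b: float = 1e-3,
    method: str = "conjugate",
    n_samples: int = 5000,
    rng_seed: int = 0,
) -> RegressionSummary:
    """Bayesian linear regression with a weakly informative conjugate prior.

    The normal-inverse-gamma prior (coefficients ~ N(0, prior_scale^2 *
    sigma^2 I), sigma^2 ~ InvGamma(prior_a, prior_b)) yields a closed-form
    Student-t posterior for the coefficients; 95% credible intervals come
    from that marginal.  ``method='gibbs'`` instead draws from the same
    posterior by Gibbs sampling — an MCMC cross-check of the closed form.
    An intercept column is always added.
    """
    common = predictors.index.intersection(response.index)
    if len(common) < 10:
        raise ValueError(f"need >= 10 common observations, got {len(common)}")
    X = predictors.loc[common].to_numpy(dtype=float)
    y = response.loc[common].to_numpy(dtype=float)
    names = ["(intercept)"] + list(predictors.columns)
    X = np.column_stack([np.ones(len(X)), X])
    n, k = X.shape

    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular design matrix")

    V0_inv = np.eye(k) / prior_scale**2
    Vn_inv = V0_inv + X.T @ X
    Vn = np.linalg.inv(Vn_inv)
    bn = Vn @ (X.T @ y)
    an = prior_a + n / 2.0
    bn_ig = prior_b + 0.5 * (y @ y - bn @ Vn_inv @ bn)
    sigma2_mean = bn_ig / (an - 1.0) if an > 1 else float("nan")

    if method == "conjugate":
        scale = np.sqrt(bn_ig / an * np.diag(Vn))
        tq = sp_stats.t.ppf(0.975, df=2.0 * an)
        coefs = [
            CoefficientSummary(names[i], float(bn[i]),
                               float(bn[i] - tq * scale[i]),
                               float(bn[i] + tq * scale[i]))
            for i in range(k)
        ]
    elif method == "gibbs":
        rng = np.random.default_rng(rng_seed)
        draws = np.empty((n_samples, k))
        chol = np.linalg.cholesky(Vn)
        for t in range(n_samples):
            sigma2 = 1.0 / rng.gamma(an, 1.0 / bn_ig)
            draws[t] = bn + np.sqrt(sigma2) * (chol @ rng.standard_normal(k))
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        mean = draws.mean(axis=0)
        coefs = [
            CoefficientSummary(names[i], float(mean[i]), float(lo[i]), float(hi[i]))
            for i in range(k)
        ]
    else:
        raise ValueError("method must be 'conjugate' or 'gibbs'")

    return RegressionSummary(
        response=response_label or str(response.name),
        coefficients=coefs,
        n_obs=n,
        sigma2_mean=float(sigma2_mean),
    )


def regress_levels(
    tables: list[WordScoreTable], response_table: WordScoreTable, **kwargs
) -> RegressionSummary:
    """Regress a higher group's word scores on one or more lower groups'."""
    words = set(response_table.scores)
    for t in tables:
        words &= set(t.scores)
    words_sorted = sorted(words)
    X = pd.DataFrame(
        {t.label or f"x{i}": [t.scores[w] for w in words_sorted] for i, t in enumerate(tables)},
        index=words_sorted,
    )
    y = pd.Series([response_table.scores[w] for w in words_sorted], index=words_sorted)
    return bayesian_regression(X, y, response_label=response_table.label, **kwargs)


@dataclass
class StaticScore:
    """Result of the static mean-of-norms baseline."""

    score: float
    coverage: float  # fraction of corpus types (or tokens) covered by norms
    n_covered: int

    def __float__(self) -> float:  # convenience for arithmetic in reports
        return self.score


def static_lpp_score(
    subcorpus: SubCorpus,
    norms: NormsTable,
    frequency_weighted: bool = False,
    content_only: bool = False,
    stoplist: frozenset[str] = FUNCTION_WORDS,
) -> StaticScore:
    """Static norms-lookup baseline on the raw rating scale.

    Unweighted: mean rating over the *unique* covered words, so duplicating
    documents cannot change it.  Frequency-weighted: token-count-weighted
    mean, sum(count_w * rating_w) / sum(count_w).  ``content_only`` drops
    stoplist words first (the content-word convention of norms-lookup
    tools).
    """
    words = set(subcorpus.counts)
    if content_only:
        words -= stoplist
    covered = sorted(w for w in words if w in norms.entries)
    if not covered:
        raise ValueError(
            f"no words of sub-corpus {subcorpus.label!r} are covered by the "
            f"{norms.dimension} norms"
        )
    if frequency_weighted:
        weights = np.array([subcorpus.counts[w] for w in covered], dtype=float)
        ratings = np.array([norms.entries[w] for w in covered])
        score = float((weights * ratings).sum() / weights.sum())
    else:
        score = float(np.mean([norms.entries[w] for w in covered]))
    coverage = len(covered) / len(words) if words else 0.0
    return StaticScore(score=score, coverage=coverage, n_covered=len(covered))
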