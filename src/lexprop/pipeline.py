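"""End-to-end orchestration: one config in, score tables and statistics out.

``run_score`` executes corpus reading -> embeddings -> graph -> seeds ->
propagation for every (group, dimension) pair and writes word-score TSVs, a
group x dimension corpus-score matrix, a QC report (isolated words, seed
coverage) and a provenance JSON.  ``run_compare`` consumes the score tables
and writes validity correlations, distance matrices, the cross-dimension
correlation matrix with its dendrogram, and adjacent-level regression
summaries.  Outputs on the deterministic solver path are byte-identical for
equal config hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus import CorpusCollection, TokenizerConfig, read_subcorpus, shared_words
from .embeddings import EmbeddingConfig, reference_embeddings, train_embeddings
from .graph import GraphConfig, build_knn_graph, to_transition_matrix
from .propagation import WalkConfig, WordScoreTable, corpus_score, score_dimension
from .seeds import (NormsTable, SeedSelectionConfig, TopicModelConfig,
                    normalize_rating, select_seeds, topic_top_words)
from .stats import (bayesian_regression, cluster_dimensions,
                    dimension_correlations, group_distances, spearman)

__all__ = ["RunConfig", "run_score", "run_compare", "ValidationError", "StageError"]

log = logging.getLogger("lexprop")


class ValidationError(ValueError):
    """Configuration or input validation failure (CLI exit code 2)."""


class StageError(RuntimeError):
    """Failure inside a pipeline stage (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Everything one scoring run needs, loadable from a single YAML file."""

    corpora: list[tuple[str, str]]  # (group label, path) in group order
    norms_files: dict[str, str]  # dimension -> norms TSV path
    output_dir: str = "lexprop_out"
    one_doc_per_line: bool = True
    trainer: str = "reference"  # "reference" (PPMI-SVD) or "sgns"
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    walk: WalkConfig = field(default_factory=WalkConfig)
    seed_selection: SeedSelectionConfig = field(default_factory=SeedSelectionConfig)
    topics: TopicModelConfig = field(default_factory=TopicModelConfig)
    use_topic_filter: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        kwargs["corpora"] = [(str(c["label"]), str(c["path"])) for c in raw.get("corpora", [])]
        kwargs["norms_files"] = {str(k): str(v) for k, v in raw.get("norms_files", {}).items()}
        for key in ("output_dir", "one_doc_per_line", "trainer", "use_topic_filter", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, klass in (
            ("tokenizer", TokenizerConfig),
            ("embedding", EmbeddingConfig),
            ("graph", GraphConfig),
            ("walk", WalkConfig),
            ("seed_selection", SeedSelectionConfig),
            ("topics", TopicModelConfig),
        ):
            if key in raw:
                section = dict(raw[key])
                for fname in ("stoplist", "function_word_stoplist", "restrict_to"):
                    if fname in section and section[fname] is not None:
                        section[fname] = frozenset(section[fname])
                if "subword_ngrams" in section and section["subword_ngrams"] is not None:
                    section["subword_ngrams"] = tuple(section["subword_ngrams"])
                kwargs[key] = klass(**section)
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientifically relevant settings (where outputs are
        written and how much is logged do not affect results)."""
        payload = _as_jsonable(self)
        payload.pop("output_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if not self.corpora:
            raise ValidationError("no corpora configured")
        if self.trainer not in ("reference", "sgns"):
            raise ValidationError(f"unknown trainer {self.trainer!r}")
        for label, path in self.corpora:
            if not Path(path).exists():
                raise ValidationError(f"corpus path for group {label!r} does not exist: {path}")
        if not self.norms_files:
            raise ValidationError("no norms files configured")
        for dim, path in self.norms_files.items():
            if not Path(path).exists():
                raise ValidationError(
                    f"norms file for dimension {dim!r} does not exist: {path}"
                )


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    return obj


def _setup_logging(level: str) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
        return False


def run_score(config: RunConfig) -> dict:
    """Execute the full scoring pipeline and write all outputs.

    Returns a dict with the in-memory score tables (``tables``), the corpus
    score matrix (``corpus_scores``) and the QC report (``qc``).
    """
    _setup_logging(config.log_level)
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    try:
        with _StageTimer("read-corpora"):
            collection = CorpusCollection(
                [
                    read_subcorpus(path, label, config.tokenizer, config.one_doc_per_line)
                    for label, path in config.corpora
                ]
            )
            targets = shared_words(collection, 1)
            log.info("%d groups, %d shared target words", len(collection), len(targets))

        with _StageTimer("norms"):
            norms = {
                dim: NormsTable.from_tsv(path, dimension=dim)
                for dim, path in config.norms_files.items()
            }

        with _StageTimer("topics"):
            topic_words = (
                topic_top_words(collection, config.topics) if config.use_topic_filter else None
            )

        with _StageTimer("seeds"):
            seed_sets = {
                dim: select_seeds(collection, table, topic_words, config.seed_selection)
                for dim, table in norms.items()
            }

        trainer = reference_embeddings if config.trainer == "reference" else train_embeddings
        tables: dict[tuple[str, str], WordScoreTable] = {}
        qc: dict = {"config_hash": chash, "groups": {}}
        for sc in collection:
            with _StageTimer(f"embed+score[{sc.label}]"):
                emb = trainer(sc, config.embedding)
                graph = build_knn_graph(emb, config.graph)
                P = to_transition_matrix(graph)
                group_qc = {"isolated_words": graph.isolated, "dimensions": {}}
                for dim, seeds in seed_sets.items():
                    table = score_dimension(P, seeds, config.walk)
                    table.label = sc.label
                    tables[(sc.label, dim)] = table
                    table.to_tsv(out / f"scores_{sc.label}_{dim}.tsv",
                                 header_comment=f"config={chash}")
                    group_qc["dimensions"][dim] = {
                        "n_scored": len(table.scores),
                        "n_unsupported": len(table.unsupported),
                        "seed_high_in_graph": sum(w in P.index for w in seeds.high_pole),
                        "seed_low_in_graph": sum(w in P.index for w in seeds.low_pole),
                    }
                qc["groups"][sc.label] = group_qc

        with _StageTimer("corpus-scores"):
            dims = sorted(norms)
            matrix = pd.DataFrame(
                {
                    dim: [corpus_score(tables[(g, dim)], targets) for g in collection.labels]
                    for dim in dims
                },
                index=collection.labels,
            )
            with open(out / "corpus_scores.tsv", "w", encoding="utf-8") as fh:
                fh.write(f"# config={chash}\n")
                matrix.to_csv(fh, sep="\t", float_format="%.8f")
            matrix_json = {"config_hash": chash, "scores": matrix.round(8).to_dict(orient="index")}
            (out / "corpus_scores.json").write_text(json.dumps(matrix_json, indent=2, sort_keys=True))

        (out / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
        provenance = {
            "config_hash": chash,
            "config": _as_jsonable(config),
            "lexprop_version": __version__,
            "numpy_version": np.__version__,
            "n_target_words": len(targets),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    except ValidationError:
        raise
    except (ValueError, RuntimeError, OSError) as exc:
        raise StageError(str(exc)) from exc

    return {"tables": tables, "corpus_scores": matrix, "qc": qc, "targets": targets}


def run_compare(
    tables: dict[tuple[str, str], WordScoreTable],
    corpus_scores: pd.DataFrame,
    norms: dict[str, NormsTable],
    output_dir: str | Path,
    group_order: list[str] | None = None,
    config_hash: str = "",
) -> dict:
    """Cross-group and cross-dimension statistics over existing score tables."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = group_order or list(corpus_scores.index)
    if len(groups) < 2:
        raise ValidationError("comparison requires at least 2 scored groups")
    dims = sorted({dim for (_g, dim) in tables})

    # Per-word scores aggregated across groups, one column per dimension.
    common: set[str] | None = None
    for key, t in tables.items():
        common = set(t.scores) if common is None else common & set(t.scores)
    if not common:
        counts = {f"{g}/{d}": len(t.scores) for (g, d), t in tables.items()}
        raise ValidationError(f"no words shared by all score tables: {counts}")
    words = sorted(common)
    agg = pd.DataFrame(
        {
            dim: [float(np.mean([tables[(g, dim)].scores[w] for g in groups])) for w in words]
            for dim in dims
        },
        index=words,
    )

    # Validity: Spearman between aggregated scores and normalized human ratings.
    validity = {}
    for dim in dims:
        if dim not in norms:
            continue
        table = norms[dim]
        covered = [w for w in words if w in table.entries]
        if len(covered) >= 3:
            human = [normalize_rating(table.entries[w], table) for w in covered]
            est = [agg.loc[w, dim] for w in covered]
            try:
                rho, p = spearman(est, human)
                validity[dim] = {"rho": rho, "p": p, "n": len(covered)}
            except ValueError as exc:
                validity[dim] = {"error": str(exc), "n": len(covered)}

    dist = group_distances(corpus_scores.loc[groups])
    corr, pval = dimension_correlations(agg)
    dendro = cluster_dimensions(corr) if len(dims) >= 2 else None

    regressions = {}
    for i in range(1, len(groups)):
        lower, higher = groups[i - 1], groups[i]
        per_dim = {}
        for dim in dims:
            lo_t, hi_t = tables[(lower, dim)], tables[(higher, dim)]
            shared = sorted(set(lo_t.scores) & set(hi_t.scores))
            X = pd.DataFrame({lower: [lo_t.scores[w] for w in shared]}, index=shared)
            y = pd.Series([hi_t.scores[w] for w in shared], index=shared, name=higher)
            summary = bayesian_regression(X, y, response_label=higher)
            coef = summary.coefficient(lower)
            per_dim[dim] = {
                "mean": coef.mean,
                "ci_low": coef.ci_low,
                "ci_high": coef.ci_high,
                "n": summary.n_obs,
            }
        regressions[f"{lower}->{higher}"] = per_dim

    header = f"# config={config_hash}\n" if config_hash else ""
    for name, frame in (
        ("distance_euclidean.tsv", dist.euclidean),
        ("distance_manhattan.tsv", dist.manhattan),
        ("dimension_correlations.tsv", corr),
        ("dimension_correlation_pvalues.tsv", pval),
    ):
        with open(out / name, "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", float_format="%.8f")
    if dendro is not None:
        (out / "dimension_dendrogram.newick").write_text(dendro.to_newick() + "\n")
        (out / "dimension_dendrogram.json").write_text(
            json.dumps({"config_hash": config_hash, "merges": dendro.merge_list()}, indent=2)
        )
    (out / "validity.json").write_text(
        json.dumps({"config_hash": config_hash, "spearman": validity}, indent=2, sort_keys=True)
    )
    (out / "regressions.json").write_text(
        json.dumps({"config_hash": config_hash, "adjacent_level": regressions},
                   indent=2, sort_keys=True)
    )
    return {
        "validity": validity,
        "distances": dist,
        "dimension_correlations": corr,
        "dendrogram": dendro,
        "regressions": regressions,
        "aggregated_word_scores": agg,
    }
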