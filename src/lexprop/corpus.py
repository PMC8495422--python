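"""Corpora partitioned into labelled groups (e.g. CEFR proficiency levels).

A :class:`SubCorpus` is a bag of tokenized documents for one learner group
together with its vocabulary counts; a :class:`CorpusCollection` is the ordered
set of groups being compared.  Group order carries meaning downstream
("adjacent level" regressions compare neighbouring entries).

Tokenization is deliberately simple and fully configurable: words are maximal
runs of Unicode letters, optionally with internal apostrophes or hyphens, and
function words are *kept* by default — scoring every word of the corpus,
function words included, is a core feature of the dynamic approach as opposed
to content-word-only norm lookups.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FUNCTION_WORDS",
    "TokenizerConfig",
    "SubCorpus",
    "CorpusCollection",
    "tokenize",
    "build_subcorpus",
    "shared_words",
    "read_subcorpus",
]

#: A small English function-word stoplist (pronouns, determiners, prepositions,
#: conjunctions, auxiliaries).  Used only where a *content-word* filter is
#: explicitly requested (seed selection, the static baseline's content_only
#: mode); the propagation pipeline itself never drops these words.
FUNCTION_WORDS: frozenset[str] = frozenset(
    """
    a an the this that these those some any each every no neither either
    i you he she it we they me him her us them my your his its our their
    mine yours hers ours theirs myself yourself himself herself itself
    ourselves themselves who whom whose which what
    in on at by for with about against between into through during before
    after above below to from up down out off over under again further of
    and or but nor so yet if then than as because while when where how why
    not only also very too just there here
    be am is are was were been being have has had having do does did doing
    will would shall should can could may might must ought
    """.split()
)


@dataclass(frozen=True)
class TokenizerConfig:
    """Rules for turning raw text into tokens.

    ``keep_function_words=True`` guarantees that no alphabetic token is ever
    discarded; setting it to ``False`` removes tokens found in ``stoplist``.
    ``drop_numerals`` controls whether digit runs are dropped (default) or
    kept as tokens.
    """

    lowercase: bool = True
    keep_function_words: bool = True
    drop_numerals: bool = True
    keep_internal_apostrophes: bool = True
    keep_internal_hyphens: bool = False
    stoplist: frozenset[str] = FUNCTION_WORDS

    def token_pattern(self) -> re.Pattern[str]:
        letter = r"[^\W\d_]"
        joiners = ""
        if self.keep_internal_apostrophes:
            joiners += "'’"
        if self.keep_internal_hyphens:
            joiners += "-"
        if joiners:
            word = f"{letter}+(?:[{joiners}]{letter}+)*"
        else:
            word = f"{letter}+"
        if self.drop_numerals:
            return re.compile(word)
        return re.compile(f"{word}|[0-9]+")


def tokenize(text: str, config: TokenizerConfig | None = None) -> list[str]:
    """Split ``text`` into tokens under ``config``.  Empty text gives ``[]``."""
    config = config or TokenizerConfig()
    tokens = config.token_pattern().findall(text)
    if config.lowercase:
        tokens = [t.lower() for t in tokens]
    # Normalise curly apostrophes so vocabulary keys are stable.
    tokens = [t.replace("’", "'") for t in tokens]
    if not config.keep_function_words:
        tokens = [t for t in tokens if t not in config.stoplist]
    return tokens


@dataclass
class SubCorpus:
    """One labelled group of tokenized documents with vocabulary counts."""

    label: str
    documents: list[list[str]]
    counts: Counter = field(default_factory=Counter)
    n_tokens: int = 0

    def __post_init__(self) -> None:
        if not self.counts and any(self.documents):
            self._recount()

    def _recount(self) -> None:
        c: Counter = Counter()
        for doc in self.documents:
            c.update(doc)
        self.counts = c
        self.n_tokens = sum(c.values())

    @property
    def vocabulary(self) -> set[str]:
        return set(self.counts)

    def __len__(self) -> int:
        return len(self.documents)

    def validate(self) -> None:
        """Check count/token bookkeeping against the stored documents."""
        c: Counter = Counter()
        for doc in self.documents:
            c.update(doc)
        if c != self.counts:
            raise ValueError(f"counts of sub-corpus {self.label!r} are stale")
        if sum(self.counts.values()) != self.n_tokens:
            raise ValueError(f"n_tokens of sub-corpus {self.label!r} is stale")

    def export_vocabulary(self, path: str | Path) -> None:
        """Write the vocabulary as ``word<TAB>count`` sorted by word."""
        with open(path, "w", encoding="utf-8") as fh:
            for word in sorted(self.counts):
                fh.write(f"{word}\t{self.counts[word]}\n")


def build_subcorpus(
    documents: Iterable[str],
    label: str,
    config: TokenizerConfig | None = None,
) -> SubCorpus:
    """Tokenize raw document strings into a :class:`SubCorpus`."""
    config = config or TokenizerConfig()
    docs = [tokenize(d, config) for d in documents]
    sc = SubCorpus(label=label, documents=docs)
    sc._recount()
    return sc


def read_subcorpus(
    path: str | Path,
    label: str | None = None,
    config: TokenizerConfig | None = None,
    one_doc_per_line: bool = True,
) -> SubCorpus:
    """Read a sub-corpus from a ``.txt`` file or a directory of ``.txt`` files.

    With ``one_doc_per_line`` each non-empty line of a file is a document;
    otherwise each file is a single document.  The group label defaults to the
    file stem / directory name.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"corpus path does not exist: {p}")
    if p.is_dir():
        files = sorted(p.glob("*.txt"))
        if not files:
            raise IOError(f"no .txt files under corpus directory: {p}")
        label = label or p.name
    else:
        files = [p]
        label = label or p.stem
    raw_docs: list[str] = []
    for f in files:
        try:
            text = f.read_text(encoding="utf-8")
        except OSError as exc:  # pragma: no cover - depends on FS state
            raise IOError(f"cannot read corpus file {f}: {exc}") from exc
        if one_doc_per_line:
            raw_docs.extend(line for line in text.splitlines() if line.strip())
        else:
            raw_docs.append(text)
    return build_subcorpus(raw_docs, label, config)


class CorpusCollection:
    """Ordered collection of :class:`SubCorpus` with unique labels."""

    def __init__(self, subcorpora: Sequence[SubCorpus]):
        labels = [sc.label for sc in subcorpora]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate sub-corpus labels: {labels}")
        self.subcorpora: list[SubCorpus] = list(subcorpora)

    @property
    def labels(self) -> list[str]:
        return [sc.label for sc in self.subcorpora]

    def __iter__(self):
        return iter(self.subcorpora)

    def __len__(self) -> int:
        return len(self.subcorpora)

    def __getitem__(self, key: int | str) -> SubCorpus:
        if isinstance(key, int):
            return self.subcorpora[key]
        for sc in self.subcorpora:
            if sc.label == key:
                return sc
        raise KeyError(key)

    def pooled_documents(self) -> list[list[str]]:
        """All documents of all groups, in group order (for topic modeling)."""
        out: list[list[str]] = []
        for sc in self.subcorpora:
            out.extend(sc.documents)
        return out


def shared_words(collection: CorpusCollection, min_count: int = 1) -> list[str]:
    """Words occurring at least ``min_count`` times in *every* sub-corpus.

    Returned sorted, so the target-word order is deterministic.
    """
    if len(collection) == 0:
        raise ValueError("shared_words requires a non-empty collection")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    shared: set[str] | None = None
    for sc in collection:
        ok = {w for w, c in sc.counts.items() if c >= min_count}
        shared = ok if shared is None else shared & ok
    return sorted(shared or set())
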