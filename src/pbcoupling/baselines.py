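"""Baseline inter-article similarity measures: bibliographic coupling and a
BM25-based text measure.

Bibliographic coupling (BC) is the Jaccard overlap of the sets of works two
articles cite.  The BM25 measure ("OK") scores two articles by summing, over
their shared terms, the product of each article's BM25 term-saturation factor
with an idf term log2(N/n)::

    OK(d1,d2) = Σ_t  TF(t,d1)(k1+1) / (TF(t,d1) + k1(1-b+b|d1|/avgdl))
                   × TF(t,d2)(k1+1) / (TF(t,d2) + k1(1-b+b|d2|/avgdl))
                   × log2(N/n)

with k1 = 8 and b = 1.0 by default.  Two field views are supported: the
title+abstract view and the whole-article view; both run through the same
scorer and differ only in the corpus statistics they are given.  The
collection statistics (N, document frequencies, avgdl) are computed over the
evaluation corpus itself.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .corpus import Article, Corpus
from .errors import ConfigError, SchemaError, ValidationError


def _identity_set(article: Article) -> frozenset[str]:
    """Resolved citation identities; unresolved references get a sentinel
    unique to (article, ref) so they enlarge the union but never match."""
    out = set()
    for ref in article.references:
        if ref.cited_article_id is not None:
            out.add(ref.cited_article_id)
        else:
            out.add(f"unresolved:{article.article_id}:{ref.ref_id}")
    return frozenset(out)


def bc_similarity(article_1: Article, article_2: Article) -> float:
    """Bibliographic coupling: |O1 ∩ O2| / |O1 ∪ O2|; 0 when both empty."""
    o1 = _identity_set(article_1)
    o2 = _identity_set(article_2)
    union = len(o1 | o2)
    if union == 0:
        return 0.0
    return len(o1 & o2) / union


class FieldView(str, enum.Enum):
    TITLE_ABSTRACT = "title_abstract"
    WHOLE_ARTICLE = "whole_article"


def _field_tokens(article: Article, view: FieldView) -> tuple[str, ...]:
    if view is FieldView.TITLE_ABSTRACT:
        return article.title_tokens + article.abstract_tokens
    return article.title_tokens + article.body_tokens


@dataclass(frozen=True)
class Bm25Params:
    k1: float = 8.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ConfigError("k1 must be positive")
        if not 0.0 <= self.b <= 1.0:
            raise ConfigError("b must lie in [0, 1]")


@dataclass
class CorpusStats:
    """Collection statistics for one field view."""

    field_view: FieldView
    N: int
    doc_freq: dict[str, int]
    avgdl: float
    term_freq: dict[str, Counter]
    doc_len: dict[str, int]


def build_corpus_stats(
    corpus: Corpus, field_view: FieldView = FieldView.WHOLE_ARTICLE
) -> CorpusStats:
    if len(corpus) == 0:
        raise ValidationError("cannot build statistics for an empty corpus")
    term_freq: dict[str, Counter] = {}
    doc_len: dict[str, int] = {}
    doc_freq: Counter = Counter()
    for article in corpus:
        tokens = _field_tokens(article, field_view)
        tf = Counter(tokens)
        term_freq[article.article_id] = tf
        doc_len[article.article_id] = len(tokens)
        doc_freq.update(tf.keys())
    avgdl = sum(doc_len.values()) / len(doc_len)
    return CorpusStats(
        field_view=field_view,
        N=len(corpus),
        doc_freq=dict(doc_freq),
        avgdl=avgdl,
        term_freq=term_freq,
        doc_len=doc_len,
    )


def _saturation(tf: int, dl: int, stats: CorpusStats, params: Bm25Params) -> float:
    denom = tf + params.k1 * (1.0 - params.b + params.b * dl / stats.avgdl)
    return tf * (params.k1 + 1.0) / denom


def ok_similarity(
    article_1: Article,
    article_2: Article,
    corpus_stats: CorpusStats,
    params: Bm25Params = Bm25Params(),
) -> float:
    """BM25-product similarity over shared terms, non-negative, symmetric."""
    try:
        tf1 = corpus_stats.term_freq[article_1.article_id]
        tf2 = corpus_stats.term_freq[article_2.article_id]
    except KeyError as exc:
        raise ValidationError(f"article {exc.args[0]!r} missing from corpus stats")
    dl1 = corpus_stats.doc_len[article_1.article_id]
    dl2 = corpus_stats.doc_len[article_2.article_id]
    score = 0.0
    for term in tf1.keys() & tf2.keys():
        n = corpus_stats.doc_freq[term]
        idf = math.log2(corpus_stats.N / n)
        if idf == 0.0:
            continue
        score += (
            _saturation(tf1[term], dl1, corpus_stats, params)
            * _saturation(tf2[term], dl2, corpus_stats, params)
            * idf
        )
    return score


# ---------------------------------------------------------------------------
# External (pre-recorded) score tables
# ---------------------------------------------------------------------------


class ExternalScoreTable:
    """Per-pair similarity scores recorded by an external system.

    Lets pre-computed scores (e.g. a hybrid measure whose formula lives
    elsewhere) flow through the same ranking/evaluation pipeline.  The file
    is TSV with a header line ``target_id<TAB>candidate_id<TAB>score``.
    """

    def __init__(self, scores: dict[tuple[str, str], float], name: str = "external"):
        self.scores = scores
        self.name = name

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "ExternalScoreTable":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines:
            raise SchemaError(f"external score file {path} is empty")
        header = lines[0].split("\t")
        if header[:3] != ["target_id", "candidate_id", "score"]:
            raise SchemaError(
                f"external score file {path}: expected header "
                f"'target_id\\tcandidate_id\\tscore', found {header!r}"
            )
        scores: dict[tuple[str, str], float] = {}
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SchemaError(f"external score file line {lineno}: need 3 fields")
            scores[(parts[0], parts[1])] = float(parts[2])
        return cls(scores, name=name or Path(path).stem)

    def __call__(self, target: Article, candidate: Article) -> float:
        try:
            return self.scores[(target.article_id, candidate.article_id)]
        except KeyError:
            raise ValidationError(
                f"no recorded score for pair "
                f"({target.article_id!r}, {candidate.article_id!r})"
            )
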