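"""Passage-based bibliographic coupling between articles.

Two references c1 (in article d1) and c2 (in d2) are similar if they resolve
to the same cited work, or — failing that — if the authors of d1 and d2
commented them with similar words, measured as the Jaccard overlap of their
context passages::

    LinkSim(c1,d1,c2,d2) = 1                      if c1 = c2
                           |CP1 ∩ CP2| / |CP1 ∪ CP2|   otherwise

Each pairwise similarity is weighted by the mean importance of the two
references (LinkSimIMP = LinkSim × (IMP1 + IMP2)/2, in [0, 2]) and the
article-level score averages, over every reference of either article, the
best-matching reference of the other article::

    PBC(d1,d2) = [ Σ_{c1} max_{c2} LinkSimIMP + Σ_{c2} max_{c1} LinkSimIMP ]
                 / (|O1| + |O2|)

so PBC is symmetric and lies in [0, 2].  Two ablations keep the weighting
and aggregation but restrict the reference similarity: the link-only component
scores 1 on identical citations and 0 otherwise, while the text-only
component always uses the passage Jaccard term, even for identical
citations.

Pairwise scores and per-reference passages/weights are cached (keyed by the
unordered article pair, the window size and the variant), so repeated
queries are cheap and return identical values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .context import (
    AlphaConfig,
    extract_context_passage,
    importance_freq,
    importance_pos,
    importance_section,
)
from .corpus import Article
from .errors import ConfigError, ValidationError


class ImportanceStrategy(str, enum.Enum):
    FREQUENCY = "frequency"
    POSITION = "position"
    SECTION = "section"


_IMPORTANCE_FN: dict[ImportanceStrategy, Callable[[Article, str], float]] = {
    ImportanceStrategy.FREQUENCY: importance_freq,
    ImportanceStrategy.POSITION: importance_pos,
    ImportanceStrategy.SECTION: importance_section,
}


@dataclass(frozen=True)
class PbcVariant:
    """Which importance strategy and which similarity components are active."""

    importance_strategy: ImportanceStrategy = ImportanceStrategy.FREQUENCY
    link_component_enabled: bool = True
    text_component_enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.link_component_enabled or self.text_component_enabled):
            raise ConfigError("at least one similarity component must be enabled")


PBC = PbcVariant()
PBC_POS = PbcVariant(importance_strategy=ImportanceStrategy.POSITION)
PBC_SECTION = PbcVariant(importance_strategy=ImportanceStrategy.SECTION)
PBC_LINK = PbcVariant(text_component_enabled=False)
PBC_TEXT = PbcVariant(link_component_enabled=False)


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def link_sim(
    ref_id_1: str,
    article_1: Article,
    ref_id_2: str,
    article_2: Article,
    alpha_config: AlphaConfig = AlphaConfig(),
    variant: PbcVariant = PBC,
) -> float:
    """Similarity between two references, in [0, 1]."""
    ref1 = article_1.get_reference(ref_id_1)
    ref2 = article_2.get_reference(ref_id_2)
    identical = (
        ref1.cited_article_id is not None
        and ref1.cited_article_id == ref2.cited_article_id
    )
    if variant.link_component_enabled and identical:
        return 1.0
    if not variant.text_component_enabled:
        return 0.0
    cp1 = extract_context_passage(article_1, ref_id_1, alpha_config).tokens
    cp2 = extract_context_passage(article_2, ref_id_2, alpha_config).tokens
    return _jaccard(cp1, cp2)


def link_sim_imp(
    ref_id_1: str,
    article_1: Article,
    ref_id_2: str,
    article_2: Article,
    alpha_config: AlphaConfig = AlphaConfig(),
    variant: PbcVariant = PBC,
) -> float:
    """Importance-weighted reference similarity, in [0, 2]."""
    sim = link_sim(ref_id_1, article_1, ref_id_2, article_2, alpha_config, variant)
    if sim == 0.0:
        return 0.0
    imp = _IMPORTANCE_FN[variant.importance_strategy]
    return sim * (imp(article_1, ref_id_1) + imp(article_2, ref_id_2)) / 2.0


def pbc_similarity(
    article_1: Article,
    article_2: Article,
    alpha_config: AlphaConfig = AlphaConfig(),
    variant: PbcVariant = PBC,
) -> float:
    """Article-level passage-based coupling score, symmetric, in [0, 2].

    Returns 0 when either article has an empty reference list.
    """
    scorer = PbcScorer(alpha_config=alpha_config, variant=variant)
    return scorer.score(article_1, article_2)


class PbcScorer:
    """Caching scorer for a fixed window size and variant.

    Per-reference context passages and importance weights are computed once
    per article, and pairwise article scores once per unordered pair.
    """

    def __init__(
        self,
        alpha_config: AlphaConfig = AlphaConfig(),
        variant: PbcVariant = PBC,
    ) -> None:
        self.alpha_config = alpha_config
        self.variant = variant
        self._article_cache: dict[str, tuple[tuple[str | None, frozenset[str], float], ...]] = {}
        self._pair_cache: dict[frozenset[str], float] = {}

    def _prepared(self, article: Article):
        cached = self._article_cache.get(article.article_id)
        if cached is not None:
            return cached
        imp = _IMPORTANCE_FN[self.variant.importance_strategy]
        prepared = tuple(
            (
                ref.cited_article_id,
                extract_context_passage(article, ref.ref_id, self.alpha_config).tokens,
                float(imp(article, ref.ref_id)),
            )
            for ref in article.references
        )
        self._article_cache[article.article_id] = prepared
        return prepared

    def _ref_pair_sim(self, item1, item2) -> float:
        identity1, cp1, imp1 = item1
        identity2, cp2, imp2 = item2
        identical = identity1 is not None and identity1 == identity2
        if self.variant.link_component_enabled and identical:
            sim = 1.0
        elif not self.variant.text_component_enabled:
            sim = 0.0
        else:
            sim = _jaccard(cp1, cp2)
        if sim == 0.0:
            return 0.0
        return sim * (imp1 + imp2) / 2.0

    def score(self, article_1: Article, article_2: Article) -> float:
        key = frozenset((article_1.article_id, article_2.article_id))
        cached = self._pair_cache.get(key)
        if cached is not None:
            return cached
        refs1 = self._prepared(article_1)
        refs2 = self._prepared(article_2)
        if not refs1 or not refs2:
            value = 0.0
        else:
            best1 = [0.0] * len(refs1)
            best2 = [0.0] * len(refs2)
            for i, item1 in enumerate(refs1):
                for j, item2 in enumerate(refs2):
                    sim = self._ref_pair_sim(item1, item2)
                    if sim > best1[i]:
                        best1[i] = sim
                    if sim > best2[j]:
                        best2[j] = sim
            value = (sum(best1) + sum(best2)) / (len(refs1) + len(refs2))
        self._pair_cache[key] = value
        return value


# ---------------------------------------------------------------------------
# Rankings and run files
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunRanking:
    """One measure's ranked candidates for one topic.

    Entries are sorted by descending score with ties broken by ascending
    candidate id, so rankings are deterministic.
    """

    topic_id: str
    target_id: str
    entries: tuple[tuple[str, float], ...]
    measure_name: str

    @property
    def ranked_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.entries)

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.entries)


def rank_candidates(
    target_article: Article,
    candidate_articles: Sequence[Article],
    measure: Callable[[Article, Article], float],
    topic_id: str = "",
    measure_name: str = "",
) -> RunRanking:
    """Score candidates against the target and sort them deterministically."""
    scored = [(cand.article_id, float(measure(target_article, cand))) for cand in candidate_articles]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return RunRanking(
        topic_id=topic_id,
        target_id=target_article.article_id,
        entries=tuple(scored),
        measure_name=measure_name,
    )


def write_run(rankings: Iterable[RunRanking], path: str | Path) -> None:
    """Write rankings as TSV: topic, target, candidate, rank, score, measure."""
    lines = []
    for ranking in rankings:
        for rank, (cid, score) in enumerate(ranking.entries, start=1):
            lines.append(
                f"{ranking.topic_id}\t{ranking.target_id}\t{cid}\t{rank}\t"
                f"{score:.10g}\t{ranking.measure_name}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_run(path: str | Path) -> dict[str, RunRanking]:
    """Read a run TSV back into per-topic rankings (one measure per file)."""
    rows: dict[str, list[tuple[int, str, float]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValidationError(
                f"run file line {lineno}: expected 6 tab-separated fields"
            )
        topic_id, target_id, cid, rank, score, measure_name = parts
        rows.setdefault(topic_id, []).append((int(rank), cid, float(score)))
        prev = meta.setdefault(topic_id, (target_id, measure_name))
        if prev != (target_id, measure_name):
            raise ValidationError(
                f"run file line {lineno}: inconsistent target/measure for "
                f"topic {topic_id!r}"
            )
    out: dict[str, RunRanking] = {}
    for topic_id, entries in rows.items():
        entries.sort()
        target_id, measure_name = meta[topic_id]
        out[topic_id] = RunRanking(
            topic_id=topic_id,
            target_id=target_id,
            entries=tuple((cid, score) for _, cid, score in entries),
            measure_name=measure_name,
        )
    return out


def ranking_from_scores(
    topic_id: str,
    target_id: str,
    scores: dict[str, float],
    measure_name: str,
) -> RunRanking:
    """Build a deterministic ranking from a candidate -> score mapping."""
    entries = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return RunRanking(
        topic_id=topic_id,
        target_id=target_id,
        entries=tuple(entries),
        measure_name=measure_name,
    )
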