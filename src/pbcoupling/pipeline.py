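"""Named-measure plumbing: score a whole qrels file with one measure.

Measure names accepted everywhere (CLI, run files, reports):

``pbc``, ``pbc-pos``, ``pbc-section``, ``pbc-link``, ``pbc-text``,
``bc``, ``ok-title-abstract``, ``ok-whole-article``.
"""

from __future__ import annotations

from typing import Callable

from .baselines import (
    Bm25Params,
    FieldView,
    bc_similarity,
    build_corpus_stats,
    ok_similarity,
)
from .context import AlphaConfig
from .corpus import Article, Corpus, Qrels
from .errors import ConfigError
from .similarity import (
    PBC,
    PBC_LINK,
    PBC_POS,
    PBC_SECTION,
    PBC_TEXT,
    PbcScorer,
    PbcVariant,
    RunRanking,
    rank_candidates,
)

PBC_VARIANTS: dict[str, PbcVariant] = {
    "pbc": PBC,
    "pbc-pos": PBC_POS,
    "pbc-section": PBC_SECTION,
    "pbc-link": PBC_LINK,
    "pbc-text": PBC_TEXT,
}

MEASURE_NAMES = tuple(PBC_VARIANTS) + ("bc", "ok-title-abstract", "ok-whole-article")

# Window defaults per variant: 10 suits the frequency- and position-weighted
# variants, 15 the section-weighted one.
DEFAULT_ALPHA: dict[str, int] = {name: 10 for name in PBC_VARIANTS}
DEFAULT_ALPHA["pbc-section"] = 15


def make_measure(
    measure_name: str,
    corpus: Corpus,
    alpha: int | None = None,
    bm25_params: Bm25Params = Bm25Params(),
) -> Callable[[Article, Article], float]:
    """Build a ``(target, candidate) -> score`` callable for a named measure."""
    name = measure_name.lower()
    if name in PBC_VARIANTS:
        alpha_value = alpha if alpha is not None else DEFAULT_ALPHA[name]
        scorer = PbcScorer(alpha_config=AlphaConfig(alpha_value), variant=PBC_VARIANTS[name])
        return scorer.score
    if name == "bc":
        return bc_similarity
    if name in {"ok-title-abstract", "ok-whole-article"}:
        view = (
            FieldView.TITLE_ABSTRACT
            if name == "ok-title-abstract"
            else FieldView.WHOLE_ARTICLE
        )
        stats = build_corpus_stats(corpus, view)
        return lambda a, b: ok_similarity(a, b, stats, bm25_params)
    raise ConfigError(
        f"unknown measure {measure_name!r}; choose one of {', '.join(MEASURE_NAMES)}"
    )


def run_measure(
    corpus: Corpus,
    qrels: Qrels,
    measure_name: str,
    alpha: int | None = None,
    bm25_params: Bm25Params = Bm25Params(),
) -> dict[str, RunRanking]:
    """Rank every topic's candidates against its target article."""
    measure = make_measure(measure_name, corpus, alpha=alpha, bm25_params=bm25_params)
    runs: dict[str, RunRanking] = {}
    for topic in qrels:
        target = corpus[topic.target_id]
        candidates = [corpus[cid] for cid in topic.candidate_ids]
        runs[topic.topic_id] = rank_candidates(
            target,
            candidates,
            measure,
            topic_id=topic.topic_id,
            measure_name=measure_name,
        )
    return runs
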