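"""Ranked-retrieval evaluation: AP/MAP, precision at X, pairs-hit summaries,
paired significance tests, and a loader for recorded per-candidate score
tables.

Average precision for one topic with k relevant candidates is

    AP = (1/k) Σ_{j=1..k}  j / rank(j)

where rank(j) is the 1-based rank of the j-th relevant candidate after the
deterministic tie-break (descending score, then ascending id).  MAP averages
AP over topics.  P@X is the fraction of relevant candidates in the top X, and
the pairs-hit fraction is the share of topics with P@X > 0.  Relevant
candidates missing from a ranking are appended after all scored candidates in
ascending id order — an unranked relevant is effectively ranked last.

Significance between two measures is a two-sided paired t-test on the
per-topic metric vectors (AP, or P@X at a given X), judged at the 0.05
level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .corpus import Qrels, Topic
from .errors import SchemaError, ValidationError
from .similarity import RunRanking, ranking_from_scores

logger = logging.getLogger(__name__)


def _full_ranking(ranked_ids: Sequence[str], relevant_ids: Iterable[str]) -> list[str]:
    """Append relevant ids missing from the ranking, last, in ascending id
    order (they are effectively ranked lowest)."""
    present = set(ranked_ids)
    missing = sorted(set(relevant_ids) - present)
    return list(ranked_ids) + missing


def average_precision(
    ranked_ids: Sequence[str],
    relevant_ids: Iterable[str],
    pessimistic_ties: bool = False,
    scores: Mapping[str, float] | None = None,
) -> float:
    """AP of one ranked list, in [0, 1].

    With ``pessimistic_ties`` (requires ``scores``), the rank of a relevant
    item is the number of candidates whose score is greater than or equal to
    its own, which charges a relevant item for every tied competitor.
    """
    relevant = set(relevant_ids)
    if not relevant:
        raise ValidationError("average precision is undefined for an empty relevant set")
    full = _full_ranking(ranked_ids, relevant)
    j = 0
    total = 0.0
    for position, cid in enumerate(full, start=1):
        if cid not in relevant:
            continue
        j += 1
        if pessimistic_ties and scores is not None and cid in scores:
            # Arc(j) counts every candidate scoring >= the relevant item.
            rank = sum(
                1 for other in full if scores.get(other, float("-inf")) >= scores[cid]
            )
        else:
            rank = position
        total += j / rank
    return total / len(relevant)


def mean_average_precision(per_topic_ap: Mapping[str, float] | Sequence[float]) -> float:
    values = (
        list(per_topic_ap.values())
        if isinstance(per_topic_ap, Mapping)
        else list(per_topic_ap)
    )
    if not values:
        raise ValidationError("MAP is undefined for zero topics")
    return float(np.mean(values))


def precision_at_x(ranked_ids: Sequence[str], relevant_ids: Iterable[str], x: int) -> float:
    if x < 1:
        raise ValidationError("X must be >= 1")
    relevant = set(relevant_ids)
    full = _full_ranking(ranked_ids, relevant)
    return sum(1 for cid in full[:x] if cid in relevant) / x


def average_p_at_x(per_topic_p: Mapping[str, float] | Sequence[float]) -> float:
    values = (
        list(per_topic_p.values())
        if isinstance(per_topic_p, Mapping)
        else list(per_topic_p)
    )
    if not values:
        raise ValidationError("average P@X is undefined for zero topics")
    return float(np.mean(values))


def pairs_hit_fraction(per_topic_p: Mapping[str, float] | Sequence[float]) -> float:
    """Fraction of topics with P@X strictly positive."""
    values = (
        list(per_topic_p.values())
        if isinstance(per_topic_p, Mapping)
        else list(per_topic_p)
    )
    if not values:
        raise ValidationError("pairs-hit fraction is undefined for zero topics")
    return float(np.mean([v > 0 for v in values]))


@dataclass(frozen=True)
class TTestResult:
    p_value: float
    t_statistic: float
    significant: bool
    degenerate: bool = False


def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test at the 0.05 level.

    Degenerate cases are made total: an all-zero difference vector reports
    p = 1.0 (no evidence of any difference), and a constant non-zero
    difference (zero variance) reports p = 0.0 with the ``degenerate`` flag
    set rather than dividing by zero.
    """
    if len(values_a) != len(values_b):
        raise ValidationError("paired t-test requires equal-length vectors")
    if len(values_a) < 2:
        raise ValidationError("paired t-test requires at least 2 pairs")
    diffs = np.asarray(values_a, dtype=float) - np.asarray(values_b, dtype=float)
    if np.all(diffs == 0.0):
        return TTestResult(p_value=1.0, t_statistic=0.0, significant=False)
    if np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-12):
        sign = float(np.sign(diffs[0]))
        return TTestResult(
            p_value=0.0,
            t_statistic=sign * float("inf"),
            significant=True,
            degenerate=True,
        )
    t_stat, p_value = scipy_stats.ttest_rel(values_a, values_b)
    return TTestResult(
        p_value=float(p_value),
        t_statistic=float(t_stat),
        significant=bool(p_value < 0.05),
    )


@dataclass
class EvalReport:
    """Per-topic and aggregate retrieval quality for a set of measures."""

    x_values: tuple[int, ...]
    per_topic_ap: dict[str, dict[str, float]] = field(default_factory=dict)
    per_topic_p_at_x: dict[str, dict[int, dict[str, float]]] = field(default_factory=dict)
    map_value: dict[str, float] = field(default_factory=dict)
    p_at_x: dict[str, dict[int, float]] = field(default_factory=dict)
    pairs_hit: dict[str, dict[int, float]] = field(default_factory=dict)
    significance: dict[str, dict] = field(default_factory=dict)

    def to_json_obj(self) -> dict:
        return {
            "x_values": list(self.x_values),
            "map": self.map_value,
            "average_p_at_x": {
                m: {str(x): v for x, v in d.items()} for m, d in self.p_at_x.items()
            },
            "pairs_hit_fraction": {
                m: {str(x): v for x, v in d.items()} for m, d in self.pairs_hit.items()
            },
            "per_topic_ap": self.per_topic_ap,
            "significance": self.significance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json_obj(), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = {}
        for measure in sorted(self.map_value):
            row = {"MAP": self.map_value[measure]}
            for x in self.x_values:
                row[f"P@{x}"] = self.p_at_x[measure][x]
            for x in self.x_values:
                row[f"hit@{x}"] = self.pairs_hit[measure][x]
            rows[measure] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> str:
        return self.summary_frame().to_string(float_format=lambda v: f"{v:.4f}")


def evaluate_runs(
    runs: Mapping[str, Mapping[str, RunRanking]],
    qrels: Qrels,
    x_values: Sequence[int] = (1, 3, 5),
    t_test_pairs: Sequence[tuple[str, str]] | None = None,
) -> EvalReport:
    """Score every measure's rankings against the qrels.

    ``runs`` maps measure name -> topic id -> ranking.  Every topic in the
    qrels must be covered by every measure.  When ``t_test_pairs`` is None,
    all measure pairs are tested on their AP vectors and per-X P@X vectors.
    """
    if len(qrels) == 0:
        raise ValidationError("cannot evaluate zero topics")
    report = EvalReport(x_values=tuple(x_values))
    topic_ids = [t.topic_id for t in qrels]
    topics: dict[str, Topic] = {t.topic_id: t for t in qrels}
    for measure, per_topic in runs.items():
        missing = set(topic_ids) - set(per_topic)
        if missing:
            raise ValidationError(
                f"measure {measure!r} lacks rankings for topics {sorted(missing)}"
            )
        ap: dict[str, float] = {}
        p_at: dict[int, dict[str, float]] = {x: {} for x in x_values}
        for tid in topic_ids:
            ranking = per_topic[tid]
            relevant = topics[tid].highly_related_ids
            ap[tid] = average_precision(ranking.ranked_ids, relevant)
            for x in x_values:
                p_at[x][tid] = precision_at_x(ranking.ranked_ids, relevant, x)
        report.per_topic_ap[measure] = ap
        report.per_topic_p_at_x[measure] = p_at
        report.map_value[measure] = mean_average_precision(ap)
        report.p_at_x[measure] = {x: average_p_at_x(p_at[x]) for x in x_values}
        report.pairs_hit[measure] = {x: pairs_hit_fraction(p_at[x]) for x in x_values}

    measures = sorted(runs)
    if t_test_pairs is None:
        t_test_pairs = [
            (a, b) for i, a in enumerate(measures) for b in measures[i + 1 :]
        ]
    if len(topic_ids) >= 2:
        for a, b in t_test_pairs:
            for metric, getter in [("AP", lambda m: report.per_topic_ap[m])] + [
                (f"P@{x}", lambda m, x=x: report.per_topic_p_at_x[m][x])
                for x in x_values
            ]:
                va = [getter(a)[tid] for tid in topic_ids]
                vb = [getter(b)[tid] for tid in topic_ids]
                result = paired_t_test(va, vb)
                report.significance[f"{a} vs {b} [{metric}]"] = {
                    "p_value": result.p_value,
                    "t_statistic": result.t_statistic,
                    "significant": result.significant,
                    "degenerate": result.degenerate,
                }
    return report


# ---------------------------------------------------------------------------
# Recorded similarity tables (supplementary-run layout)
# ---------------------------------------------------------------------------

S1_MEASURES = (
    "PBC",
    "PBC-Pos",
    "PBC-Section",
    "BC",
    "OK-TitleAbstract",
    "OK-WholeArticle",
    "HybridK50-TitleAbstract",
    "HybridK50-WholeArticle",
)

_S1_KEY_COLUMNS = ("topic_id", "target_id", "candidate_id", "highly_related")


def load_s1_run(path: str | Path) -> tuple[Qrels, dict[str, dict[str, RunRanking]]]:
    """Load a recorded-similarity table into qrels plus one run per measure.

    The expected layout is tab-separated text with a header row naming the
    four key columns ``topic_id, target_id, candidate_id, highly_related``
    followed by one column per recorded measure (see :data:`S1_MEASURES`).
    Topics without any highly related candidate are dropped with a warning;
    an unknown column layout raises :class:`SchemaError` listing the headers
    found.
    """
    df = pd.read_csv(path, sep="\t", dtype={"highly_related": int})
    missing = [c for c in _S1_KEY_COLUMNS + S1_MEASURES if c not in df.columns]
    if missing:
        raise SchemaError(
            f"recorded-run table {path} is missing columns {missing}; "
            f"detected headers: {list(df.columns)}"
        )
    df = df.astype({"topic_id": str, "target_id": str, "candidate_id": str})
    topics: list[Topic] = []
    runs: dict[str, dict[str, RunRanking]] = {m: {} for m in S1_MEASURES}
    for topic_id, group in df.groupby("topic_id", sort=True):
        targets = group["target_id"].unique()
        if len(targets) != 1:
            raise SchemaError(
                f"topic {topic_id!r} has conflicting target ids {list(targets)}"
            )
        relevant = frozenset(
            group.loc[group["highly_related"] == 1, "candidate_id"]
        )
        if not relevant:
            logger.warning(
                "topic %r has no highly related candidate; excluded", topic_id
            )
            continue
        topics.append(
            Topic(
                topic_id=str(topic_id),
                target_id=str(targets[0]),
                candidate_ids=tuple(group["candidate_id"]),
                highly_related_ids=relevant,
            )
        )
        for measure in S1_MEASURES:
            scores = dict(zip(group["candidate_id"], group[measure].astype(float)))
            runs[measure][str(topic_id)] = ranking_from_scores(
                str(topic_id), str(targets[0]), scores, measure
            )
    qrels = Qrels(topics=topics)
    qrels.validate()
    return qrels, runs
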