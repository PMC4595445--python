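import itertools
import logging

import numpy as np
import pytest
from scipy import stats as scipy_stats

from oracles import brute_average_precision
from pbcoupling.errors import SchemaError, ValidationError
from pbcoupling.evaluation import (
    S1_MEASURES,
    average_p_at_x,
    average_precision,
    evaluate_runs,
    load_s1_run,
    mean_average_precision,
    paired_t_test,
    pairs_hit_fraction,
    precision_at_x,
)
from pbcoupling.corpus import Qrels, Topic
from pbcoupling.similarity import ranking_from_scores


class TestAveragePrecision:
    def test_hand_worked_values(self):
        assert average_precision(["r", "x", "y"], {"r"}) == 1.0
        # relevants at ranks 1 and 3: (1/1 + 2/3) / 2
        assert average_precision(["r1", "x", "r2"], {"r1", "r2"}) == pytest.approx(
            (1 + 2 / 3) / 2
        )
        assert average_precision(["x", "y", "z", "r"], {"r"}) == 0.25

    def test_empty_relevant_set_rejected(self):
        with pytest.raises(ValidationError):
            average_precision(["x"], set())

    def test_unranked_relevants_appended_ascending(self):
        # r2 and r1 are missing; they are appended as r1 then r2
        ap = average_precision(["x", "y"], {"r2", "r1"})
        assert ap == pytest.approx((1 / 3 + 2 / 4) / 2)

    def test_depends_only_on_relevant_positions(self):
        base = average_precision(["x", "r1", "y", "r2", "z"], {"r1", "r2"})
        permuted = average_precision(["z", "r1", "x", "r2", "y"], {"r1", "r2"})
        assert base == permuted

    def test_perfect_iff_relevants_on_top(self):
        assert average_precision(["r1", "r2", "x"], {"r1", "r2"}) == 1.0
        assert average_precision(["r1", "x", "r2"], {"r1", "r2"}) < 1.0

    def test_moving_a_relevant_up_never_decreases_ap(self):
        ids = ["a", "b", "c", "d", "e"]
        relevant = {"c"}
        for pos in range(4, 0, -1):
            lower = ids.copy()
            higher = ids.copy()
            lower.remove("c"), higher.remove("c")
            lower.insert(pos, "c")
            higher.insert(pos - 1, "c")
            assert average_precision(higher, relevant) >= average_precision(
                lower, relevant
            )

    def test_exhaustive_agreement_with_literal_formula(self):
        # every relevance pattern on rankings of length 1..8
        for n in range(1, 9):
            for pattern in itertools.product((0, 1), repeat=n):
                if not any(pattern):
                    continue
                ids = [f"c{i}" for i in range(n)]
                relevant = {f"c{i}" for i, bit in enumerate(pattern) if bit}
                assert average_precision(ids, relevant) == pytest.approx(
                    brute_average_precision(ids, relevant)
                )

    def test_pessimistic_ties_charges_tied_competitors(self):
        ids = ["r", "x", "y"]
        scores = {"r": 0.5, "x": 0.5, "y": 0.1}
        optimistic = average_precision(ids, {"r"})
        pessimistic = average_precision(ids, {"r"}, pessimistic_ties=True, scores=scores)
        assert optimistic == 1.0
        assert pessimistic == pytest.approx(0.5)


class TestAggregates:
    def test_map_examples(self):
        assert mean_average_precision({"t1": 1.0, "t2": 0.5}) == 0.75
        assert mean_average_precision([1.0, 1.0]) == 1.0
        assert mean_average_precision([0.37]) == 0.37
        with pytest.raises(ValidationError):
            mean_average_precision([])

    def test_precision_at_x(self):
        assert precision_at_x(["r1", "x", "r2"], {"r1", "r2"}, 3) == pytest.approx(2 / 3)
        assert precision_at_x(["r1", "x"], {"r1"}, 1) == 1.0
        assert precision_at_x(["x", "y", "z"], {"r"}, 3) == 0.0
        with pytest.raises(ValidationError):
            precision_at_x(["x"], {"x"}, 0)

    def test_average_p_at_x_and_pairs_hit(self):
        per_topic = {"t1": 0.5, "t2": 0.0, "t3": 0.0, "t4": 1.0}
        assert average_p_at_x(per_topic) == pytest.approx(0.375)
        assert pairs_hit_fraction(per_topic) == 0.5
        assert pairs_hit_fraction([1.0, 0.2]) == 1.0
        assert pairs_hit_fraction([0.0, 0.0]) == 0.0
        with pytest.raises(ValidationError):
            pairs_hit_fraction([])


class TestPairedTTest:
    def test_identical_vectors_no_difference(self):
        result = paired_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert result.p_value == 1.0
        assert not result.significant
        assert not result.degenerate

    def test_constant_difference_is_degenerate(self):
        result = paired_t_test([0.1, 0.2, 0.3, 0.4], [0.2, 0.3, 0.4, 0.5])
        assert result.degenerate
        assert result.p_value == 0.0
        assert result.significant

    def test_matches_independent_computation(self):
        rng = np.random.default_rng(12)
        a = rng.random(10)
        b = a + rng.normal(0.1, 0.05, size=10)
        result = paired_t_test(list(a), list(b))
        # textbook paired t on the differences, via the one-sample test
        expected = scipy_stats.ttest_1samp(a - b, 0.0)
        assert result.p_value == pytest.approx(expected.pvalue)
        assert result.t_statistic == pytest.approx(expected.statistic)

    def test_two_sidedness_under_swap(self):
        rng = np.random.default_rng(13)
        a = list(rng.random(8))
        b = list(rng.random(8))
        assert paired_t_test(a, b).p_value == pytest.approx(paired_t_test(b, a).p_value)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            paired_t_test([1.0], [1.0])
        with pytest.raises(ValidationError):
            paired_t_test([1.0, 2.0], [1.0])


def small_qrels():
    return Qrels(
        topics=[
            Topic("t1", "tgtA", ("c1", "c2", "c3"), frozenset({"c1"})),
            Topic("t2", "tgtB", ("c4", "c5", "c6"), frozenset({"c5", "c6"})),
        ]
    )


def runs_for(scores_by_topic, name):
    qrels = small_qrels()
    return {
        t.topic_id: ranking_from_scores(
            t.topic_id, t.target_id, scores_by_topic[t.topic_id], name
        )
        for t in qrels
    }


def test_evaluate_runs_end_to_end():
    qrels = small_qrels()
    good = runs_for(
        {"t1": {"c1": 0.9, "c2": 0.5, "c3": 0.1}, "t2": {"c4": 0.1, "c5": 0.9, "c6": 0.8}},
        "good",
    )
    bad = runs_for(
        {"t1": {"c1": 0.1, "c2": 0.5, "c3": 0.9}, "t2": {"c4": 0.9, "c5": 0.1, "c6": 0.2}},
        "bad",
    )
    report = evaluate_runs({"good": good, "bad": bad}, qrels, x_values=(1, 3))
    assert report.map_value["good"] == 1.0
    assert report.map_value["bad"] < report.map_value["good"]
    assert report.p_at_x["good"][1] == 1.0
    assert report.pairs_hit["good"][1] == 1.0
    assert report.map_value["good"] == pytest.approx(
        np.mean(list(report.per_topic_ap["good"].values()))
    )
    assert "good vs bad [AP]" in report.significance or "bad vs good [AP]" in report.significance
    frame = report.summary_frame()
    assert "MAP" in frame.columns and set(frame.index) == {"good", "bad"}


def test_evaluate_runs_requires_full_coverage():
    qrels = small_qrels()
    partial = {
        "t1": ranking_from_scores("t1", "tgtA", {"c1": 1.0, "c2": 0.5, "c3": 0.2}, "m")
    }
    with pytest.raises(ValidationError, match="t2"):
        evaluate_runs({"m": partial}, qrels)


def s1_table_lines(include_all_columns=True, empty_topic=False):
    measures = list(S1_MEASURES if include_all_columns else S1_MEASURES[:-1])
    header = ["topic_id", "target_id", "candidate_id", "highly_related"] + measures
    rows = [header]
    rng = np.random.default_rng(2)
    topics = ["t1", "t2"] + (["t3"] if empty_topic else [])
    for topic in topics:
        for i in range(4):
            label = 1 if (i == 0 and topic != "t3") else 0
            row = [topic, f"tgt_{topic}", f"{topic}c{i}", str(label)]
            row += [f"{rng.random():.4f}" for _ in measures]
            rows.append(row)
    return "\n".join("\t".join(r) for r in rows) + "\n"


class TestS1Loader:
    def test_synthetic_table_gives_eight_runs(self, tmp_path):
        path = tmp_path / "s1.tsv"
        path.write_text(s1_table_lines())
        qrels, runs = load_s1_run(path)
        assert len(qrels) == 2
        assert set(runs) == set(S1_MEASURES)
        for measure in S1_MEASURES:
            assert set(runs[measure]) == {"t1", "t2"}
            for ranking in runs[measure].values():
                scores = [s for _, s in ranking.entries]
                assert scores == sorted(scores, reverse=True)

    def test_missing_measure_column_is_schema_error(self, tmp_path):
        path = tmp_path / "s1.tsv"
        path.write_text(s1_table_lines(include_all_columns=False))
        with pytest.raises(SchemaError, match="HybridK50-WholeArticle"):
            load_s1_run(path)

    def test_topic_without_relevants_excluded_with_warning(self, tmp_path, caplog):
        path = tmp_path / "s1.tsv"
        path.write_text(s1_table_lines(empty_topic=True))
        with caplog.at_level(logging.WARNING):
            qrels, runs = load_s1_run(path)
        assert len(qrels) == 2
        assert "t3" in caplog.text
        assert all("t3" not in per_topic for per_topic in runs.values())
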