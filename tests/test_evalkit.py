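"""Confusion-count accounting, severity filtering, and metric rounding."""

import pytest

from phenotext.evalkit import (
    ErrorRecord,
    EvalCounts,
    compare_hpo_sets,
    compare_phi_spans,
    compute_metrics,
    filter_counts_by_severity,
    mean_per_report,
)
from phenotext.hposum import PhenotypeHit


def hit(tid, confidence):
    reason = "affirmed" if confidence == "high" else "negated"
    return PhenotypeHit(
        term_id=tid, label=tid, confidence=confidence, reason=reason,
        evidence_sentence=0, matched_text="x", quantitative=None, count=1, first_offset=0,
    )


class TestComputeMetrics:
    def test_deid_benchmark_counts(self):
        m = compute_metrics(EvalCounts(tp=443, fp=133, fn=6))
        assert m.recall_pct == 99
        assert m.precision_pct == 77

    def test_low_confidence_precision(self):
        m = compute_metrics(EvalCounts(tp=125, fp=130, fn=0))
        assert m.precision_pct == 49

    def test_degenerate_counts_undefined(self):
        m = compute_metrics(EvalCounts(0, 0, 0))
        assert not m.defined
        assert m.recall_pct is None and m.precision_pct is None and m.f1 is None

    def test_perfect_counts(self):
        m = compute_metrics(EvalCounts(tp=7, fp=0, fn=0))
        assert m.recall_pct == 100 and m.precision_pct == 100 and m.f1 == 1.0

    def test_f1_from_unrounded_fractions(self):
        # P = 0.5, R = 0.25 -> F1 = 1/3 -> 0.33
        m = compute_metrics(EvalCounts(tp=1, fp=1, fn=3))
        assert m.f1 == 0.33

    def test_half_up_rounding(self):
        # 0.625 -> 63% under half-up (banker's rounding would give 62)
        m = compute_metrics(EvalCounts(tp=5, fp=3, fn=3))
        assert m.recall_pct == 63 and m.precision_pct == 63

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EvalCounts(tp=-1)


class TestSeverityFilter:
    def test_minor_exclusion_reproduces_benchmark(self):
        errors = (
            [ErrorRecord("deid_fp", "major")] * 9
            + [ErrorRecord("deid_fp", "moderate")] * 55
            + [ErrorRecord("deid_fp", "minor")] * 69
        )
        c = filter_counts_by_severity(errors, EvalCounts(tp=443, fp=133, fn=6), {"major", "moderate"})
        assert c == EvalCounts(tp=443, fp=64, fn=6)
        assert compute_metrics(c).precision_pct == 87

    def test_keep_all_identity(self):
        errors = [ErrorRecord("deid_fp", "minor")] * 3
        c = EvalCounts(tp=10, fp=3, fn=1)
        assert filter_counts_by_severity(errors, c, {"major", "moderate", "minor"}) == c

    def test_keep_nothing_zeroes_fp_only(self):
        errors = [ErrorRecord("deid_fp", "minor")] * 3
        c = filter_counts_by_severity(errors, EvalCounts(tp=10, fp=3, fn=1), set())
        assert c == EvalCounts(tp=10, fp=0, fn=1)

    def test_record_count_mismatch(self):
        with pytest.raises(ValueError):
            filter_counts_by_severity([], EvalCounts(tp=1, fp=2, fn=0), {"major"})

    def test_fp_monotone_under_shrinking_keep_set(self):
        errors = (
            [ErrorRecord("deid_fp", "major")] * 2
            + [ErrorRecord("deid_fp", "moderate")] * 3
            + [ErrorRecord("deid_fp", "minor")] * 4
        )
        c = EvalCounts(tp=5, fp=9, fn=1)
        fps = [
            filter_counts_by_severity(errors, c, keep).fp
            for keep in ({"major", "moderate", "minor"}, {"major", "moderate"}, {"major"}, set())
        ]
        assert fps == sorted(fps, reverse=True)


class TestMeanPerReport:
    @pytest.mark.parametrize("total,n,expected", [(332, 50, 6.6), (0, 50, 0.0), (7, 2, 3.5), (1, 3, 0.3)])
    def test_examples(self, total, n, expected):
        assert mean_per_report(total, n) == expected

    def test_zero_reports_rejected(self):
        with pytest.raises(ValueError):
            mean_per_report(1, 0)


class TestCompareHpoSets:
    def test_high_only_vs_all(self):
        predicted = [hit("HP:0000001", "high"), hit("HP:0000002", "low")]
        gold = {"HP:0000001", "HP:0000002"}
        assert compare_hpo_sets(predicted, gold, "high_only") == EvalCounts(tp=1, fp=0, fn=1)
        assert compare_hpo_sets(predicted, gold, "all") == EvalCounts(tp=2, fp=0, fn=0)

    def test_disjoint(self):
        c = compare_hpo_sets([hit("HP:0000003", "high")], {"HP:0000001"})
        assert c == EvalCounts(tp=0, fp=1, fn=1)

    def test_conservation(self):
        predicted = [hit(f"HP:000000{i}", "high") for i in range(1, 5)]
        gold = {"HP:0000001", "HP:0000002", "HP:0000009"}
        c = compare_hpo_sets(predicted, gold, "all")
        assert c.tp + c.fn == len(gold)
        assert c.tp + c.fp == 4


class TestComparePhiSpans:
    def test_exact_match(self):
        assert compare_phi_spans([(0, 5)], [((0, 5), "PERSON")]) == EvalCounts(tp=1, fp=0, fn=0)

    def test_partial_overlap_counts_detected(self):
        assert compare_phi_spans([(2, 4)], [((0, 5), "PERSON")]) == EvalCounts(tp=1, fp=0, fn=0)

    def test_disjoint(self):
        assert compare_phi_spans([(10, 12)], [((0, 5), "DATE_TIME")]) == EvalCounts(tp=0, fp=1, fn=1)

    def test_overlapping_predictions_rejected(self):
        with pytest.raises(ValueError):
            compare_phi_spans([(0, 5), (3, 8)], [])
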