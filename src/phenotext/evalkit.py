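"""TP/FP/FN accounting and metrics for de-identification and summarization.

The conventions: a missed PHI redaction is a false negative, an excess
redaction of non-PHI text a false positive; for summarization an excess
HPO term is a false positive and a missed one a false negative.  PHI
detection credit needs ≥1 character of overlap with a gold span (category
ignored — what matters is whether the leak was covered); severity grading
handles partial redactions separately.  Percentages round half-up to
integers, F1 is computed from the unrounded fractions and rounded to two
decimals — the arithmetic that reproduces every printed benchmark figure
from its confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence, Set, Tuple

__all__ = [
    "EvalCounts",
    "MetricsResult",
    "ErrorRecord",
    "compute_metrics",
    "filter_counts_by_severity",
    "mean_per_report",
    "compare_hpo_sets",
    "compare_phi_spans",
]

Span = Tuple[int, int]


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricsResult:
    recall_pct: Optional[int]
    precision_pct: Optional[int]
    f1: Optional[float]
    defined: bool


@dataclass(frozen=True)
class ErrorRecord:
    kind: str  # deid_fn | deid_fp | hpo_fp | hpo_fn
    severity: str  # major | moderate | minor
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deid_fn", "deid_fp", "hpo_fp", "hpo_fn"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.severity not in ("major", "moderate", "minor"):
            raise ValueError(f"bad severity {self.severity!r}")


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_metrics(c: EvalCounts, rounding: str = "half_up_integer_pct") -> MetricsResult:
    """Recall/precision as half-up integer percents; F1 (2 dp) from the
    unrounded fractions.  Degenerate denominators give ``defined=False``.
    """
    if rounding != "half_up_integer_pct":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    if c.tp + c.fn == 0 or c.tp + c.fp == 0:
        return MetricsResult(None, None, None, defined=False)
    recall = c.tp / (c.tp + c.fn)
    precision = c.tp / (c.tp + c.fp)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsResult(
        recall_pct=int(_round_half_up(recall * 100, 0)),
        precision_pct=int(_round_half_up(precision * 100, 0)),
        f1=_round_half_up(f1, 2),
        defined=True,
    )


def filter_counts_by_severity(
    errors: Sequence[ErrorRecord], c: EvalCounts, keep: Iterable[str]
) -> EvalCounts:
    """Drop FP credit for excluded-severity false positives.

    There must be exactly one ``deid_fp`` record per counted FP; tp and fn
    are never changed (severity only regrades the *excess* redactions).
    """
    keep_set = set(keep)
    fp_records = [e for e in errors if e.kind == "deid_fp"]
    if len(fp_records) != c.fp:
        raise ValueError(
            f"fp record count {len(fp_records)} does not match counts.fp {c.fp}"
        )
    kept_fp = sum(1 for e in fp_records if e.severity in keep_set)
    return EvalCounts(tp=c.tp, fp=kept_fp, fn=c.fn)


def mean_per_report(total: int, n_reports: int) -> float:
    """Mean items per report, rounded half-up to one decimal."""
    if n_reports <= 0:
        raise ValueError("n_reports must be positive")
    if total < 0:
        raise ValueError("total must be non-negative")
    return _round_half_up(total / n_reports, 1)


def compare_hpo_sets(
    predicted: Sequence, gold: Set[str], mode: str = "all"
) -> EvalCounts:
    """Exact term-id comparison of predicted hits against a gold id set.

    ``mode="high_only"`` restricts predictions to high-confidence hits;
    no ontology-distance credit is given.
    """
    if mode not in ("high_only", "all"):
        raise ValueError(f"bad mode {mode!r}")
    ids = {
        h.term_id
        for h in predicted
        if mode == "all" or h.confidence == "high"
    }
    return EvalCounts(
        tp=len(ids & gold), fp=len(ids - gold), fn=len(gold - ids)
    )


def _check_nonoverlapping(spans: Sequence[Span], label: str) -> None:
    prev_end = None
    for s, e in sorted(spans):
        if prev_end is not None and s < prev_end:
            raise ValueError(f"{label} spans overlap at offset {s}")
        prev_end = e


def compare_phi_spans(
    predicted: Sequence, gold: Sequence[Tuple[Span, str]]
) -> EvalCounts:
    """Span-overlap PHI scoring: a gold span is detected (TP) when any
    predicted span overlaps it by ≥1 character, category ignored."""
    pred_spans = [p.span if hasattr(p, "span") else tuple(p) for p in predicted]
    gold_spans = [tuple(g[0]) for g in gold]
    _check_nonoverlapping(pred_spans, "predicted")
    _check_nonoverlapping(gold_spans, "gold")

    def overlaps(a: Span, b: Span) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    tp = sum(1 for g in gold_spans if any(overlaps(g, p) for p in pred_spans))
    fn = len(gold_spans) - tp
    fp = sum(1 for p in pred_spans if not any(overlaps(p, g) for g in gold_spans))
    return EvalCounts(tp=tp, fp=fp, fn=fn)
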