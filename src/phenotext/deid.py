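"""Rule-based PHI detection, gazetteer overrides, and redaction.

Three detector channels mirror the de-identification audit categories:
dates/times, persons, and locations.  The hybrid override logic then runs:
allowlists (medical eponyms, drugs, gene symbols) veto detector output so
clinical content survives, while the geographic denylist *forces*
redaction and is never vetoed — a direct allow/deny conflict resolves to
redaction (privacy first) and is logged.

Offsets are 0-based half-open throughout; placeholders are the five fixed
tokens ``<PERSON> <DATE_TIME> <LOCATION> <ID> <OTHER>``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from ._text import fold, fold_with_offsets
from .lexicons import Gazetteer, Polarity

logger = logging.getLogger(__name__)

__all__ = [
    "RedactionSpan",
    "PhiSeverity",
    "detect_dates",
    "detect_persons",
    "detect_locations",
    "apply_allowlist",
    "merge_spans",
    "redact",
    "CATEGORY_PRIORITY",
]

Span = Tuple[int, int]

CATEGORIES = ("PERSON", "DATE_TIME", "LOCATION", "ID", "OTHER")
#: Tie-break priority when overlapping spans start at the same offset.
CATEGORY_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

SEVERITY_LEVELS = ("major", "moderate", "minor")


@dataclass(frozen=True)
class PhiSeverity:
    """Severity grade of a de-identification error.

    major: directly identifying leak, or a diagnosis redacted in excess;
    moderate: indirect identifier leak (e.g. a location), or a clinical
    term redacted; minor: non-clinical filler redacted.
    """

    level: str

    def __post_init__(self) -> None:
        if self.level not in SEVERITY_LEVELS:
            raise ValueError(f"unknown severity {self.level!r}")


@dataclass(frozen=True)
class RedactionSpan:
    """One detected PHI interval."""

    span: Span
    category: str
    surface: str
    source: str = "detector"  # "detector" | "denylist"

    def __post_init__(self) -> None:
        s, e = self.span
        if e <= s:
            raise ValueError(f"empty span {self.span}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.source not in ("detector", "denylist"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def placeholder(self) -> str:
        return f"<{self.category}>"

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def _mk(text: str, start: int, end: int, category: str, source: str = "detector") -> RedactionSpan:
    return RedactionSpan(
        span=(start, end), category=category, surface=text[start:end], source=source
    )


MONTHS_EN = (
    "january february march april may june july august september october "
    "november december".split()
)
MONTHS_FR = (
    "janvier fevrier mars avril mai juin juillet aout septembre octobre "
    "novembre decembre".split()
)

_NUMERIC_DATE_RE = re.compile(
    r"\b(\d{4}-\d{2}-\d{2}|\d{1,2}[/.]\d{1,2}[/.]\d{2,4}|\d{1,2}-\d{1,2}-\d{2,4})\b"
)
#: Cue words licensing a bare 4-digit year as a date.
_YEAR_CUES = ("born", "in", "since", "until", "ne", "nee", "depuis", "en")


def detect_dates(
    text: str, extra_month_names: Optional[Iterable[str]] = None
) -> List[RedactionSpan]:
    """Detect numeric dates, month-name dates, and cue-adjacent bare years.

    Month names are matched in English plus the source language's list
    (French by default, extensible via *extra_month_names*); a standalone
    4-digit year needs a cue word ("born", "in", ...) immediately before
    it, so "trisomy 2023" stays untouched.
    """
    months = set(MONTHS_EN) | set(MONTHS_FR) | set(
        fold(m) for m in (extra_month_names or ())
    )
    spans: List[RedactionSpan] = []
    for m in _NUMERIC_DATE_RE.finditer(text):
        spans.append(_mk(text, m.start(1), m.end(1), "DATE_TIME"))

    folded, offsets = fold_with_offsets(text)
    month_alt = "(?:" + "|".join(sorted(months, key=len, reverse=True)) + ")"
    # "12 march 2023" | "march 12, 2023" | "march 2023" — a bare month name
    # is never a date ("may" is a modal verb)
    month_re = re.compile(
        r"\b(?:\d{1,2}(?:st|nd|rd|th)?\s+" + month_alt + r"(?:\s+\d{4})?"
        r"|" + month_alt + r"\s+\d{1,2}(?:,\s*\d{4})?"
        r"|" + month_alt + r"\s+\d{4})\b"
    )
    for m in month_re.finditer(folded):
        start, end = _map_back(offsets, m.start(), m.end(), len(text))
        spans.append(_mk(text, start, end, "DATE_TIME"))

    year_re = re.compile(
        r"\b(?:" + "|".join(_YEAR_CUES) + r")\s+((?:19|20)\d{2})\b"
    )
    for m in year_re.finditer(folded):
        start, end = _map_back(offsets, m.start(1), m.end(1), len(text))
        spans.append(_mk(text, start, end, "DATE_TIME"))
    return merge_spans(spans)


def _map_back(offsets: Sequence[int], fstart: int, fend: int, text_len: int) -> Span:
    start = offsets[fstart]
    end = offsets[fend - 1] + 1 if fend - 1 < len(offsets) else text_len
    return start, end


#: Default person-trigger tokens (titles and maiden-name markers).
DEFAULT_PERSON_TRIGGERS = (
    "Mr", "Mrs", "Ms", "Miss", "Dr", "Pr", "Prof", "M", "Mme", "Mlle",
    "née", "né", "born",
)

_CAP_NAME = r"[A-ZÀ-Þ][\w'\-]*"


def detect_persons(
    text: str,
    triggers: Sequence[str] = DEFAULT_PERSON_TRIGGERS,
    name_gazetteer: Optional[Gazetteer] = None,
) -> List[RedactionSpan]:
    """Detect person names: capitalized sequences after a trigger token,
    plus any occurrence of a gazetteer name.

    This recognizer is deliberately pluggable — an external NER can replace
    it behind the same ``(text, triggers, name_gazetteer) -> spans``
    signature.
    """
    spans: List[RedactionSpan] = []
    trig_alt = "|".join(re.escape(t) for t in sorted(triggers, key=len, reverse=True))
    trig_re = re.compile(
        r"(?<!\w)(?:" + trig_alt + r")\.?\s+(" + _CAP_NAME + r"(?:\s+" + _CAP_NAME + r")*)"
    )
    for m in trig_re.finditer(text):
        spans.append(_mk(text, m.start(1), m.end(1), "PERSON"))

    if name_gazetteer is not None and len(name_gazetteer):
        folded, offsets = fold_with_offsets(text)
        for phrase in sorted(name_gazetteer.phrases):
            for m in re.finditer(r"\b" + re.escape(phrase) + r"\b", folded):
                start, end = _map_back(offsets, m.start(), m.end(), len(text))
                spans.append(_mk(text, start, end, "PERSON"))
    return merge_spans(spans)


def detect_locations(text: str, denylist: Gazetteer) -> List[RedactionSpan]:
    """Force-redact every whole-word occurrence of a denylist phrase."""
    if denylist.polarity is not Polarity.DENY:
        raise ValueError("detect_locations requires a deny-polarity gazetteer")
    spans: List[RedactionSpan] = []
    folded, offsets = fold_with_offsets(text)
    for phrase in sorted(denylist.phrases):
        for m in re.finditer(r"\b" + re.escape(phrase) + r"\b", folded):
            start, end = _map_back(offsets, m.start(), m.end(), len(text))
            spans.append(_mk(text, start, end, "LOCATION", source="denylist"))
    return merge_spans(spans)


def apply_allowlist(
    spans: Sequence[RedactionSpan],
    allowlists: Sequence[Gazetteer],
    text: str,
) -> List[RedactionSpan]:
    """Veto detector spans covered by an allowlist; never touch denylist spans.

    A span is removed when its normalized surface is an allowlisted phrase,
    or when it lies wholly inside an occurrence of an allowlisted
    multi-word phrase ("Iso" inside "Iso Kikuchi").  Removals are logged
    with the matching category; an allow/deny conflict keeps the redaction
    and is logged too.
    """
    allow = [g for g in allowlists if g.polarity is Polarity.ALLOW]
    folded, offsets = fold_with_offsets(text)
    multiword_hits: List[Tuple[Span, Gazetteer]] = []
    for g in allow:
        for phrase in g.phrases:
            if " " not in phrase:
                continue
            for m in re.finditer(r"\b" + re.escape(phrase) + r"\b", folded):
                multiword_hits.append((_map_back(offsets, m.start(), m.end(), len(text)), g))

    kept: List[RedactionSpan] = []
    for span in spans:
        veto_category = None
        for g in allow:
            if fold(span.surface) in g.phrases:
                veto_category = g.category.value
                break
        if veto_category is None:
            for (hs, he), g in multiword_hits:
                if hs <= span.start and span.end <= he:
                    veto_category = g.category.value
                    break
        if veto_category is not None:
            if span.source == "denylist":
                logger.info(
                    "allow/deny conflict on %r: keeping redaction (privacy-first)",
                    span.surface,
                )
                kept.append(span)
            else:
                logger.info(
                    "allowlist (%s) vetoed %s span %r", veto_category, span.category, span.surface
                )
            continue
        kept.append(span)
    return kept


def merge_spans(spans: Sequence[RedactionSpan]) -> List[RedactionSpan]:
    """Normalize a span collection to sorted, non-overlapping spans.

    Same-category overlapping or exactly-adjacent spans merge.  Across
    categories the earlier-starting span wins; ties break by priority
    PERSON > DATE_TIME > LOCATION > ID > OTHER.  A denylist source is
    sticky under merge.
    """
    if not spans:
        return []
    ordered = sorted(spans, key=lambda r: (r.start, CATEGORY_PRIORITY[r.category], r.end))

    # first pass: merge same-category overlap/adjacency
    by_cat: Dict[str, List[RedactionSpan]] = {}
    for sp in ordered:
        lst = by_cat.setdefault(sp.category, [])
        if lst and sp.start <= lst[-1].end:
            prev = lst[-1]
            new_span = (prev.start, max(prev.end, sp.end))
            source = "denylist" if "denylist" in (prev.source, sp.source) else "detector"
            lst[-1] = RedactionSpan(
                span=new_span,
                category=sp.category,
                surface=_merge_surface(prev, sp),
                source=source,
            )
        else:
            lst.append(sp)

    merged = sorted(
        (sp for lst in by_cat.values() for sp in lst),
        key=lambda r: (r.start, CATEGORY_PRIORITY[r.category]),
    )
    # second pass: drop later-starting spans that overlap a kept span
    result: List[RedactionSpan] = []
    for sp in merged:
        if result and sp.start < result[-1].end:
            continue
        result.append(sp)
    return result


def _merge_surface(a: RedactionSpan, b: RedactionSpan) -> str:
    """Surface of the union span, reconstructed from the two overlapping pieces."""
    start = a.start
    end = max(a.end, b.end)
    if b.end <= a.end:
        return a.surface
    return a.surface + b.surface[a.end - b.start :] if b.start <= a.end else a.surface


def redact(
    text: str, spans: Sequence[RedactionSpan]
) -> Tuple[str, List[Dict[str, object]]]:
    """Replace each span by its placeholder; text outside spans is untouched.

    Returns the de-identified text and an audit report of
    ``{category, start, end, surface, placeholder, source}`` rows.
    Overlapping input spans violate the contract and raise ``ValueError``.
    """
    prev_end = 0
    for sp in spans:
        if sp.start < prev_end:
            raise ValueError(f"overlapping spans at offset {sp.start}")
        if sp.end > len(text):
            raise ValueError(f"span {sp.span} out of bounds")
        if text[sp.start : sp.end] != sp.surface:
            raise ValueError(f"span surface mismatch at {sp.span}")
        prev_end = sp.end

    out: List[str] = []
    report: List[Dict[str, object]] = []
    pos = 0
    for sp in spans:
        out.append(text[pos : sp.start])
        out.append(sp.placeholder)
        report.append(
            {
                "category": sp.category,
                "start": sp.start,
                "end": sp.end,
                "surface": sp.surface,
                "placeholder": sp.placeholder,
                "source": sp.source,
            }
        )
        pos = sp.end
    out.append(text[pos:])
    return "".join(out), report
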