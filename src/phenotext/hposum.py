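"""Sentence-level HPO concept recognition with confidence flags.

A term matches a sentence when the lemmatized token set of one of its
labels (name or synonym) is a subset of the sentence's lemmatized tokens —
the ClinPhen matching semantics.  Each matched sentence is then flagged:
a family-member cue puts the match in family context, otherwise a negation
cue marks it negated, otherwise it is affirmed.  Per document and term one
:class:`PhenotypeHit` is emitted: *high* confidence if the term is
affirmed anywhere, else *low* with the reason of its earliest occurrence.
Negated terms are reported (low confidence), not dropped — the consumer
decides; nearby measurements ("-2.5 SD", "48 cm") are captured as
quantitative evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from ._text import fold
from .ontology import SynonymIndex
from .preprocess import Document, Sentence

__all__ = [
    "PhenotypeHit",
    "CueLists",
    "DEFAULT_CUES",
    "match_sentence",
    "detect_negation",
    "detect_family",
    "extract_quantitative",
    "summarize_document",
]


@dataclass(frozen=True)
class CueLists:
    """Normalized negation and family-context cues (tokens or phrases)."""

    negation_cues: FrozenSet[str]
    family_cues: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.negation_cues or not self.family_cues:
            raise ValueError("cue sets must be non-empty")
        if self.negation_cues & self.family_cues:
            raise ValueError("negation and family cues must be disjoint")


DEFAULT_CUES = CueLists(
    negation_cues=frozenset(
        {
            "no", "not", "without", "never", "denies", "denied",
            "absence of", "absent", "neither", "nor", "ruled out",
            "negative for", "free of",
        }
    ),
    family_cues=frozenset(
        {
            "mother", "father", "brother", "sister", "aunt", "uncle",
            "grandmother", "grandfather", "cousin", "nephew", "niece",
            "parents", "sibling", "siblings", "maternal", "paternal",
            "family history", "familial history",
        }
    ),
)


@dataclass(frozen=True)
class PhenotypeHit:
    """One extracted HPO term for a document."""

    term_id: str
    label: str
    confidence: str  # "high" | "low"
    reason: str  # "affirmed" | "negated" | "family"
    evidence_sentence: int
    matched_text: str
    quantitative: Optional[str]
    count: int
    first_offset: int

    def __post_init__(self) -> None:
        if self.confidence not in ("high", "low"):
            raise ValueError(f"bad confidence {self.confidence!r}")
        if self.reason not in ("affirmed", "negated", "family"):
            raise ValueError(f"bad reason {self.reason!r}")
        if (self.reason == "affirmed") != (self.confidence == "high"):
            raise ValueError("affirmed ⟺ high confidence violated")
        if self.count < 1:
            raise ValueError("count must be ≥ 1")


def match_sentence(
    sentence: Sentence, index: SynonymIndex, text: Optional[str] = None
) -> List[Tuple[str, str, str, int]]:
    """All terms whose indexed token set is a subset of the sentence lemmas.

    Returns ``(term_id, matched label, matched_text, match_offset)`` tuples,
    one per term (the first matching label wins).  ``matched_text`` is the
    minimal sentence substring covering one occurrence of each matched
    lemma; *text* is the document text the sentence spans refer to (falls
    back to joining token surfaces when absent).
    """
    lemma_set = sentence.lemma_set(index.stopwords)
    if not lemma_set:
        return []
    hits: List[Tuple[str, str, str, int]] = []
    seen: Set[str] = set()
    for key, members in index.entries.items():
        if key <= lemma_set:
            for term_id, label in sorted(members):
                if term_id in seen:
                    continue
                seen.add(term_id)
                span = _minimal_window(sentence, key)
                matched_text = (
                    text[span[0] : span[1]]
                    if text is not None
                    else " ".join(
                        s for s, (a, b) in sentence.tokens if a >= span[0] and b <= span[1]
                    )
                )
                hits.append((term_id, label, matched_text, span[0]))
    hits.sort(key=lambda h: (h[3], h[0]))
    return hits


def _minimal_window(sentence: Sentence, key: FrozenSet[str]) -> Tuple[int, int]:
    """Smallest token window containing every lemma of *key* at least once."""
    positions = [
        (i, lemma) for i, lemma in enumerate(sentence.lemmas) if lemma in key
    ]
    need = len(key)
    best: Optional[Tuple[int, int]] = None  # token index range (inclusive)
    counts: Dict[str, int] = {}
    covered = 0
    left = 0
    for right, (ri, rlem) in enumerate(positions):
        counts[rlem] = counts.get(rlem, 0) + 1
        if counts[rlem] == 1:
            covered += 1
        while covered == need:
            li, llem = positions[left]
            if best is None or ri - li < best[1] - best[0]:
                best = (li, ri)
            counts[llem] -= 1
            if counts[llem] == 0:
                covered -= 1
            left += 1
    assert best is not None, "caller guarantees key ⊆ sentence lemmas"
    start = sentence.tokens[best[0]][1][0]
    end = sentence.tokens[best[1]][1][1]
    return start, end


def _contains_cue(sentence_text: str, lemma_set: FrozenSet[str], cues: FrozenSet[str]) -> bool:
    folded = fold(sentence_text)
    for cue in cues:
        if " " in cue:
            if re.search(r"\b" + re.escape(cue) + r"\b", folded):
                return True
        elif cue in lemma_set or re.search(r"\b" + re.escape(cue) + r"\b", folded):
            return True
    return False


def detect_negation(sentence: Sentence, cues: CueLists, text: str = "") -> bool:
    """Whole-sentence negation scope: any negation cue present."""
    sent_text = text[sentence.span[0] : sentence.span[1]] if text else " ".join(
        s for s, _ in sentence.tokens
    )
    return _contains_cue(sent_text, frozenset(sentence.lemmas), cues.negation_cues)


def detect_family(sentence: Sentence, cues: CueLists, text: str = "") -> bool:
    """Whole-sentence family-member scope: any family cue present."""
    sent_text = text[sentence.span[0] : sentence.span[1]] if text else " ".join(
        s for s, _ in sentence.tokens
    )
    return _contains_cue(sent_text, frozenset(sentence.lemmas), cues.family_cues)


#: number + unit, standard-deviation notation, or percentile expression
_MEASUREMENT_RE = re.compile(
    r"([+-]?\d+(?:[.,]\d+)?\s*(?:SD|DS|cm|mm|kg|g|m|%|centile[s]?|percentile[s]?)"
    r"|\d+(?:st|nd|rd|th)?\s+(?:centile|percentile)"
    r"|[+-]\d+(?:[.,]\d+)?)",
    re.IGNORECASE,
)


def extract_quantitative(
    sentence: Sentence, matched_span: Tuple[int, int], text: str
) -> Optional[str]:
    """Nearest measurement expression in the sentence, or ``None``.

    Distance is in tokens between the measurement and the matched text;
    ties break on character gap, then toward the earlier measurement.
    """
    s, e = sentence.span
    sent_text = text[s:e]
    candidates = [(m.start() + s, m.end() + s, m.group(0)) for m in _MEASUREMENT_RE.finditer(sent_text)]
    # drop measurements inside the matched phrase itself
    candidates = [
        c for c in candidates if not (c[0] >= matched_span[0] and c[1] <= matched_span[1])
    ]
    if not candidates:
        return None

    def distance(c: Tuple[int, int, str]) -> Tuple[int, int]:
        cs, ce, _ = c
        between = [
            1
            for _, (ts, te) in sentence.tokens
            if (ts >= matched_span[1] and te <= cs) or (ts >= ce and te <= matched_span[0])
        ]
        char_gap = cs - matched_span[1] if cs >= matched_span[1] else matched_span[0] - ce
        return len(between), max(char_gap, 0)

    best = min(candidates, key=lambda c: (*distance(c), c[0]))
    return best[2].strip()


def summarize_document(
    doc: Document,
    index: SynonymIndex,
    cues: CueLists = DEFAULT_CUES,
) -> List[PhenotypeHit]:
    """Extract one flagged :class:`PhenotypeHit` per term for a document.

    Per sentence: match terms, then classify the sentence — family cue →
    ``family``, else negation cue → ``negated``, else ``affirmed``.  Per
    term across sentences: any affirmed occurrence makes the hit high
    confidence; otherwise the earliest occurrence's reason is kept, family
    outranking negated on a same-sentence tie.  Output is sorted by first
    match offset.
    """
    # occurrences[term] = list of (sentence idx, reason, matched_text, span, label)
    occurrences: Dict[str, List[Tuple[int, str, str, Tuple[int, int], str]]] = {}
    for si, sentence in enumerate(doc.sentences):
        matches = match_sentence(sentence, index, doc.text)
        if not matches:
            continue
        if detect_family(sentence, cues, doc.text):
            reason = "family"
        elif detect_negation(sentence, cues, doc.text):
            reason = "negated"
        else:
            reason = "affirmed"
        for term_id, label, matched_text, offset in matches:
            span = (offset, offset + len(matched_text))
            occurrences.setdefault(term_id, []).append(
                (si, reason, matched_text, span, label)
            )

    reason_rank = {"family": 0, "negated": 1}  # family outranks negated on ties
    hits: List[PhenotypeHit] = []
    for term_id, occs in occurrences.items():
        affirmed = [o for o in occs if o[1] == "affirmed"]
        if affirmed:
            rep = affirmed[0]
            confidence, reason = "high", "affirmed"
        else:
            rep = min(occs, key=lambda o: (o[0], reason_rank[o[1]]))
            confidence, reason = "low", rep[1]
        si, _, matched_text, span, _ = rep
        quantitative = extract_quantitative(doc.sentences[si], span, doc.text)
        hits.append(
            PhenotypeHit(
                term_id=term_id,
                label=index.labels.get(term_id, term_id),
                confidence=confidence,
                reason=reason,
                evidence_sentence=si,
                matched_text=matched_text,
                quantitative=quantitative,
                count=len({o[0] for o in occs}),
                first_offset=min(o[3][0] for o in occs),
            )
        )
    hits.sort(key=lambda h: (h.first_offset, h.term_id))
    return hits
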