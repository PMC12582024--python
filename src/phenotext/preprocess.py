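"""Sentence segmentation, tokenization, and abbreviation expansion.

A :class:`Document` carries character-span sentence and token structure
through every pipeline stage (raw → expanded → translated →
deidentified), so downstream flags (negation, family context) and audit
reports can always point back into the exact text they were computed on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from ._text import Lemmatizer, normalize_token, tokenize

__all__ = [
    "Document",
    "Sentence",
    "segment_sentences",
    "expand_abbreviations",
    "apply_edits",
    "shift_spans",
    "make_document",
]

Span = Tuple[int, int]

#: Tokens whose trailing period never ends a sentence (titles etc.);
#: dictionary abbreviations are added per call.
DEFAULT_NONBREAKING = frozenset({"Mr", "Mrs", "Ms", "Dr", "Pr", "Prof", "M", "Mme", "Mlle", "St", "etc", "e.g", "i.e", "cf", "vs"})

#: The five redaction placeholder bodies; when they appear angle-bracketed
#: in de-identified text their tokens are never lemma-matched.
PLACEHOLDER_BODIES = frozenset({"PERSON", "DATE_TIME", "LOCATION", "ID", "OTHER"})


@dataclass(frozen=True)
class Sentence:
    """One sentence: its span in the document plus aligned tokens/lemmas."""

    span: Span
    tokens: Tuple[Tuple[str, Span], ...]  # (surface, absolute char span)
    lemmas: Tuple[str, ...]  # normalized token per surface token ("" if folded away)

    def lemma_set(self, stopwords: Sequence[str] = ()) -> frozenset:
        stop = frozenset(stopwords)
        return frozenset(l for l in self.lemmas if l and l not in stop)


@dataclass(frozen=True)
class Document:
    doc_id: str
    language: str
    text: str
    sentences: Tuple[Sentence, ...] = ()
    stage: str = "raw"

    def sentence_text(self, i: int) -> str:
        s, e = self.sentences[i].span
        return self.text[s:e]


def segment_sentences(
    text: str, known_abbreviations: Optional[Sequence[str]] = None
) -> List[Span]:
    """Split *text* into sentence spans (0-based, half-open, trimmed).

    Terminators are ".", "!", "?" and the newline.  A period does not split
    when it sits between digits (numeric dates "12.03.2019") or when the
    preceding token is a known abbreviation or title.
    """
    nonbreaking = set(DEFAULT_NONBREAKING)
    if known_abbreviations:
        nonbreaking.update(a.rstrip(".") for a in known_abbreviations)

    boundaries: List[int] = []
    n = len(text)
    for i, ch in enumerate(text):
        if ch == "\n":
            boundaries.append(i + 1)
            continue
        if ch in ".!?":
            if ch == ".":
                prev = text[i - 1] if i > 0 else ""
                nxt = text[i + 1] if i + 1 < n else ""
                if prev.isdigit() and nxt.isdigit():
                    continue  # internal date/decimal period
                m = re.search(r"([\w.]+)$", text[:i], re.UNICODE)
                if m and m.group(1).rstrip(".") in nonbreaking:
                    continue
                if nxt in ".!?":
                    continue  # ellipsis; break at the last terminator
            boundaries.append(i + 1)

    spans: List[Span] = []
    start = 0
    for b in boundaries + [n]:
        chunk = text[start:b]
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((start + lstrip, b - rstrip))
        start = b
    return spans


def expand_abbreviations(text: str, d) -> Tuple[str, List[Tuple[Span, str]]]:
    """Replace whole-token dictionary keys by their expansions (single pass).

    Matching is case-sensitive on the stored key form; at a given position
    the longest key wins.  Returns the expanded text and an edit map of
    ``((start, end) in the original text, replacement string)`` entries;
    applying the edits to the original reproduces the output exactly.
    """
    if not d.entries:
        return text, []
    keys = sorted(d.entries, key=len, reverse=True)
    pattern = re.compile(
        r"(?<!\w)(" + "|".join(re.escape(k) for k in keys) + r")(?!\w)"
    )
    edits: List[Tuple[Span, str]] = []
    out: List[str] = []
    pos = 0
    for m in pattern.finditer(text):
        out.append(text[pos : m.start()])
        out.append(d.entries[m.group(1)])
        edits.append(((m.start(), m.end()), d.entries[m.group(1)]))
        pos = m.end()
    out.append(text[pos:])
    return "".join(out), edits


def apply_edits(text: str, edits: Sequence[Tuple[Span, str]]) -> str:
    """Apply an edit map (original-text coordinates) — the round-trip check."""
    out: List[str] = []
    pos = 0
    for (start, end), repl in sorted(edits):
        out.append(text[pos:start])
        out.append(repl)
        pos = end
    out.append(text[pos:])
    return "".join(out)


def shift_spans(
    spans: Sequence[Span], edits: Sequence[Tuple[Span, str]]
) -> List[Span]:
    """Remap spans from pre-edit to post-edit coordinates.

    Spans must not overlap any edit site (planted annotations never do).
    """
    shifted: List[Span] = []
    for s, e in spans:
        delta = 0
        for (a, b), repl in edits:
            if b <= s:
                delta += len(repl) - (b - a)
            elif a < e:
                raise ValueError(f"span ({s},{e}) overlaps edit site ({a},{b})")
        shifted.append((s + delta, e + delta))
    return shifted


def _build_sentence(
    text: str, span: Span, lemmatizer: Optional[Lemmatizer] = None
) -> Sentence:
    toks = []
    lemmas = []
    for surface, (ts, te) in tokenize(text[span[0] : span[1]]):
        abs_span = (span[0] + ts, span[0] + te)
        toks.append((surface, abs_span))
        # angle-bracketed placeholders are opaque: never lemma-matched
        if (
            surface in PLACEHOLDER_BODIES
            and abs_span[0] > 0
            and text[abs_span[0] - 1] == "<"
            and abs_span[1] < len(text)
            and text[abs_span[1]] == ">"
        ):
            lemmas.append("")
        else:
            lemmas.append(normalize_token(surface, lemmatizer))
    return Sentence(span=span, tokens=tuple(toks), lemmas=tuple(lemmas))


def make_document(
    doc_id: str,
    text: str,
    language: str = "en",
    stage: str = "raw",
    known_abbreviations: Optional[Sequence[str]] = None,
    lemmatizer: Optional[Lemmatizer] = None,
) -> Document:
    """Segment and tokenize *text* into a stage-tagged :class:`Document`."""
    spans = segment_sentences(text, known_abbreviations)
    sentences = tuple(_build_sentence(text, sp, lemmatizer) for sp in spans)
    return Document(
        doc_id=doc_id, language=language, text=text, sentences=sentences, stage=stage
    )
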