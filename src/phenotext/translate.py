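"""Translation-engine contract with deterministic offline engines.

Real neural machine translation is an optional adapter configured by name
(engine, model path, language pair) and is never required: the pipeline's
contract is only that an engine maps each source sentence to one English
sentence, deterministically.  Two engines ship here — a passthrough and a
whole-token glossary substitutor — which is enough to exercise every
downstream stage offline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Dict, List

from .preprocess import Document, make_document

__all__ = [
    "TranslationEngine",
    "TranslationError",
    "make_passthrough_engine",
    "make_glossary_engine",
    "translate_document",
]


class TranslationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TranslationEngine:
    """A named, deterministic sentence → English-sentence function."""

    name: str
    source_language: str
    translate_sentence: Callable[[str], str]


def make_passthrough_engine(source_language: str = "en") -> TranslationEngine:
    """Identity engine (already-English input, or testing)."""
    return TranslationEngine(
        name="passthrough",
        source_language=source_language,
        translate_sentence=lambda s: s,
    )


def make_glossary_engine(
    glossary: Dict[str, str], source_language: str = "fr"
) -> TranslationEngine:
    """Whole-token glossary substitution; non-key tokens pass verbatim.

    Deterministic by construction; an empty glossary behaves as a
    passthrough.
    """
    if not glossary:
        return TranslationEngine(
            name="glossary", source_language=source_language, translate_sentence=lambda s: s
        )
    keys = sorted(glossary, key=len, reverse=True)
    pattern = re.compile(r"(?<!\w)(" + "|".join(re.escape(k) for k in keys) + r")(?!\w)")

    def _translate(sentence: str) -> str:
        return pattern.sub(lambda m: glossary[m.group(1)], sentence)

    return TranslationEngine(
        name="glossary", source_language=source_language, translate_sentence=_translate
    )


def translate_document(doc: Document, engine: TranslationEngine) -> Document:
    """Translate an expanded document sentence-by-sentence into English.

    Sentence count and paragraph breaks (the text between sentence spans)
    are preserved; the result is re-tokenized at stage ``translated`` with
    ``language="en"``.
    """
    if doc.language != engine.source_language:
        raise TranslationError(
            f"document language {doc.language!r} does not match engine "
            f"source language {engine.source_language!r}"
        )
    pieces: List[str] = []
    pos = 0
    for i, sent in enumerate(doc.sentences):
        s, e = sent.span
        pieces.append(doc.text[pos:s])  # inter-sentence gap / paragraph break
        source = doc.text[s:e]
        try:
            translated = engine.translate_sentence(source)
        except Exception as exc:
            raise TranslationError(f"engine {engine.name} failed on sentence {i}") from exc
        if source and not translated:
            raise TranslationError(
                f"engine {engine.name} returned empty output for sentence {i}"
            )
        pieces.append(translated)
        pos = e
    pieces.append(doc.text[pos:])
    new_text = "".join(pieces)
    out = make_document(
        doc.doc_id, new_text, language="en", stage="translated"
    )
    if len(out.sentences) != len(doc.sentences):
        # engines must not merge/split sentences; re-segmentation disagreement
        # indicates an engine emitting extra terminators
        raise TranslationError(
            f"sentence count changed after translation "
            f"({len(doc.sentences)} -> {len(out.sentences)})"
        )
    return out
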