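"""Shared text normalization: accent folding, tokenization, lemmatization.

The normalizer is deliberately deterministic and dependency-free so that
ontology indexing and sentence matching use byte-identical rules.  A
different lemmatizer (e.g. a spaCy pipeline) can be plugged in anywhere a
``lemmatizer`` argument is accepted, as long as the same callable is used
for both the index and the sentences.
"""

from __future__ import annotations

import re
import unicodedata
from typing import Callable, FrozenSet, Iterable, List, Optional, Tuple

Lemmatizer = Callable[[str], str]

#: Small fixed English stopword list: articles, prepositions, copulas and
#: auxiliaries that carry no phenotype content.  "no"/"not"/"without" are
#: deliberately absent — negation cues must survive normalization.
STOPWORDS: FrozenSet[str] = frozenset(
    {
        "a", "an", "the",
        "of", "in", "on", "at", "to", "by", "for", "from", "with",
        "and", "or",
        "is", "are", "was", "were", "be", "been", "being",
        "has", "have", "had",
        "this", "that", "these", "those", "it", "its",
    }
)

#: Irregular plurals and domain words the suffix rules would mangle.
LEMMA_EXCEPTIONS = {
    "feet": "foot",
    "teeth": "tooth",
    "men": "man",
    "women": "woman",
    "children": "child",
    "mice": "mouse",
    "calves": "calf",
    "reflexes": "reflex",
    "ataxias": "ataxia",
    "iris": "iris",
    "pes": "pes",
    "facies": "facies",
    "diabetes": "diabetes",
    "scoliosis": "scoliosis",
    "ptosis": "ptosis",
    "analyses": "analysis",
}

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


def fold(text: str) -> str:
    """Lowercase and strip accents/diacritics (NFKD, combining marks removed)."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c)).lower()


def fold_with_offsets(text: str) -> Tuple[str, List[int]]:
    """Fold *text* and return (folded, offsets) where ``offsets[i]`` is the
    index in the original string of the character that produced ``folded[i]``.

    Needed to map regex matches on folded text back to original spans
    (folding can change string length, e.g. "œ" → "oe").
    """
    out: List[str] = []
    offsets: List[int] = []
    for i, ch in enumerate(text):
        folded = fold(ch)
        for fc in folded:
            out.append(fc)
            offsets.append(i)
        if not folded:  # character folded away entirely (bare combining mark)
            continue
    return "".join(out), offsets


def default_lemmatizer(token: str) -> str:
    """Deterministic rule+table lemmatizer for English clinical vocabulary.

    Handles regular plural inflection and a table of irregulars; anything
    else passes through unchanged.  Input is assumed lowercased/folded.
    """
    if token in LEMMA_EXCEPTIONS:
        return LEMMA_EXCEPTIONS[token]
    n = len(token)
    if n > 3 and token.endswith("ies"):
        return token[:-3] + "y"
    if n > 3 and token.endswith("es") and token[:-2].endswith(("s", "x", "z", "ch", "sh")):
        return token[:-2]
    if n > 3 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def tokenize(text: str) -> List[Tuple[str, Tuple[int, int]]]:
    """Word tokens with 0-based half-open character spans."""
    return [(m.group(0), (m.start(), m.end())) for m in _TOKEN_RE.finditer(text)]


def normalize_token(token: str, lemmatizer: Optional[Lemmatizer] = None) -> str:
    lem = lemmatizer or default_lemmatizer
    folded = fold(token)
    folded = re.sub(r"[^\w]", "", folded, flags=re.UNICODE)
    if not folded:
        return ""
    return lem(folded)


def normalize_phrase(
    text: str,
    stopwords: Iterable[str] = STOPWORDS,
    lemmatizer: Optional[Lemmatizer] = None,
) -> FrozenSet[str]:
    """Normalize a phrase to its matching key: a frozenset of lemmas.

    Tokens are lowercased, accent-folded, punctuation-stripped, lemmatized,
    and stopwords removed; duplicates collapse.  Empty input yields the
    empty set.
    """
    stop = frozenset(stopwords)
    out = set()
    for surface, _ in tokenize(text):
        norm = normalize_token(surface, lemmatizer)
        if norm and norm not in stop:
            out.add(norm)
    return frozenset(out)
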