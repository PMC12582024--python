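"""Curated dictionaries: abbreviation expansions, allowlists, denylists.

Three kinds of lexicon steer the pipeline:

* an abbreviation dictionary (per source language) expanded before
  translation;
* *allowlists* of medical proper names, drugs and gene symbols that veto
  de-identification (disease eponyms like "Noonan" must survive);
* a *denylist* of geographic names whose redaction is forced regardless of
  what the detectors think.

All gazetteer matching is exact on the normalized (lowercase,
accent-folded) phrase — no substring or fuzzy credit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, Set

import pandas as pd

from ._text import fold

logger = logging.getLogger(__name__)

__all__ = [
    "AbbreviationDictionary",
    "Gazetteer",
    "GazetteerCategory",
    "Polarity",
    "LexiconSchemaError",
    "DuplicateKeyError",
    "load_tsv_lexicon",
    "gazetteer_contains",
]


class GazetteerCategory(str, Enum):
    MEDICAL_NAME = "medical_name"
    DRUG = "drug"
    GENE = "gene"
    LOCATION = "location"


class Polarity(str, Enum):
    ALLOW = "allow"  # veto redaction
    DENY = "deny"  # force redaction


#: Locations are always deny-polarity; clinical vocabularies always allow.
CATEGORY_POLARITY = {
    GazetteerCategory.MEDICAL_NAME: Polarity.ALLOW,
    GazetteerCategory.DRUG: Polarity.ALLOW,
    GazetteerCategory.GENE: Polarity.ALLOW,
    GazetteerCategory.LOCATION: Polarity.DENY,
}


class LexiconSchemaError(ValueError):
    """A required TSV column is missing; message names the column."""


class DuplicateKeyError(ValueError):
    """An abbreviation key appears more than once."""


@dataclass
class AbbreviationDictionary:
    language: str = "en"
    entries: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for abbrev, expansion in self.entries.items():
            if not expansion:
                raise ValueError(f"abbreviation {abbrev!r} has an empty expansion")
            if abbrev == expansion:
                raise ValueError(f"abbreviation {abbrev!r} equals its expansion")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Gazetteer:
    category: GazetteerCategory
    phrases: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        self.category = GazetteerCategory(self.category)
        self.phrases = frozenset(fold(p) for p in self.phrases if p.strip())

    @property
    def polarity(self) -> Polarity:
        return CATEGORY_POLARITY[self.category]

    def __len__(self) -> int:
        return len(self.phrases)

    def __contains__(self, phrase: str) -> bool:
        return gazetteer_contains(self, phrase)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise LexiconSchemaError(f"{path}: missing required column {col!r}")


def load_tsv_lexicon(path: str, kind: str, language: str = "en"):
    """Load a TSV lexicon.

    ``kind="abbrev"`` expects columns (abbreviation, expansion) and returns
    an :class:`AbbreviationDictionary`; duplicate keys are an error.
    ``kind="gazetteer"`` expects columns (phrase, category) and returns a
    dict mapping :class:`GazetteerCategory` to :class:`Gazetteer`;
    duplicate phrases within a category are silently de-duplicated.

    An empty file (header only) is a valid empty lexicon.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise LexiconSchemaError(f"{path}: no header row") from exc
    if df.empty:
        logger.warning("lexicon %s is empty", path)
    if kind == "abbrev":
        _require_columns(df, ("abbreviation", "expansion"), path)
        entries: Dict[str, str] = {}
        for _, row in df.iterrows():
            key = row["abbreviation"]
            if key in entries:
                raise DuplicateKeyError(f"{path}: duplicate abbreviation {key!r}")
            entries[key] = row["expansion"]
        return AbbreviationDictionary(language=language, entries=entries)
    if kind == "gazetteer":
        _require_columns(df, ("phrase", "category"), path)
        by_cat: Dict[GazetteerCategory, Set[str]] = {}
        for _, row in df.iterrows():
            cat = GazetteerCategory(row["category"])
            by_cat.setdefault(cat, set()).add(row["phrase"])
        return {cat: Gazetteer(category=cat, phrases=frozenset(p)) for cat, p in by_cat.items()}
    raise ValueError(f"unknown lexicon kind: {kind!r}")


def gazetteer_contains(g: Gazetteer, phrase: str) -> bool:
    """Exact membership of the normalized phrase (case/accent-insensitive)."""
    return fold(phrase) in g.phrases
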