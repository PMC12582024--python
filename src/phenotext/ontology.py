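"""Phenotype ontology loading and the normalized synonym index.

Terms come from an OBO file (the ``HP:NNNNNNN`` namespace of the Human
Phenotype Ontology, or any fixture ontology with the same structure).
Concept recognition downstream is sentence-level subset matching in the
ClinPhen style: a term matches a sentence when the lemmatized token set of
one of its labels is a subset of the sentence's lemmatized tokens.  The
:class:`SynonymIndex` holds those label token sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import obonet

from ._text import STOPWORDS, Lemmatizer, normalize_phrase

logger = logging.getLogger(__name__)

HP_ID_RE = re.compile(r"^HP:\d{7}$")

__all__ = [
    "OntologyTerm",
    "SynonymIndex",
    "OboParseError",
    "EmptyOntologyError",
    "load_ontology",
    "build_synonym_index",
    "normalize_phrase",
]


class OboParseError(ValueError):
    """Raised when an OBO stanza is malformed; message names the line."""


class EmptyOntologyError(ValueError):
    """Raised when an OBO file contains no [Term] stanzas."""


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term: a CURIE id, primary name, synonyms, parents."""

    id: str
    name: str
    synonyms: Tuple[str, ...] = ()
    parents: Tuple[str, ...] = ()
    obsolete: bool = False
    replaced_by: Optional[str] = None

    def __post_init__(self) -> None:
        if not HP_ID_RE.match(self.id):
            raise ValueError(f"term id {self.id!r} does not match HP:NNNNNNN")
        if not self.name:
            raise ValueError(f"term {self.id} has an empty name")

    @property
    def labels(self) -> Tuple[str, ...]:
        """Primary name plus all synonyms."""
        return (self.name,) + self.synonyms


@dataclass
class SynonymIndex:
    """Normalized lookup structure over term labels.

    ``entries`` maps a frozen lemma set (the key) to the set of
    ``(term id, source label)`` pairs whose label normalizes to that key.
    ``term_token_sets`` keeps, per term, every key contributed by its name
    and synonyms — used by brute-force checks and matched-text recovery.
    """

    entries: Dict[FrozenSet[str], Set[Tuple[str, str]]] = field(default_factory=dict)
    term_token_sets: Dict[str, List[FrozenSet[str]]] = field(default_factory=dict)
    stopwords: FrozenSet[str] = STOPWORDS
    labels: Dict[str, str] = field(default_factory=dict)  # term id -> primary name

    def __len__(self) -> int:
        return len(self.entries)


_SYNONYM_QUOTE_RE = re.compile(r'^"(.*)"')


def _dequote_synonym(raw: str) -> str:
    """OBO synonym values look like '"small head" EXACT []'; keep the quoted text."""
    m = _SYNONYM_QUOTE_RE.match(raw.strip())
    return m.group(1) if m else raw.strip()


def _validate_obo_lines(path: str) -> None:
    """Light structural pre-scan so parse errors can name the offending line."""
    in_term = False
    have_id = False
    stanza_line = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("["):
                if in_term and not have_id:
                    raise OboParseError(
                        f"[Term] stanza at line {stanza_line} has no id line"
                    )
                in_term = stripped == "[Term]"
                have_id = False
                stanza_line = lineno
                continue
            if in_term and stripped.startswith("id:"):
                have_id = True
            if in_term and stripped and ":" not in stripped:
                raise OboParseError(f"malformed tag-value line {lineno}: {stripped!r}")
    if in_term and not have_id:
        raise OboParseError(f"[Term] stanza at line {stanza_line} has no id line")


def load_ontology(path: str, fmt: str = "obo") -> List[OntologyTerm]:
    """Load all HP-namespace [Term] stanzas from an OBO file.

    Obsolete terms are kept (with ``obsolete=True``) so callers can resolve
    ``replaced_by`` pointers; they are excluded from indexing later.

    Raises ``OboParseError`` for malformed stanzas (naming the line),
    ``EmptyOntologyError`` when no term is present, and ``OSError`` for an
    unreadable file.
    """
    if fmt != "obo":
        raise ValueError(f"unsupported ontology format: {fmt!r}")
    _validate_obo_lines(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except OSError:
        raise
    except Exception as exc:  # obonet raises assorted ValueErrors
        raise OboParseError(f"failed to parse OBO file {path}: {exc}") from exc

    terms: List[OntologyTerm] = []
    for node, data in graph.nodes(data=True):
        if not HP_ID_RE.match(str(node)):
            continue
        name = data.get("name", "")
        if not name:
            continue
        synonyms = tuple(_dequote_synonym(s) for s in data.get("synonym", []))
        parents = tuple(p for p in data.get("is_a", []) if HP_ID_RE.match(p))
        obsolete = data.get("is_obsolete", "false") in ("true", True)
        replaced = data.get("replaced_by", [None])
        replaced_by = replaced[0] if isinstance(replaced, list) else replaced
        terms.append(
            OntologyTerm(
                id=str(node),
                name=name,
                synonyms=synonyms,
                parents=parents,
                obsolete=obsolete,
                replaced_by=replaced_by,
            )
        )
    if not terms:
        raise EmptyOntologyError(f"no [Term] stanzas found in {path}")
    return sorted(terms, key=lambda t: t.id)


def build_synonym_index(
    terms: Iterable[OntologyTerm],
    stopwords: Iterable[str] = STOPWORDS,
    lemmatizer: Optional[Lemmatizer] = None,
) -> SynonymIndex:
    """Index every non-obsolete term's name and synonyms by normalized key.

    Two labels normalizing to the same key keep all their term ids under
    that key.  Labels that normalize to the empty set are skipped with a
    logged warning (e.g. punctuation-only synonyms).
    """
    stop = frozenset(stopwords)
    index = SynonymIndex(stopwords=stop)
    n_indexable = 0
    for term in terms:
        if term.obsolete:
            continue
        n_indexable += 1
        index.labels[term.id] = term.name
        token_sets: List[FrozenSet[str]] = []
        for label in term.labels:
            key = normalize_phrase(label, stop, lemmatizer)
            if not key:
                logger.warning(
                    "label %r of term %s normalizes to the empty set; skipped",
                    label,
                    term.id,
                )
                continue
            token_sets.append(key)
            index.entries.setdefault(key, set()).add((term.id, label))
        index.term_token_sets[term.id] = token_sets
    if n_indexable == 0:
        raise EmptyOntologyError("no non-obsolete terms to index")
    return index
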