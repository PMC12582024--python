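"""Pipeline orchestration: expand → translate → de-identify → summarize.

The four stages run in order per report; summarization runs on the
de-identified text so exported evidence snippets are shareable
(placeholders are angle-bracketed uppercase and are never lemma-matched).
Outputs per report: de-identified text, CSV term list, PhenoTips-style
JSON, and a TSV span report for audit.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .deid import (
    RedactionSpan,
    apply_allowlist,
    detect_dates,
    detect_locations,
    detect_persons,
    merge_spans,
    redact,
)
from .hposum import DEFAULT_CUES, CueLists, PhenotypeHit, summarize_document
from .lexicons import AbbreviationDictionary, Gazetteer
from .ontology import SynonymIndex, build_synonym_index, load_ontology
from .preprocess import expand_abbreviations, make_document
from .translate import TranslationEngine, make_passthrough_engine, translate_document

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineResources",
    "PipelineResult",
    "process_text",
    "run_pipeline",
    "write_csv",
    "write_phenotips_json",
    "write_span_report",
    "CSV_HEADER",
]

CSV_HEADER = [
    "report_id", "hpo_id", "hpo_label", "confidence", "reason",
    "count", "evidence_sentence", "matched_text", "quantitative",
]

DEFAULT_EMIT = frozenset({"deid_text", "csv", "phenotips_json", "span_report"})


@dataclass
class PipelineResources:
    """Everything one run needs, loaded once and shared across reports."""

    index: SynonymIndex
    abbreviations: Optional[AbbreviationDictionary] = None
    allowlists: Sequence[Gazetteer] = ()
    denylist: Optional[Gazetteer] = None
    name_gazetteer: Optional[Gazetteer] = None
    engine: Optional[TranslationEngine] = None
    cues: CueLists = DEFAULT_CUES
    language: str = "en"

    @classmethod
    def from_paths(
        cls,
        ontology_path: str,
        abbreviations: Optional[AbbreviationDictionary] = None,
        allowlists: Sequence[Gazetteer] = (),
        denylist: Optional[Gazetteer] = None,
        name_gazetteer: Optional[Gazetteer] = None,
        engine: Optional[TranslationEngine] = None,
        language: str = "en",
    ) -> "PipelineResources":
        terms = load_ontology(ontology_path)
        return cls(
            index=build_synonym_index(terms),
            abbreviations=abbreviations,
            allowlists=allowlists,
            denylist=denylist,
            name_gazetteer=name_gazetteer,
            engine=engine,
            language=language,
        )


@dataclass
class PipelineResult:
    """Per-report pipeline output plus stage counters for the run log."""

    doc_id: str
    deid_text: str
    hits: List[PhenotypeHit]
    span_report: List[Dict[str, object]]
    n_abbreviations_expanded: int = 0
    spans_by_source: Dict[str, int] = field(default_factory=dict)
    hits_by_confidence: Dict[str, int] = field(default_factory=dict)


def _detect_all(text: str, res: PipelineResources) -> List[RedactionSpan]:
    spans: List[RedactionSpan] = []
    spans += detect_dates(text)
    spans += detect_persons(text, name_gazetteer=res.name_gazetteer)
    if res.denylist is not None:
        spans += detect_locations(text, res.denylist)
    spans = apply_allowlist(spans, res.allowlists, text)
    return merge_spans(spans)


def process_text(doc_id: str, text: str, res: PipelineResources) -> PipelineResult:
    """Run all four stages on one report text."""
    known_abbrev = list(res.abbreviations.entries) if res.abbreviations else None

    # (i) abbreviation expansion
    if res.abbreviations is not None:
        expanded_text, edits = expand_abbreviations(text, res.abbreviations)
    else:
        expanded_text, edits = text, []
    doc = make_document(
        doc_id, expanded_text, language=res.language, stage="expanded",
        known_abbreviations=known_abbrev,
    )

    # (ii) translation
    engine = res.engine or make_passthrough_engine(res.language)
    doc = translate_document(doc, engine)

    # (iii) de-identification
    spans = _detect_all(doc.text, res)
    deid_text, span_report = redact(doc.text, spans)
    deid_doc = make_document(
        doc_id, deid_text, language="en", stage="deidentified",
        known_abbreviations=known_abbrev,
    )

    # (iv) HPO summarization on the de-identified text
    hits = summarize_document(deid_doc, res.index, res.cues)

    by_source: Dict[str, int] = {}
    for row in span_report:
        by_source[str(row["source"])] = by_source.get(str(row["source"]), 0) + 1
    by_conf: Dict[str, int] = {}
    for h in hits:
        by_conf[h.confidence] = by_conf.get(h.confidence, 0) + 1
    logger.info(
        "%s: %d abbreviations expanded, %d spans redacted %s, %d hits %s",
        doc_id, len(edits), len(span_report), by_source, len(hits), by_conf,
    )
    return PipelineResult(
        doc_id=doc_id,
        deid_text=deid_text,
        hits=hits,
        span_report=span_report,
        n_abbreviations_expanded=len(edits),
        spans_by_source=by_source,
        hits_by_confidence=by_conf,
    )


def run_pipeline(
    input_paths: Sequence[str],
    res: PipelineResources,
    output_dir: str,
    emit: frozenset = DEFAULT_EMIT,
) -> Tuple[List[PipelineResult], int]:
    """Process report files and write the requested outputs.

    Returns (results, exit_code): 0 when every report succeeded, 1 on
    partial failure (failed reports are skipped with a logged reason).
    A usage error (no inputs) raises ``ValueError``.
    """
    if not input_paths:
        raise ValueError("no input reports given")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: List[PipelineResult] = []
    failures = 0
    for path in input_paths:
        doc_id = Path(path).stem
        try:
            text = Path(path).read_text(encoding="utf-8")
            result = process_text(doc_id, text, res)
        except Exception as exc:
            failures += 1
            logger.error("report %s skipped: %s", path, exc)
            continue
        results.append(result)
        if "deid_text" in emit:
            (out / f"{doc_id}.deid.txt").write_text(result.deid_text, encoding="utf-8")
        if "csv" in emit:
            write_csv(result.hits, out / f"{doc_id}.hpo.csv", report_id=doc_id)
        if "phenotips_json" in emit:
            write_phenotips_json(result.hits, out / f"{doc_id}.phenotips.json")
        if "span_report" in emit:
            write_span_report(result.span_report, out / f"{doc_id}.spans.tsv")
    return results, (1 if failures else 0)


def write_csv(hits: Sequence[PhenotypeHit], path, report_id: str = "") -> None:
    """RFC 4180 CSV, UTF-8, LF; one row per hit in hit order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for h in hits:
            writer.writerow(
                [
                    report_id, h.term_id, h.label, h.confidence, h.reason,
                    h.count, h.evidence_sentence, h.matched_text,
                    h.quantitative or "",
                ]
            )


def write_phenotips_json(hits: Sequence[PhenotypeHit], path) -> None:
    """PhenoTips-style features JSON.

    High-confidence hits are observed phenotypes; negated hits are
    explicitly not observed; family-context hits go to a lossless
    ``family_features`` sidecar (the richer qualifier semantics of real
    EHR schemas are deliberately not invented here).
    """
    features = []
    family_features = []
    for h in sorted(hits, key=lambda h: h.first_offset):
        element = {
            "id": h.term_id,
            "label": h.label,
            "type": "phenotype",
            "observed": "yes" if h.confidence == "high" else "no",
        }
        if h.reason == "family":
            element["observed"] = "yes"
            family_features.append(element)
        else:
            features.append(element)
    payload = {"features": features, "family_features": family_features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_span_report(rows: Sequence[Dict[str, object]], path) -> None:
    """TSV audit report of redactions: category, offsets, surface, source."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("category\tstart\tend\tsurface\tplaceholder\tsource\n")
        for row in rows:
            fh.write(
                f"{row['category']}\t{row['start']}\t{row['end']}\t"
                f"{row['surface']}\t{row['placeholder']}\t{row['source']}\n"
            )
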