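"""Synthetic clinical reports with machine-readable planted ground truth.

Every pipeline stage is testable offline: the generator plants PHI
(names, dates, locations), abbreviations, affirmed / negated /
family-context symptom phrases and measurements into templated reports,
and emits a gold record whose spans point into the generated text.  The
same name and location pools the generator samples from are exported as
detector gazetteers, so a correctly wired pipeline must reach 100% PHI
and HPO recall on its own corpora.

Template families deliberately include the hard cases seen in real
reports: the maiden name ("née X"), the bare city mention, the
family-symptom and negated-symptom sentence, and a descriptive-syndrome
sentence mentioning a symptom the patient does not have — the last is
recorded as a *probe*, an expected false positive, not as gold.

Default rates are the real-report medians the generator emulates:
15 PHI, 7 HPO phrases and 3 abbreviations per report, with the PHI mass
split ≈ 52% dates / 37% persons / 11% locations.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .lexicons import AbbreviationDictionary, Gazetteer, GazetteerCategory
from .ontology import OntologyTerm

__all__ = [
    "GeneratorConfig",
    "GoldRecord",
    "make_fixture_ontology",
    "generate_corpus",
    "build_name_gazetteer",
    "build_location_denylist",
    "build_medical_allowlist",
    "build_abbreviation_dictionary",
    "write_corpus",
    "GLOSSARY_FR_EN",
]

Span = Tuple[int, int]

# ---------------------------------------------------------------------------
# pools — also exported as gazetteers/lexicons

SURNAMES = (
    "Dupont", "Durand", "Lefebvre", "Moreau", "Fournier", "Girard",
    "Bonnet", "Lambert", "Rousseau", "Vincent", "Muller", "Faure",
    "Andre", "Mercier", "Blanc", "Guerin", "Chevalier", "Garnier",
    "Francois", "Legrand",
)

CITIES = (
    "Montpellier", "Nîmes", "Lyon", "Paris", "Toulouse", "Marseille",
    "Bordeaux", "Nantes", "Lille", "Strasbourg", "Grenoble", "Dijon",
    "Rennes", "Avignon", "Perpignan", "Béziers",
)

#: Disease eponyms and clinical proper names that must survive redaction.
MEDICAL_NAMES = (
    "Noonan", "Marfan", "Ehlers-Danlos", "Iso Kikuchi", "Kabuki",
    "Prader-Willi", "Angelman", "Rett", "Cornelia de Lange", "Coffin-Siris",
    "Silver-Russell", "Beckwith-Wiedemann", "Smith-Magenis", "Williams",
    "DiGeorge", "Pierre Robin", "Turner", "Klinefelter",
)

DRUGS = (
    "valproate", "levetiracetam", "carbamazepine", "lamotrigine",
    "topiramate", "risperidone", "melatonin", "baclofen", "omeprazole",
    "amoxicillin", "paracetamol", "ibuprofen", "vigabatrin", "clobazam",
)

GENES = (
    "SCN1A", "MECP2", "PTPN11", "FBN1", "NSD1", "ARID1B", "KMT2D",
    "CHD7", "TCF4", "STXBP1", "SHANK3", "DYRK1A", "ANKRD11", "KCNQ2",
)

ABBREVIATIONS = {
    "EEG": "electroencephalogram",
    "MRI": "magnetic resonance imaging",
    "OFC": "occipitofrontal circumference",
    "GA": "gestational age",
    "BW": "birth weight",
    "PT": "physiotherapy",
    "ENT": "ear nose and throat",
    "GI": "gastrointestinal",
    "CT": "computed tomography",
    "IQ": "intelligence quotient",
}

#: Phenotype name pool for the fixture ontology: (name, synonyms).
#: Chosen so that no label's lemma set is a subset of another label's —
#: planting one term per sentence then yields exactly one match.
TERM_POOL: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("Seizure", ("Seizures", "Epileptic seizure")),
    ("Microcephaly", ("Small head",)),
    ("Macrocephaly", ("Large head",)),
    ("Hypotonia", ()),
    ("Scoliosis", ()),
    ("Short stature", ()),
    ("Hearing impairment", ("Deafness",)),
    ("Cleft palate", ()),
    ("Strabismus", ("Squint",)),
    ("Ptosis", ()),
    ("Nystagmus", ()),
    ("Global developmental delay", ()),
    ("Ataxia", ()),
    ("Spasticity", ()),
    ("Micrognathia", ("Small jaw",)),
    ("Atrial septal defect", ()),
    ("Ventricular septal defect", ()),
    ("Hepatomegaly", ("Enlarged liver",)),
    ("Splenomegaly", ()),
    ("Tall stature", ()),
    ("Obesity", ()),
    ("Failure to thrive", ()),
    ("Macroglossia", ("Large tongue",)),
    ("Pes planus", ("Flat feet",)),
    ("Hypertelorism", ("Widely spaced eyes",)),
    ("Epicanthus", ()),
    ("Brachydactyly", ("Short digits",)),
    ("Clinodactyly", ()),
    ("Syndactyly", ()),
    ("Polydactyly", ()),
    ("Intellectual disability", ()),
    ("Dysarthria", ()),
    ("Dysphagia", ()),
    ("Gastroesophageal reflux", ()),
    ("Constipation", ()),
    ("Feeding difficulties", ()),
    ("Joint hypermobility", ()),
    ("Delayed speech", ("Speech delay",)),
    ("Anemia", ()),
    ("Proteinuria", ()),
)

#: Glossary for the "fr-like" source language: French function words the
#: glossary engine maps token-wise to English, leaving phenotype and PHI
#: surfaces untouched.
GLOSSARY_FR_EN: Dict[str, str] = {
    "Le": "The", "le": "the", "La": "The", "la": "the",
    "patient": "patient", "patiente": "patient",
    "présente": "presents with", "montre": "shows",
    "Pas": "No", "pas": "no", "aucune": "no", "aucun": "no",
    "de": "of", "des": "of", "du": "of",
    "Sa": "His", "sa": "his", "Son": "His", "son": "his",
    "mère": "mother", "père": "father", "soeur": "sister", "frère": "brother",
    "observée": "observed", "observé": "observed",
    "examen": "examination", "clinique": "clinical",
    "était": "was", "est": "is", "normal": "normal", "normale": "normal",
}

MEASUREMENTS = ("-2.5 SD", "+2.1 SD", "-3 SD", "48 cm", "97th percentile", "3rd percentile")

DATE_FORMATS = (
    "{d:02d}/{m:02d}/{y}",
    "{d:02d}.{m:02d}.{y}",
    "{y}-{m:02d}-{d:02d}",
    "{d} {month} {y}",
)

MONTH_NAMES_EN = (
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
)


# ---------------------------------------------------------------------------
# lexicon exports

def build_name_gazetteer() -> Gazetteer:
    """The generator's surname pool as a PERSON-detector gazetteer."""
    return Gazetteer(category=GazetteerCategory.MEDICAL_NAME, phrases=frozenset(SURNAMES))


def build_location_denylist() -> Gazetteer:
    """The generator's city pool as the force-redaction denylist."""
    return Gazetteer(category=GazetteerCategory.LOCATION, phrases=frozenset(CITIES))


def build_medical_allowlist() -> List[Gazetteer]:
    """Allowlists: medical eponyms, drugs, gene symbols."""
    return [
        Gazetteer(category=GazetteerCategory.MEDICAL_NAME, phrases=frozenset(MEDICAL_NAMES)),
        Gazetteer(category=GazetteerCategory.DRUG, phrases=frozenset(DRUGS)),
        Gazetteer(category=GazetteerCategory.GENE, phrases=frozenset(GENES)),
    ]


def build_abbreviation_dictionary(language: str = "en") -> AbbreviationDictionary:
    return AbbreviationDictionary(language=language, entries=dict(ABBREVIATIONS))


# ---------------------------------------------------------------------------
# fixture ontology

def make_fixture_ontology(seed: int, n_terms: int) -> str:
    """Deterministic OBO text with *n_terms* HP-style terms.

    At least 30% of terms carry synonyms, is_a links form a tree rooted at
    the first term, and exactly one term (the last) is obsolete with a
    ``replaced_by`` pointer.
    """
    if n_terms < 5:
        raise ValueError("n_terms must be ≥ 5")
    if n_terms > len(TERM_POOL):
        raise ValueError(f"n_terms must be ≤ {len(TERM_POOL)}")
    rng = random.Random(seed)

    with_syn = [t for t in TERM_POOL if t[1]]
    without_syn = [t for t in TERM_POOL if not t[1]]
    rng.shuffle(with_syn)
    rng.shuffle(without_syn)
    n_syn = max(1, -(-n_terms * 2 // 5))  # ceil(0.4 n): comfortably ≥ 30%
    n_syn = min(n_syn, len(with_syn))
    chosen = with_syn[:n_syn] + without_syn[: n_terms - n_syn]
    if len(chosen) < n_terms:
        chosen += with_syn[n_syn : n_syn + n_terms - len(chosen)]
    rng.shuffle(chosen)

    lines = ["format-version: 1.2", "ontology: hp-fixture", ""]
    ids = [f"HP:{9000001 + i:07d}" for i in range(n_terms)]
    for i, (name, synonyms) in enumerate(chosen):
        lines.append("[Term]")
        lines.append(f"id: {ids[i]}")
        obsolete = i == n_terms - 1
        lines.append(f"name: {'obsolete ' + name if obsolete else name}")
        if not obsolete:
            for syn in synonyms:
                lines.append(f'synonym: "{syn}" EXACT []')
        if obsolete:
            lines.append("is_obsolete: true")
            lines.append(f"replaced_by: {ids[0]}")
        elif i > 0:
            parent = ids[rng.randrange(0, i)]
            lines.append(f"is_a: {parent}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# corpus generation

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    seed: int = 0
    n_reports: int = 50
    language: str = "en"  # "en" | "fr-like"
    n_sentences: Tuple[int, int] = (25, 30)
    phi_per_report: int = 15
    abbreviations_per_report: int = 3
    hpo_per_report: int = 7
    fraction_negated: float = 0.35
    fraction_family: float = 0.15
    fraction_measurement: float = 0.3

    def __post_init__(self) -> None:
        for frac in (self.fraction_negated, self.fraction_family, self.fraction_measurement):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_negated + self.fraction_family > 1.0:
            raise ValueError("negated + family fractions exceed 1")
        if min(self.phi_per_report, self.abbreviations_per_report, self.hpo_per_report) < 0:
            raise ValueError("per-report rates must be ≥ 0")
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        if self.language not in ("en", "fr-like"):
            raise ValueError(f"unknown language {self.language!r}")


@dataclass
class GoldRecord:
    """Planted ground truth for one generated report."""

    doc_id: str
    phi_spans: List[Tuple[Span, str]] = field(default_factory=list)
    hpo_terms: List[Tuple[str, str, str]] = field(default_factory=list)  # (id, confidence, reason)
    abbreviation_sites: List[Span] = field(default_factory=list)
    probe_term_ids: List[str] = field(default_factory=list)  # designed FPs, not gold


class _ReportBuilder:
    """Accumulates sentences while tracking absolute spans of marked pieces."""

    def __init__(self) -> None:
        self.parts: List[str] = []
        self.length = 0
        self.gold_phi: List[Tuple[Span, str]] = []
        self.gold_abbrev: List[Span] = []

    def add_sentence(self, pieces: Sequence[Tuple[str, Optional[str]]]) -> None:
        if self.length:
            self.parts.append(" ")
            self.length += 1
        for piece, tag in pieces:
            start = self.length
            self.parts.append(piece)
            self.length += len(piece)
            if tag is None:
                continue
            if tag.startswith("phi:"):
                self.gold_phi.append(((start, self.length), tag.split(":", 1)[1]))
            elif tag == "abbrev":
                self.gold_abbrev.append((start, self.length))

    def text(self) -> str:
        return "".join(self.parts)


def _date_pieces(rng: random.Random) -> str:
    y = rng.randint(2015, 2023)
    m = rng.randint(1, 12)
    d = rng.randint(1, 28)
    fmt = rng.choice(DATE_FORMATS)
    return fmt.format(d=d, m=m, y=y, month=MONTH_NAMES_EN[m - 1])


FILLER_SENTENCES = (
    "Clinical examination was otherwise unremarkable.",
    "Growth parameters were recorded during the visit.",
    "A follow-up appointment was scheduled.",
    "Laboratory results were reviewed during the consultation.",
    "The remainder of the assessment was completed.",
    "Vaccinations are up to date.",
)


def _reason_counts(cfg: GeneratorConfig, rng: random.Random) -> Tuple[int, int, int]:
    n = cfg.hpo_per_report
    n_neg = round(cfg.fraction_negated * n)
    n_fam = round(cfg.fraction_family * n)
    if n_neg + n_fam > n:
        n_fam = n - n_neg
    return n - n_neg - n_fam, n_neg, n_fam


def generate_corpus(
    cfg: GeneratorConfig,
    terms: Sequence[OntologyTerm],
    abbreviations: Optional[AbbreviationDictionary] = None,
) -> List[Tuple[str, GoldRecord]]:
    """Generate ``cfg.n_reports`` templated reports with gold records.

    PHI slots are filled from the exported name/location/date pools, HPO
    slots with term names or synonyms wrapped in affirmed / negated /
    family templates, abbreviations and measurements per rate.  Gold spans
    point into the returned text.  Identical config → identical corpus.
    """
    rng = random.Random(cfg.seed)
    abbrev = abbreviations or build_abbreviation_dictionary()
    usable_terms = [t for t in terms if not t.obsolete]
    if cfg.hpo_per_report + 1 > len(usable_terms):
        raise ValueError("ontology too small for hpo_per_report plus probe")

    n_dates = round(0.52 * cfg.phi_per_report)
    n_persons = round(0.37 * cfg.phi_per_report)
    n_locations = cfg.phi_per_report - n_dates - n_persons
    if n_locations < 0:
        raise ValueError("phi_per_report too small for the channel split")
    # sentence budget: dates + persons (maiden-name sentence carries 2) +
    # locations + hpo + abbreviations + 1 probe
    person_sentences = max(0, n_persons - 1) if n_persons >= 2 else n_persons
    required = (
        n_dates + person_sentences + n_locations
        + cfg.hpo_per_report + cfg.abbreviations_per_report + 1
    )
    if required > cfg.n_sentences[1]:
        raise ValueError(
            f"rates need {required} sentences but budget allows {cfg.n_sentences[1]}"
        )

    fr = cfg.language == "fr-like"
    corpus: List[Tuple[str, GoldRecord]] = []
    for r in range(cfg.n_reports):
        b = _ReportBuilder()
        sentences: List[List[Tuple[str, Optional[str]]]] = []

        for _ in range(n_dates):
            if rng.random() < 0.2:  # bare year, licensed by the "in" cue
                year = str(rng.randint(2015, 2023))
                sentences.append([("The patient was born in ", None), (year, "phi:DATE_TIME"), (".", None)])
            else:
                date_str = _date_pieces(rng)
                sentences.append([("The patient was seen on ", None), (date_str, "phi:DATE_TIME"), (".", None)])

        remaining_persons = n_persons
        if remaining_persons >= 2:
            married, maiden = rng.sample(SURNAMES, 2)
            sentences.append(
                [
                    ("Mrs ", None), (married, "phi:PERSON"),
                    (", née ", None), (maiden, "phi:PERSON"),
                    (", accompanied the child.", None),
                ]
            )
            remaining_persons -= 2
        for _ in range(remaining_persons):
            name = rng.choice(SURNAMES)
            title = rng.choice(("Mr", "Dr", "Mrs"))
            sentences.append(
                [(f"{title} ", None), (name, "phi:PERSON"), (" attended the consultation.", None)]
            )

        for _ in range(n_locations):
            city = rng.choice(CITIES)
            sentences.append([("The family lives in ", None), (city, "phi:LOCATION"), (".", None)])

        n_aff, n_neg, n_fam = _reason_counts(cfg, rng)
        report_terms = rng.sample(usable_terms, cfg.hpo_per_report + 1)
        probe_term = report_terms[-1]
        planted = report_terms[: cfg.hpo_per_report]
        reasons = ["affirmed"] * n_aff + ["negated"] * n_neg + ["family"] * n_fam
        gold_hpo: List[Tuple[str, str, str]] = []
        for term, reason in zip(planted, reasons):
            label = term.name if not term.synonyms or rng.random() < 0.5 else rng.choice(term.synonyms)
            surface = label.lower()
            if reason == "affirmed":
                if fr:
                    pieces = [("Le patient présente ", None), (surface, None)]
                else:
                    pieces = [(rng.choice(("The patient has ", "Examination showed ")), None), (surface, None)]
                if rng.random() < cfg.fraction_measurement:
                    pieces.append((f" at {rng.choice(MEASUREMENTS)}", None))
                pieces.append((".", None))
                gold_hpo.append((term.id, "high", "affirmed"))
            elif reason == "negated":
                if fr:
                    pieces = [("Pas de ", None), (surface, None), (".", None)]
                else:
                    pieces = [("No ", None), (surface, None), (" was observed.", None)]
                gold_hpo.append((term.id, "low", "negated"))
            else:
                if fr:
                    pieces = [("Sa mère présente ", None), (surface, None), (".", None)]
                else:
                    pieces = [(rng.choice(("His mother has ", "There is a family history of ")), None), (surface, None), (".", None)]
                gold_hpo.append((term.id, "low", "family"))
            sentences.append(pieces)

        sentences.append(
            [
                ("This syndrome is classically associated with ", None),
                (probe_term.name.lower(), None),
                (".", None),
            ]
        )

        abbrev_keys = rng.sample(sorted(abbrev.entries), min(cfg.abbreviations_per_report, len(abbrev.entries)))
        for key in abbrev_keys:
            sentences.append([("An ", None), (key, "abbrev"), (" was performed.", None)])

        total = rng.randint(*cfg.n_sentences)
        while len(sentences) < total:
            sentences.append([(rng.choice(FILLER_SENTENCES), None)])

        rng.shuffle(sentences)
        for pieces in sentences:
            b.add_sentence(pieces)

        doc_id = f"report_{r:03d}"
        gold = GoldRecord(
            doc_id=doc_id,
            phi_spans=sorted(b.gold_phi),
            hpo_terms=gold_hpo,
            abbreviation_sites=sorted(b.gold_abbrev),
            probe_term_ids=[probe_term.id],
        )
        corpus.append((b.text(), gold))
    return corpus


# ---------------------------------------------------------------------------
# on-disk export (seed-named directory)

def write_corpus(
    out_dir: str,
    cfg: GeneratorConfig,
    n_ontology_terms: int = 30,
) -> Path:
    """Write reports, gold annotations, fixture ontology and lexicons.

    Layout: ``<out_dir>/seed-<seed>/`` containing ``reports/*.txt``,
    ``gold.tsv`` (doc_id, kind, start, end, category_or_term_id),
    ``gold.json`` (full records incl. expected confidence/reason),
    ``fixture.obo`` and the lexicon TSVs.
    """
    from .ontology import load_ontology  # local import to avoid cycle at module load

    root = Path(out_dir) / f"seed-{cfg.seed}"
    (root / "reports").mkdir(parents=True, exist_ok=True)
    obo_text = make_fixture_ontology(cfg.seed, n_ontology_terms)
    (root / "fixture.obo").write_text(obo_text, encoding="utf-8")
    terms = load_ontology(str(root / "fixture.obo"))
    corpus = generate_corpus(cfg, terms)

    gold_rows = ["doc_id\tkind\tstart\tend\tcategory_or_term_id"]
    gold_json = []
    for text, gold in corpus:
        (root / "reports" / f"{gold.doc_id}.txt").write_text(text, encoding="utf-8")
        for (s, e), cat in gold.phi_spans:
            gold_rows.append(f"{gold.doc_id}\tphi\t{s}\t{e}\t{cat}")
        for term_id, _conf, _reason in gold.hpo_terms:
            gold_rows.append(f"{gold.doc_id}\thpo\t\t\t{term_id}")
        gold_json.append(
            {
                "doc_id": gold.doc_id,
                "phi_spans": [[list(span), cat] for span, cat in gold.phi_spans],
                "hpo_terms": [list(t) for t in gold.hpo_terms],
                "abbreviation_sites": [list(s) for s in gold.abbreviation_sites],
                "probe_term_ids": gold.probe_term_ids,
            }
        )
    (root / "gold.tsv").write_text("\n".join(gold_rows) + "\n", encoding="utf-8")
    (root / "gold.json").write_text(json.dumps(gold_json, indent=1) + "\n", encoding="utf-8")

    abbrev_rows = ["abbreviation\texpansion"] + [f"{k}\t{v}" for k, v in sorted(ABBREVIATIONS.items())]
    (root / "abbreviations.tsv").write_text("\n".join(abbrev_rows) + "\n", encoding="utf-8")
    gaz_rows = ["phrase\tcategory"]
    gaz_rows += [f"{p}\tmedical_name" for p in sorted(MEDICAL_NAMES)]
    gaz_rows += [f"{p}\tdrug" for p in sorted(DRUGS)]
    gaz_rows += [f"{p}\tgene" for p in sorted(GENES)]
    (root / "allowlist.tsv").write_text("\n".join(gaz_rows) + "\n", encoding="utf-8")
    loc_rows = ["phrase\tcategory"] + [f"{c}\tlocation" for c in sorted(CITIES)]
    (root / "denylist.tsv").write_text("\n".join(loc_rows) + "\n", encoding="utf-8")
    name_rows = ["phrase\tcategory"] + [f"{s}\tmedical_name" for s in sorted(SURNAMES)]
    (root / "names.tsv").write_text("\n".join(name_rows) + "\n", encoding="utf-8")
    return root
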