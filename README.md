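# phenotext

Translate, de-identify, and summarize clinical reports into Human
Phenotype Ontology (HPO) terms — fully offline.

## The problem

Genomic medicine depends on sharing precise phenotype descriptions across
institutions and language barriers, particularly for rare-disease
matchmaking. Free-text medical reports are the richest phenotype source,
but they cannot be shared as-is: they contain protected health
information (PHI — names, dates, locations), and their clinical content
is unstructured. `phenotext` is a pipeline for clinical geneticists and
data engineers that processes a report in four stages:

1. **Abbreviation expansion** from a curated dictionary ("EEG" →
   "electroencephalogram"), recorded as a reversible edit map.
2. **Translation** into English through a pluggable engine contract
   (sentence in → English sentence out, deterministic). Deterministic
   passthrough and glossary engines ship with the package; a neural
   engine can be plugged in behind the same interface.
3. **De-identification**: rule-based date/person/location recognizers
   plus a hybrid override layer — *allowlists* of medical eponyms, drugs,
   and gene symbols veto redaction so clinical content ("Noonan",
   "Iso Kikuchi") survives, while a geographic *denylist* forces
   redaction of place names the recognizers miss. PHI spans are replaced
   by placeholders (`<PERSON>`, `<DATE_TIME>`, `<LOCATION>`, …).
4. **HPO summarization** in the ClinPhen style: an ontology term matches
   a sentence when the lemmatized token set of one of its labels is a
   subset of the sentence's lemmatized tokens. Each extracted term is
   flagged **high confidence** (affirmed for the proband) or **low
   confidence** (the sentence is negated or concerns a family member),
   with nearby measurements ("-2.5 SD", "48 cm") captured as
   quantitative evidence.

The package also contains the evaluation machinery (TP/FP/FN accounting
with major/moderate/minor severity grading, recall/precision/F1 with
half-up percent rounding, span-overlap PHI scoring) and a synthetic
report generator that plants PHI, abbreviations, and symptom phrases with
machine-readable gold annotations, so the whole pipeline is testable with
no external data.

## Worked example

```bash
# a fixture ontology (30 HP-style terms) and a small report
python -c "from phenotext import make_fixture_ontology; \
  open('fixture.obo','w').write(make_fixture_ontology(7, 30))"
cat > report.txt <<'EOF'
Mr Dupont was seen on 12/03/2023 in Montpellier. The patient has seizures at -2.5 SD. His mother has hypotonia. No ptosis was observed. An EEG was performed.
EOF

DATA=$(python -c "import phenotext, pathlib; print(pathlib.Path(phenotext.__file__).parent/'data')")
phenotext deid report.txt --ontology fixture.obo \
  --abbreviations $DATA/abbreviations.tsv \
  --allowlist $DATA/allowlist.tsv --denylist $DATA/denylist_locations.tsv
```

```
Mr <PERSON> was seen on <DATE_TIME> in <LOCATION>. The patient has seizures at -2.5 SD. His mother has hypotonia. No ptosis was observed. An electroencephalogram was performed.
```

The name, date, and city are redacted by category; the abbreviation is
expanded; the clinical content is untouched. Summarizing the same report:

```bash
phenotext summarize report.txt --ontology fixture.obo --abbreviations $DATA/abbreviations.tsv
```

```
report_id,hpo_id,hpo_label,confidence,reason,count,evidence_sentence,matched_text,quantitative
report,HP:9000010,Seizure,high,affirmed,1,1,seizures,-2.5 SD
report,HP:9000008,Hypotonia,low,family,1,2,hypotonia,
report,HP:9000012,Ptosis,low,negated,1,3,ptosis,
```

Seizures are affirmed for the proband → high confidence, with the
standard-deviation measurement attached. Hypotonia occurs in a
family-member sentence and ptosis in a negated sentence → both reported
at low confidence with their reason, rather than dropped, so a reviewing
clinician can decide. `phenotext run` writes the same information per
report as de-identified text, CSV, PhenoTips-style JSON
(`features` with `observed: yes/no`, family findings in a
`family_features` sidecar), and a TSV redaction audit;
`phenotext synth` generates a gold-annotated synthetic corpus and
`phenotext eval` scores pipeline output against it.

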