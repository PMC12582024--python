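# Methods

## Pipeline model and assumptions

`phenotext` treats a clinical report as a `Document` with character-span
sentence and token structure that is rebuilt after every text-changing
stage, so all downstream decisions (negation scope, redaction audit,
evidence offsets) can be traced to exact positions in the text they were
computed on. Stages run strictly in order: abbreviation expansion →
translation → de-identification → HPO summarization. Summarization runs
on the *de-identified* text so that exported evidence snippets are
shareable; this is safe because placeholders are angle-bracketed
uppercase tokens that the tokenizer marks as opaque and never
lemma-matches.

Offsets are 0-based half-open everywhere. All determinism claims are
strict: identical inputs and configuration produce byte-identical
outputs, which the test suite checks at the bundle level.

## Normalization and matching

Concept recognition is sentence-level subset matching (the ClinPhen
semantics): term *T* matches sentence *S* iff the normalized token set of
one of *T*'s labels (name or any OBO synonym, all synonym scopes) is a
subset of *S*'s normalized tokens. Normalization = lowercase → NFKD
accent folding → punctuation stripping → lemmatization → stopword
removal. The lemmatizer is a deterministic rule-plus-exception table
(regular English plurals plus clinical irregulars); it is deliberately
engine-independent so unit tests do not depend on a model download, and
every function that normalizes accepts a pluggable `lemmatizer` callable
for real deployments — the only contract is that the index and the
sentences use the same one. The stopword list is a small fixed English
set (articles, prepositions, copulas); negation markers ("no", "not",
"without") are deliberately excluded from it so cues survive
normalization.

The matched text reported for a hit is the minimal token window covering
one occurrence of each matched lemma (classic minimal-window scan,
deterministic tie-break toward the earlier window).

Ancestor/descendant reconciliation between matched terms is deliberately
not performed; redundant general terms are reported as matched.

## Confidence flags

Cue scope is the whole sentence: a family cue anywhere in the sentence
labels every match in it `family`; otherwise a negation cue labels them
`negated`; otherwise `affirmed`. Per term across the document: any
affirmed occurrence promotes the term to high confidence (recall-first);
otherwise the earliest occurrence's reason is kept, with family
outranking negation when both cues co-occur ("his mother has no
seizures" is family context first). Negated terms are reported at low
confidence rather than dropped or labeled "absent" — distinguishing
truly-absent phenotypes would require proper negation-scope resolution,
which is out of scope here. The representative evidence sentence (and
therefore the attached measurement) is the first affirmed occurrence if
any, else the earliest occurrence.

## De-identification

Three rule-based recognizer channels:

* **dates** — numeric formats (`dd/mm/yyyy`, `dd.mm.yyyy`,
  `yyyy-mm-dd`), month-name dates in English and French, and bare
  4-digit years only when licensed by an adjacent cue ("born", "in"), so
  "trisomy 2023" is never redacted. A bare month name alone is never a
  date ("may" is a modal verb).
* **persons** — capitalized token sequences after a trigger (titles,
  "née"/"né", "born") plus whole-word occurrences of names from an
  optional gazetteer. The recognizer signature is pluggable so an
  external NER can replace it.
* **locations** — whole-word occurrences of denylist phrases, matched
  case- and accent-insensitively through an offset-preserving fold.

Override logic: allowlists (medical eponyms, drugs, gene symbols) veto
detector spans whose surface is allowlisted or that lie wholly inside an
allowlisted multi-word phrase occurrence; denylist spans are never
vetoed, and a direct allow/deny conflict resolves to redaction
(privacy-first — identity leakage is the major-severity error class) and
is logged. Overlapping spans merge within a category; across categories
the earlier-starting span wins, ties broken PERSON > DATE_TIME >
LOCATION > ID > OTHER.

## Evaluation conventions

Missed PHI = FN, excess redaction = FP; for summarization, excess term =
FP, missed term = FN. PHI detection credit requires ≥ 1 character of
overlap with a gold span, category ignored — the confusion matrix counts
detection events, while partial or excess redactions are graded
separately by severity (major = direct identifier leaked / diagnosis
redacted; moderate = indirect identifier / clinical term; minor =
non-clinical filler). Severity filtering only regrades FPs; TP and FN
are never changed. Percentages are rounded half-up to integers and F1 is
computed from the unrounded fractions (2 decimals); this arithmetic
reproduces every published benchmark figure from its confusion counts.
HPO comparison is exact on term ids with no ontology-distance credit,
pooled per report over distinct ids.

Per-report averaged F1 is not computed: the per-report confusion counts
needed for that average are not available, only pooled totals.

## Synthetic-data generator

The generator emulates the measured medians of real genetics reports:
15 PHI, 7 HPO phrases, and 3 abbreviations per report (defaults), with
the PHI mass split ≈ 52% dates / 37% persons / 11% locations to mirror
the observed channel proportions. The confidence mix defaults to 50%
affirmed / 35% negated / 15% family, approximating the observed high/low
split with negation outnumbering family context roughly 2.7:1; 30% of
affirmed sentences carry a measurement (not reported in the source data;
fixed once as a plausible rate). Reports are 25–30 templated sentences.

Template families deliberately reproduce documented hard cases: the
maiden name ("Mrs X, née Y"), the bare city mention, the family-symptom
and negated-symptom sentences, and a descriptive-syndrome sentence
("This syndrome is classically associated with …") whose term is
recorded as a *probe* — an expected false positive, excluded from gold —
so premature-mention behavior is visible in precision numbers without
contaminating recall. The name and location pools are exported as
detector gazetteers; with them, a correctly wired pipeline must reach
100% PHI and HPO recall on generated corpora, and the test suite asserts
exactly that.

What the generator does **not** emulate: realistic clinical prose and
discourse structure, spelling errors and OCR noise, ambiguous negation
scope, co-referential family narratives, abbreviations whose expansions
are themselves phenotype phrases (covered by a dedicated unit test
instead, to keep corpus gold unambiguous), and translation divergence
beyond token-level glossary substitution. Passing the synthetic closure
therefore demonstrates that the machinery is wired correctly and
lossless under its own assumptions — not that real-world recall would be
100%; on real reports the published benchmarks (99% PHI recall, 78%
overall HPO recall) are the relevant reference points.

The fixture ontology is generated from a curated pool of 40 phenotype
names whose label token sets are mutually subset-free (a property the
suite asserts), so one planted phrase matches exactly one term; ~40% of
terms carry synonyms, links form a tree, and exactly one term is
obsolete with a `replaced_by` pointer to exercise the loader.

## Numerical and degenerate-input choices

* Half-up decimal rounding (`decimal.ROUND_HALF_UP`), never banker's
  rounding, for all reported percentages and means.
* Zero denominators in metrics yield `defined=False` rather than an
  exception; empty documents yield empty summaries; an empty lexicon is
  valid (with a logged warning) but a missing TSV column or duplicate
  abbreviation key is an error.
* Abbreviation matching is case-sensitive and whole-token, longest key
  first; expansion is single pass (expansions are not re-scanned).
* Sentence segmentation breaks on `.`, `!`, `?`, and newline, except
  periods between digits (dates, decimals) and after known
  abbreviations/titles.
* Translation preserves sentence count and inter-sentence gaps by
  contract; an engine that merges or splits sentences is rejected.

## Problem sizes

The test suite and acceptance script use a 30-term fixture ontology and
50-report corpora (~1,350 sentences), the same report count as the
published evaluation; matcher–oracle equivalence is asserted over all
generated sentences against a brute-force all-terms subset check. The
full suite runs in a few seconds on one CPU.

## Known limitations

* Negation and family cues use whole-sentence scope; sub-sentence scope
  ("no seizures but frequent falls") over- or under-flags — recoverable
  downstream because flagged terms are reported, not dropped.
* The person recognizer's trigger heuristic misses untitled bare names
  not present in the gazetteer; this mirrors the accepted design where a
  curated name list backs the detector.
* Gene-symbol allowlisting is case-insensitive like the other lists, so
  a gene symbol that is also a common capitalized word could veto a
  legitimate redaction; the bundled fixture lists avoid such symbols.
* The PhenoTips-style JSON is a declared convention (`features` +
  `family_features`), not a byte-level claim about any EHR vendor's
  dialect.
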