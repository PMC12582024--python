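"""Concept matching, negation/family flags, quantitative capture, summaries."""

import pytest

from phenotext.hposum import (
    DEFAULT_CUES,
    CueLists,
    detect_family,
    detect_negation,
    extract_quantitative,
    match_sentence,
    summarize_document,
)
from phenotext.ontology import normalize_phrase
from phenotext.preprocess import make_document


def oracle_term_ids(sentence, terms, stopwords):
    """Brute force: test every term's every label by direct subset check."""
    lemmas = sentence.lemma_set(stopwords)
    out = set()
    for t in terms:
        if t.obsolete:
            continue
        for label in t.labels:
            key = normalize_phrase(label, stopwords)
            if key and key <= lemmas:
                out.add(t.id)
                break
    return out


def test_match_sentence_fixture_example(terms, index):
    by_name = {t.name: t for t in terms}
    assert "Seizure" in by_name  # fixture invariant for this seed
    doc = make_document("d", "He has seizures and hypotonia today.")
    hits = match_sentence(doc.sentences[0], index, doc.text)
    ids = {h[0] for h in hits}
    assert by_name["Seizure"].id in ids
    assert by_name["Hypotonia"].id in ids


def test_match_sentence_no_indexed_lemma(index):
    doc = make_document("d", "Nothing relevant here.")
    assert match_sentence(doc.sentences[0], index, doc.text) == []


def test_match_equals_bruteforce_oracle_on_corpus(terms, index, corpus):
    """Matcher ≡ all-terms subset oracle over every generated sentence."""
    n_sentences = 0
    for text, _ in corpus[:20]:
        doc = make_document("d", text)
        for sent in doc.sentences:
            n_sentences += 1
            got = {h[0] for h in match_sentence(sent, index, doc.text)}
            assert got == oracle_term_ids(sent, terms, index.stopwords)
    assert n_sentences >= 400


def test_matched_text_is_minimal_covering_substring(index, terms):
    by_name = {t.name: t for t in terms}
    target = by_name["Atrial septal defect"]
    doc = make_document("d", "Echo found an atrial large septal defect today.")
    hits = {h[0]: h for h in match_sentence(doc.sentences[0], index, doc.text)}
    assert hits[target.id][2] == "atrial large septal defect"


@pytest.mark.parametrize(
    "text,negated,family",
    [
        ("No seizures were observed", True, False),
        ("Seizures since age 2", False, False),
        ("Absence of speech", True, False),
        ("His mother has microcephaly", False, True),
        ("The patient has microcephaly", False, False),
        ("Family history of epilepsy", False, True),
        ("His mother has no seizures", True, True),
    ],
)
def test_cue_detection(text, negated, family):
    doc = make_document("d", text)
    assert detect_negation(doc.sentences[0], DEFAULT_CUES, doc.text) is negated
    assert detect_family(doc.sentences[0], DEFAULT_CUES, doc.text) is family


def test_cue_lists_must_be_disjoint():
    with pytest.raises(ValueError):
        CueLists(negation_cues=frozenset({"no"}), family_cues=frozenset({"no", "mother"}))


class TestQuantitative:
    def _hit_span(self, doc, phrase):
        start = doc.text.index(phrase)
        return (start, start + len(phrase))

    def test_sd_notation(self):
        doc = make_document("d", "Microcephaly at -2.5 SD was noted.")
        got = extract_quantitative(doc.sentences[0], self._hit_span(doc, "Microcephaly"), doc.text)
        assert got == "-2.5 SD"

    def test_absent_when_no_measurement(self):
        doc = make_document("d", "He has seizures.")
        assert extract_quantitative(doc.sentences[0], self._hit_span(doc, "seizures"), doc.text) is None

    def test_nearest_of_two_measurements(self):
        # oracle by hand: one token ("at" / "with") separates each candidate
        # from "microcephaly", so the character gap decides: 4 chars to
        # "-3 SD" vs 6 chars to "48 cm"
        doc = make_document("d", "Height 48 cm with microcephaly at -3 SD.")
        got = extract_quantitative(doc.sentences[0], self._hit_span(doc, "microcephaly"), doc.text)
        assert got == "-3 SD"

    def test_percentile(self):
        doc = make_document("d", "Short stature at 3rd percentile.")
        got = extract_quantitative(doc.sentences[0], self._hit_span(doc, "Short stature"), doc.text)
        assert got == "3rd percentile"


class TestSummarize:
    def test_worked_report_three_flags(self, terms, index):
        by_name = {t.name: t for t in terms}
        text = (
            "The patient has seizures at -2.5 SD. "
            "His mother has hypotonia. "
            "No ptosis was observed."
        )
        doc = make_document("d", text)
        hits = {h.term_id: h for h in summarize_document(doc, index)}
        assert hits[by_name["Seizure"].id].confidence == "high"
        assert hits[by_name["Seizure"].id].reason == "affirmed"
        assert hits[by_name["Seizure"].id].quantitative == "-2.5 SD"
        assert hits[by_name["Hypotonia"].id].confidence == "low"
        assert hits[by_name["Hypotonia"].id].reason == "family"
        assert hits[by_name["Ptosis"].id].confidence == "low"
        assert hits[by_name["Ptosis"].id].reason == "negated"

    def test_empty_document(self, index):
        assert summarize_document(make_document("d", ""), index) == []

    def test_affirmed_then_negated_promotes_high_with_count(self, terms, index):
        by_name = {t.name: t for t in terms}
        text = "The patient has seizures. Sleep is normal. EEG done. No seizures today."
        doc = make_document("d", text)
        (hit,) = [h for h in summarize_document(doc, index) if h.term_id == by_name["Seizure"].id]
        assert hit.confidence == "high" and hit.reason == "affirmed"
        assert hit.count == 2

    def test_partition_and_order(self, index, corpus):
        for text, _ in corpus[:10]:
            doc = make_document("d", text)
            hits = summarize_document(doc, index)
            for h in hits:
                assert (h.reason == "affirmed") == (h.confidence == "high")
            offsets = [h.first_offset for h in hits]
            assert offsets == sorted(offsets)
            assert len({h.term_id for h in hits}) == len(hits)  # one hit per term

    def test_adding_sentence_never_removes_or_downgrades(self, index, corpus):
        text = corpus[0][0]
        doc_full = make_document("d", text + " The patient has nystagmus.")
        doc_base = make_document("d", text)
        base = {h.term_id: h for h in summarize_document(doc_base, index)}
        full = {h.term_id: h for h in summarize_document(doc_full, index)}
        for tid, h in base.items():
            assert tid in full
            if h.confidence == "high":
                assert full[tid].confidence == "high"

    def test_determinism(self, index, corpus):
        doc = make_document("d", corpus[0][0])
        assert summarize_document(doc, index) == summarize_document(doc, index)
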