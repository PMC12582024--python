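"""PHI detection, gazetteer overrides, span merging, redaction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenotext.deid import (
    RedactionSpan,
    apply_allowlist,
    detect_dates,
    detect_locations,
    detect_persons,
    merge_spans,
    redact,
)
from phenotext.lexicons import Gazetteer, GazetteerCategory


def spans_of(detected):
    return [(r.span, r.surface) for r in detected]


class TestDates:
    @pytest.mark.parametrize(
        "text,expected_surface",
        [
            ("seen on 12/03/2023", "12/03/2023"),
            ("born 12.03.2019 at term", "12.03.2019"),
            ("admitted 2023-01-17", "2023-01-17"),
            ("12 March 2023", "12 March 2023"),
            ("reviewed in March 2021", "March 2021"),
            ("le 3 mars 2019", "3 mars 2019"),  # source-language month
            ("born in 2019", "2019"),  # cue-licensed bare year
        ],
    )
    def test_positive(self, text, expected_surface):
        hits = detect_dates(text)
        assert [h.surface for h in hits] == [expected_surface]
        assert all(h.category == "DATE_TIME" for h in hits)

    @pytest.mark.parametrize("text", ["trisomy 2023", "karyotype 46,XY", "he may walk"])
    def test_negative(self, text):
        assert detect_dates(text) == []


class TestPersons:
    def test_trigger_title(self):
        hits = detect_persons("Mr Dupont was seen")
        assert [h.surface for h in hits] == ["Dupont"]
        assert hits[0].category == "PERSON"

    def test_maiden_name_trigger(self):
        hits = detect_persons("his mother, née Martin, is healthy")
        assert [h.surface for h in hits] == ["Martin"]

    def test_lowercase_untriggered_word_not_flagged(self):
        assert detect_persons("noonan syndrome suspected") == []

    def test_gazetteer_name_flagged_anywhere(self):
        gaz = Gazetteer(category=GazetteerCategory.MEDICAL_NAME, phrases=frozenset({"Dupont"}))
        hits = detect_persons("child Dupont returned", name_gazetteer=gaz)
        assert [h.surface for h in hits] == ["Dupont"]


class TestLocations:
    DENY = Gazetteer(category=GazetteerCategory.LOCATION, phrases=frozenset({"montpellier", "nîmes"}))

    def test_denylist_forces_redaction(self):
        hits = detect_locations("lives in Nîmes", self.DENY)
        assert [h.surface for h in hits] == ["Nîmes"]
        assert hits[0].source == "denylist"

    def test_no_denylist_phrase_no_span(self):
        assert detect_locations("lives in Berlin", self.DENY) == []

    def test_repeated_phrase_two_spans(self):
        hits = detect_locations("Montpellier then again Montpellier", self.DENY)
        assert len(hits) == 2

    def test_allow_polarity_rejected(self):
        allow = Gazetteer(category=GazetteerCategory.GENE, phrases=frozenset({"SCN1A"}))
        with pytest.raises(ValueError):
            detect_locations("x", allow)


class TestAllowlist:
    MEDICAL = Gazetteer(
        category=GazetteerCategory.MEDICAL_NAME,
        phrases=frozenset({"noonan", "iso kikuchi"}),
    )

    def test_eponym_vetoed(self):
        text = "features of Noonan syndrome"
        span = RedactionSpan(span=(12, 18), category="PERSON", surface="Noonan")
        assert apply_allowlist([span], [self.MEDICAL], text) == []

    def test_token_inside_multiword_phrase_vetoed(self):
        text = "nails show Iso Kikuchi anomaly"
        span = RedactionSpan(span=(11, 14), category="PERSON", surface="Iso")
        assert apply_allowlist([span], [self.MEDICAL], text) == []

    def test_denylist_span_never_vetoed(self):
        text = "seen in Noonan"  # imagine a town coinciding with the eponym
        span = RedactionSpan(span=(8, 14), category="LOCATION", surface="Noonan", source="denylist")
        assert apply_allowlist([span], [self.MEDICAL], text) == [span]

    def test_unlisted_span_kept(self):
        text = "Mr Dupont was seen"
        span = RedactionSpan(span=(3, 9), category="PERSON", surface="Dupont")
        assert apply_allowlist([span], [self.MEDICAL], text) == [span]


class TestMergeRedact:
    def test_same_category_overlap_merges(self):
        text = "on 12 March 2023 exactly"
        a = RedactionSpan(span=(3, 11), category="DATE_TIME", surface=text[3:11])
        b = RedactionSpan(span=(6, 16), category="DATE_TIME", surface=text[6:16])
        merged = merge_spans([a, b])
        assert len(merged) == 1
        assert merged[0].span == (3, 16)
        assert merged[0].surface == text[3:16]

    def test_empty_input(self):
        assert merge_spans([]) == []

    def test_cross_category_priority(self):
        text = "x" * 20
        person = RedactionSpan(span=(5, 10), category="PERSON", surface=text[5:10])
        location = RedactionSpan(span=(5, 12), category="LOCATION", surface=text[5:12])
        merged = merge_spans([location, person])
        assert len(merged) == 1
        assert merged[0].category == "PERSON"

    def test_redact_example(self):
        text = "Mr Dupont, 12/03/2023"
        spans = [
            RedactionSpan(span=(3, 9), category="PERSON", surface="Dupont"),
            RedactionSpan(span=(11, 21), category="DATE_TIME", surface="12/03/2023"),
        ]
        out, report = redact(text, spans)
        assert out == "Mr <PERSON>, <DATE_TIME>"
        assert [r["surface"] for r in report] == ["Dupont", "12/03/2023"]

    def test_redact_no_spans_identity(self):
        text = "nothing to hide"
        out, report = redact(text, [])
        assert out == text and report == []

    def test_redact_rejects_overlap(self):
        text = "abcdefgh"
        spans = [
            RedactionSpan(span=(0, 4), category="PERSON", surface="abcd"),
            RedactionSpan(span=(2, 6), category="DATE_TIME", surface="cdef"),
        ]
        with pytest.raises(ValueError):
            redact(text, spans)

    @given(st.lists(st.tuples(st.integers(0, 90), st.integers(1, 8)), max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_placeholder_count_and_outside_text_preserved(self, raw):
        text = "abcdefghij" * 10
        spans = merge_spans(
            [
                RedactionSpan(span=(s, s + w), category="ID", surface=text[s : s + w])
                for s, w in raw
                if s + w <= len(text)
            ]
        )
        out, report = redact(text, spans)
        assert out.count("<ID>") == len(spans) == len(report)
        # text outside spans is byte-identical
        rebuilt = out
        for sp in spans:
            rebuilt = rebuilt.replace("<ID>", sp.surface, 1)
        assert rebuilt == text

    def test_merge_order_independence(self):
        text = "Mr Dupont seen on 12 March 2023 in town"
        spans = [
            RedactionSpan(span=(3, 9), category="PERSON", surface="Dupont"),
            RedactionSpan(span=(18, 26), category="DATE_TIME", surface=text[18:26]),
            RedactionSpan(span=(21, 31), category="DATE_TIME", surface=text[21:31]),
        ]
        import itertools

        outputs = {
            redact(text, merge_spans(list(perm)))[0]
            for perm in itertools.permutations(spans)
        }
        assert len(outputs) == 1
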