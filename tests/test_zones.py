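"""Zone segmentation, ranking, cohort/population extraction, meta/review."""

import itertools

import pytest

from mutdx.ingest import Document
from mutdx.zones import (
    ZONE_RANK,
    detect_meta_analysis,
    detect_outcomes,
    detect_patient_context,
    detect_review,
    extract_cohort,
    extract_population,
    load_country_gazetteer,
    rank_zone,
    segment_zones,
)


@pytest.fixture(scope="module")
def countries():
    return load_country_gazetteer()


class TestSegmentation:
    def test_structured_labels_override(self):
        doc = Document.from_sentences("1", "A title.", [
            "BACKGROUND: Cancer is common.",
            "METHODS: We genotyped patients.",
            "RESULTS: The variant was associated.",
            "CONCLUSIONS: It matters.",
        ])
        doc.structured_labels = {1: "BACKGROUND", 2: "METHODS",
                                 3: "RESULTS", 4: "CONCLUSIONS"}
        assert segment_zones(doc) == ["Title", "Introduction", "Methods",
                                      "Results", "Conclusion"]

    def test_cue_free_four_sentence_abstract(self):
        doc = Document.from_sentences("1", "A title.", [
            "First plain sentence.", "Second plain sentence.",
            "Third plain sentence.", "Fourth plain sentence.",
        ])
        # 1-3 Introduction; Methods would start at 4 but the last sentence
        # is claimed by the Conclusion default
        assert segment_zones(doc) == ["Title", "Introduction", "Introduction",
                                      "Introduction", "Conclusion"]

    def test_zone_blocks_partition_and_are_ordered(self):
        doc = Document.from_sentences("1", "A title.", [
            "Background statement.",
            "We studied 100 patients.",
            "We found that the variant mattered.",
            "In conclusion, it matters.",
        ])
        zones = segment_zones(doc)
        assert len(zones) == len(doc.sentences)
        order = ["Title", "Introduction", "Methods", "Results", "Conclusion"]
        indices = [order.index(z) for z in zones]
        assert indices == sorted(indices)


class TestRanking:
    def test_results_beats_introduction(self):
        assert rank_zone({"Introduction", "Results"}) == "Results"

    def test_singleton(self):
        assert rank_zone({"Methods"}) == "Methods"

    def test_full_order_enumeration(self):
        # oracle: brute force over all non-empty subsets
        for r in range(1, 6):
            for subset in itertools.combinations(ZONE_RANK, r):
                expected = min(subset, key=ZONE_RANK.index)
                assert rank_zone(set(subset)) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            rank_zone(set())


class TestPatientContext:
    def test_first_cohort_sentence_wins(self):
        doc = Document.from_sentences("1", "A title.", [
            "Background without any cohort.",
            "A total of 50 patients were enrolled.",
            "Another 80 controls were recruited later.",
        ])
        assert detect_patient_context(doc) == 2

    def test_no_cohort_words(self):
        doc = Document.from_sentences("1", "A title.", ["Nothing relevant."])
        assert detect_patient_context(doc) is None


class TestCohort:
    def test_no_numbers(self):
        assert extract_cohort("patients and controls were compared") == (None, None)

    def test_thousands_separator(self):
        assert extract_cohort("we enrolled 10,137 cases and 15,566 controls") \
            == (10137, 15566)

    def test_counts_literally_occur_in_sentence(self):
        text = "A total of 453 breast cancer patients and 382 controls."
        p, c = extract_cohort(text)
        assert str(p) in text and str(c) in text


class TestPopulation:
    def test_demonym_maps_to_country(self, countries):
        assert extract_population("66 Finnish HPC families", countries) == ["Finland"]

    def test_no_geography(self, countries):
        assert extract_population("a control group was used", countries) == []

    def test_dedup_preserves_order(self, countries):
        got = extract_population(
            "patients from Greece and Turkey; Greek controls", countries)
        assert got == ["Greece", "Turkey"]


class TestMetaReview:
    def test_no_keyword(self):
        doc = Document.from_sentences("1", "A title.", ["Ordinary study."])
        assert detect_meta_analysis(doc) == (False, None, None, None)

    def test_subjects_via_case_control_summation(self):
        doc = Document.from_sentences("1", "A meta-analysis of IL-6.", [
            "Data from 10,137 cases and 15,566 controls were pooled."])
        is_meta, _, _, subjects = detect_meta_analysis(doc)
        assert is_meta and subjects == 10137 + 15566

    def test_review_flag_exact_match(self):
        doc = Document.from_sentences("1", "T.", [],
                                      [("Journal Article", "PT"), ("Review", "PT")])
        assert detect_review(doc)

    def test_review_flag_empty_pt(self):
        doc = Document.from_sentences("1", "T.", [])
        assert not detect_review(doc)

    def test_review_prefix_mode_is_opt_in(self):
        doc = Document.from_sentences("1", "T.", [],
                                      [("Review of Reported Cases", "PT")])
        assert not detect_review(doc)
        assert detect_review(doc, match="prefix")


class TestOutcomes:
    def test_no_trigger_no_links(self):
        assert detect_outcomes("the variant was common in carriers") == []

    def test_resistance_with_to_phrase(self):
        (link,) = [l for l in detect_outcomes("resistance to cisplatin emerged")
                   if l.outcome == "drug-resistance"]
        assert link.drug == "cisplatin"
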