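"""Dictionary tagging, acronym filtering, generic-disease resolution."""

import re

import pytest

from mutdx.chunker import parse_sentence
from mutdx.entities import (
    DictionaryTagger,
    Gazetteer,
    GazetteerError,
    filter_disease_acronyms,
    resolve_generic_diseases,
    tag_entities,
)
from mutdx.ingest import Document


@pytest.fixture
def genes():
    return Gazetteer("gene", {"SELP": "SELP", "PSGL-1": "PSGL-1",
                              "Androgen Receptor": "AR", "BRCA1": "BRCA1"})


@pytest.fixture
def diseases():
    return Gazetteer("disease", {
        "breast cancer": "breast cancer", "cancer": "cancer",
        "CHD": "coronary heart disease", "gastric cancer": "gastric cancer",
        "HNPCC": "hereditary non-polyposis colorectal cancer",
        "hereditary non-polyposis colorectal cancer":
            "hereditary non-polyposis colorectal cancer",
    })


class TestDictionaryTagger:
    def test_tags_genes_in_listing_sentence(self, genes, diseases):
        doc = Document.from_sentences("1", "A title.", [
            "The SNPs T715P in SELP, Met62Ile in PSGL-1 gene contribute "
            "to CHD."])
        mentions = tag_entities(doc, genes, diseases)
        got = {(m.kind, m.text) for m in mentions}
        assert ("gene", "SELP") in got
        assert ("gene", "PSGL-1") in got
        assert ("disease", "CHD") in got

    def test_empty_gazetteers_yield_nothing(self):
        doc = Document.from_sentences("1", "BRCA1 and breast cancer.", [])
        assert tag_entities(doc, Gazetteer("gene"), Gazetteer("disease")) == []

    def test_leftmost_longest_against_bruteforce(self, genes, diseases):
        text = "A role for breast cancer and cancer genetics."
        tagger = DictionaryTagger(genes, diseases)
        got = [(m.start, m.end, m.text) for m in tagger.tag_sentence(text, 0)]
        # oracle: every gazetteer term occurrence, then leftmost-longest
        hits = []
        for term in list(genes.term_to_canonical) + list(diseases.term_to_canonical):
            for m in re.finditer(rf"(?<![\w-]){re.escape(term)}(?![\w-])",
                                 text, re.I):
                hits.append((m.start(), m.end(), m.group(0)))
        hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
        chosen = []
        for h in hits:
            if all(h[0] >= c[1] or h[1] <= c[0] for c in chosen):
                chosen.append(h)
        assert got == chosen
        assert ("breast cancer" in [t for _, _, t in got])
        # the nested bare "cancer" inside "breast cancer" is not re-tagged
        assert all(not (s >= got[0][0] and e <= got[0][1]) or t == "breast cancer"
                   for s, e, t in got)

    def test_missing_gazetteer_file_is_config_error(self, tmp_path):
        with pytest.raises(GazetteerError):
            Gazetteer.from_tsv(tmp_path / "nope.tsv", "gene")


class TestAcronymFilter:
    def test_gene_long_form_removes_disease_acronym(self, genes, diseases):
        doc = Document.from_sentences("17591767", "A title.", [
            "The Androgen Receptor (AR) is expressed; AR was linked to risk."])
        mentions = [m for m in tag_entities(doc, genes, diseases)]
        # simulate the external disease tagger reporting "AR" as a disease
        from mutdx.entities import EntityMention

        mentions.append(EntityMention("disease", "AR", 1, (45, 47), "AR"))
        out = filter_disease_acronyms(mentions, doc.acronyms, genes, diseases)
        assert all(not (m.kind == "disease" and m.text == "AR") for m in out)

    def test_no_acronyms_leaves_mentions_unchanged(self, genes, diseases):
        from mutdx.entities import EntityMention

        mentions = [EntityMention("disease", "breast cancer", 0, (0, 13),
                                  "breast cancer")]
        assert filter_disease_acronyms(mentions, {}, genes, diseases) == mentions

    def test_disease_long_form_is_retained(self, genes, diseases):
        from mutdx.entities import EntityMention

        acronyms = {"HNPCC": "hereditary non-polyposis colorectal cancer"}
        mentions = [EntityMention("disease", "HNPCC", 0, (0, 5), "HNPCC")]
        out = filter_disease_acronyms(mentions, acronyms, genes, diseases)
        assert out == mentions

    def test_filtering_never_adds_mentions(self, genes, diseases):
        from mutdx.entities import EntityMention

        mentions = [
            EntityMention("disease", "AR", 0, (0, 2), "AR"),
            EntityMention("gene", "BRCA1", 0, (10, 15), "BRCA1"),
        ]
        out = filter_disease_acronyms(
            mentions, {"AR": "Androgen Receptor"}, genes, diseases)
        assert len(out) <= len(mentions)


class TestGenericDiseaseResolution:
    def _mentions(self, specs):
        from mutdx.entities import EntityMention

        return [EntityMention("disease", t, s, span, t) for t, s, span in specs]

    def test_single_candidate(self):
        mentions = self._mentions([
            ("breast cancer", 0, (10, 23)),
            ("tumor", 2, (4, 9)),
        ])
        out = resolve_generic_diseases(mentions)
        assert out[1].canonical == "breast cancer"

    def test_specific_mention_unchanged(self):
        mentions = self._mentions([("gastric cancer", 0, (0, 14))])
        assert resolve_generic_diseases(mentions)[0].canonical == "gastric cancer"

    def test_nearer_of_two_candidates_wins(self):
        mentions = self._mentions([
            ("gastric cancer", 0, (0, 14)),
            ("breast cancer", 3, (0, 13)),
            ("cancer", 4, (20, 26)),
        ])
        # brute-force distance: breast cancer (1 sentence away) beats gastric (4)
        out = resolve_generic_diseases(mentions)
        assert out[2].canonical == "breast cancer"

    def test_same_merged_np_preferred(self):
        text = "the tumor of breast cancer patients was large"
        parsed = {0: parse_sentence(text)}
        mentions = self._mentions([
            ("gastric cancer", 0, (60, 74)),   # outside the NP, nearer later
            ("breast cancer", 0, (13, 26)),
            ("tumor", 0, (4, 9)),
        ])
        out = resolve_generic_diseases(mentions, parsed)
        assert out[2].canonical == "breast cancer"

    def test_no_specific_disease_stays_generic(self):
        mentions = self._mentions([("cancer", 0, (0, 6))])
        assert resolve_generic_diseases(mentions)[0].canonical == "cancer"
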