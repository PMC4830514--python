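"""Record parsing, sentence splitting, acronym detection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutdx.ingest import (
    Document,
    RecordParseError,
    detect_acronyms,
    parse_medline,
    parse_pubmed_xml,
    parse_record,
    split_sentences,
)

PUBMED_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
 <PubmedArticle>
  <MedlineCitation>
   <PMID>12345</PMID>
   <Article>
    <ArticleTitle>BRCA1 variants in breast cancer.</ArticleTitle>
    <Abstract>
     <AbstractText Label="BACKGROUND">Breast cancer is common.</AbstractText>
     <AbstractText Label="METHODS">We genotyped 100 patients.</AbstractText>
     <AbstractText Label="RESULTS">The T877A variant was associated with breast cancer.</AbstractText>
     <AbstractText Label="CONCLUSIONS">T877A matters.</AbstractText>
    </Abstract>
   </Article>
   <MeshHeadingList>
    <MeshHeading><DescriptorName>Breast Neoplasms</DescriptorName></MeshHeading>
   </MeshHeadingList>
   <PublicationTypeList>
    <PublicationType>Journal Article</PublicationType>
   </PublicationTypeList>
  </MedlineCitation>
 </PubmedArticle>
</PubmedArticleSet>
"""

MEDLINE_FLAT = """PMID- 20043205
TI  - Lack of an association: a meta-analysis involving 25,703 subjects.
AB  - A total of 11 publications containing 12 studies including 10,137 cases
      and 15,566 controls were identified.
MH  - Breast Neoplasms
PT  - Journal Article
PT  - Meta-Analysis
"""


class TestParseRecord:
    def test_pubmed_xml_structured_labels(self):
        (doc,) = parse_pubmed_xml(PUBMED_XML)
        assert doc.pmid == "12345"
        assert doc.title.startswith("BRCA1")
        labels = {doc.structured_labels[i] for i in doc.structured_labels}
        assert labels == {"BACKGROUND", "METHODS", "RESULTS", "CONCLUSIONS"}
        assert ("Breast Neoplasms", "MH") in doc.mesh_terms
        assert ("Journal Article", "PT") in doc.mesh_terms
        assert ("Review", "PT") not in doc.mesh_terms

    def test_medline_flat(self):
        (doc,) = parse_medline(MEDLINE_FLAT)
        assert doc.pmid == "20043205"
        assert "publications" in doc.sentences[1].text
        assert ("Meta-Analysis", "PT") in doc.mesh_terms

    def test_title_only_record_is_flagged(self):
        (doc,) = parse_record("Just a title, nothing else")
        assert len(doc.sentences) == 1
        assert not doc.has_abstract

    def test_malformed_xml_raises(self):
        with pytest.raises(RecordParseError):
            parse_pubmed_xml("<PubmedArticleSet><broken")

    def test_missing_pmid_raises(self):
        xml = "<PubmedArticleSet><PubmedArticle><MedlineCitation><Article><ArticleTitle>t</ArticleTitle></Article></MedlineCitation></PubmedArticle></PubmedArticleSet>"
        with pytest.raises(RecordParseError):
            parse_pubmed_xml(xml)


class TestSplitSentences:
    def test_empty(self):
        assert split_sentences("") == []

    def test_two_sentence_passage(self):
        text = ("Here, we screened for mutations of the ELAC2/HPC2 gene in 66 "
                "Finnish HPC families. Several sequence variants, including a "
                "new exonic variant (Glu622Val) were found, but none of the "
                "mutations were truncating.")
        sents = split_sentences(text)
        assert len(sents) == 2
        assert sents[0].text.endswith("families.")
        assert sents[1].text.startswith("Several")

    @pytest.mark.parametrize("text", [
        "The effect (e.g. in Fig. 2) was clear. A second sentence follows.",
        "Cases vs. controls were compared. The P value was 0.043.",
        "Values were 30.7 weeks and 24.7 weeks. Nothing was split inside.",
    ])
    def test_abbreviations_and_decimals_do_not_split(self, text):
        assert len(split_sentences(text)) == 2

    @given(st.lists(
        st.sampled_from([
            "The BRCA1 variant was common.",
            "We studied 453 patients from Greece.",
            "No association was found (P = 0.52).",
            "Results indicate a role for T877A in cancer.",
        ]),
        min_size=0, max_size=6,
    ))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_never_loses_characters(self, sentences):
        text = " ".join(sentences)
        sents = split_sentences(text)
        # re-concatenation with original gap whitespace reconstructs the text
        rebuilt = ""
        last = 0
        for s in sents:
            rebuilt += text[last:s.char_span[0]] + s.text
            last = s.char_span[0] + len(s.text)
        rebuilt += text[last:]
        assert rebuilt == text
        spans = [s.char_span for s in sents]
        assert spans == sorted(spans)
        assert all(b[0] >= a[1] for a, b in zip(spans, spans[1:]))


class TestAcronyms:
    @pytest.mark.parametrize("text,short,long", [
        ("the chemokine-like receptor 1 (CMKLR1) was associated",
         "CMKLR1", "chemokine-like receptor 1"),
        ("improved progression-free survival (PFS) in the cohort",
         "PFS", "progression-free survival"),
    ])
    def test_letter_alignment(self, text, short, long):
        doc = Document.from_sentences("1", "A title.", [text + "."])
        assert doc.acronyms.get(short) == long

    def test_no_parentheses_yields_empty_map(self):
        doc = Document.from_sentences("1", "A title.", ["No short forms here."])
        assert doc.acronyms == {}

    def test_first_definition_wins(self):
        doc = Document.from_sentences("1", "A title.", [
            "Overall survival (OS) improved.",
            "The operating system (OS) is irrelevant.",
        ])
        assert doc.acronyms["OS"] == "Overall survival"

    def test_unalignable_parenthetical_skipped(self):
        doc = Document.from_sentences("1", "A title.", [
            "The cohort (XYZQ) was large."])
        assert "XYZQ" not in doc.acronyms
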