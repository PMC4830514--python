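"""Sentence-type classification, disease fallback, pair extraction."""

import pytest

from mutdx.disease_link import (
    NPContext,
    STAT_RE,
    resolve_disease_fallback,
)
from mutdx.ingest import Document


def analyze(pipe, title, body):
    return pipe.process(Document.from_sentences("t", title, body))


class TestClassification:
    def test_comparison_via_compare_pattern(self, analyses):
        res = analyses["ex10"].sentence_types[1]
        assert res.primary == "Comparison"
        assert res.match.pattern.trigger == "compare"

    def test_statistical_requires_no_pattern_match(self, analyses):
        res = analyses["ex12"].sentence_types[1]
        assert res.primary == "Statistical"
        assert res.match is None

    def test_mutation_found_via_detect_pattern(self, analyses):
        res = analyses["ex13"].sentence_types[1]
        assert res.mutation_found is not None
        assert res.mutation_found.pattern.trigger == "detect"

    def test_association_precedence_over_statistical(self, pipe):
        # matches an association pattern AND contains a P-value: Association
        a = analyze(pipe, "A title.", [
            "The T877A variant was significantly associated with lung "
            "cancer (P = 0.01)."])
        assert a.sentence_types[1].primary == "Association"

    @pytest.mark.parametrize("text,expected", [
        ("the difference was significant (P = 0.043)", True),
        ("an odds ratio of 2.1 was reported", True),
        ("OR = 1.52 in carriers", True),
        ("either one or the other allele", False),
        ("the P protein binds DNA", False),
    ])
    def test_stat_regex(self, text, expected):
        assert bool(STAT_RE.search(text)) == expected


class TestNPTyping:
    def test_specific_mutation_np(self, analyses):
        a = analyses["ex3"]
        ctx = NPContext(a, 0)
        (np,) = [c for c in a.sentences[0].parsed.chunks if c.kind == "NP"]
        assert ctx.np_is_mutation(np)
        assert "R-1699-W" in ctx.referents(np)

    def test_plain_np_is_not_mutation(self, pipe):
        a = analyze(pipe, "A title.", ["An increased risk was observed."])
        ctx = NPContext(a, 1)
        np = next(c for c in a.sentences[1].parsed.chunks if c.kind == "NP")
        assert not ctx.np_is_mutation(np)

    def test_generic_np_with_gene_pulls_referent(self, analyses):
        # "known and new PON1 mutations" refers back to I102V
        a = analyses["ex9"]
        ctx = NPContext(a, 2)
        keys = []
        for c in a.sentences[2].parsed.chunks:
            if c.kind == "NP":
                keys.extend(ctx.referents(c))
        assert "I-102-V" in keys


class TestFallback:
    def test_title_fallback(self, analyses):
        assert resolve_disease_fallback(1, analyses["ex12"]) == ("NSCLC", "title")

    def test_pc_fallback_beats_title(self, analyses):
        # ex14: PC sentence (breast cancer) precedes the MutationFound sentence
        fb = resolve_disease_fallback(2, analyses["ex14"])
        assert fb == ("breast cancer", "PC")

    def test_pc_only_if_before_current_sentence(self, pipe):
        a = analyze(pipe, "KLF6 variants in cancer of the prostate.", [
            "The IVS1 -27G> A variant was studied (P = 0.02).",
            "A total of 100 prostate cancer patients were enrolled."])
        # PC is sentence 2, after the statistical sentence 1: title used
        fb = resolve_disease_fallback(1, a)
        assert fb is not None and fb[1] == "title"

    def test_no_disease_anywhere(self, pipe):
        a = analyze(pipe, "A neutral title.", ["Nothing medical here."])
        assert resolve_disease_fallback(1, a) is None


class TestExtraction:
    def test_statistical_pair_uses_title_disease(self, analyses):
        pairs = {(p.mutation_key, p.disease) for p in analyses["ex12"].pairs}
        assert ("C--37-A", "NSCLC") in pairs

    def test_mutation_found_lookahead(self, analyses):
        pairs = [(p.mutation_key, p.disease, p.sentence_type)
                 for p in analyses["ex14"].pairs]
        assert sorted(p[0] for p in pairs) == ["9474insA", "982del4", "C-8729-A"]
        assert all(p[1] == "breast cancer" for p in pairs)
        assert all(p[2] == "MutationFound" for p in pairs)

    def test_title_type_fires_without_pattern(self, analyses):
        (pair,) = analyses["ex15"].pairs
        assert pair.sentence_type in ("Title", "Association")
        assert (pair.mutation_key, pair.disease) == ("G-IVS1-27-A", "prostate cancer")

    def test_statistical_without_mutation_yields_nothing(self, pipe):
        a = analyze(pipe, "A title about breast cancer.", [
            "The difference between groups was significant (P = 0.02)."])
        assert a.pairs == []

    def test_pair_mutations_exist_in_document(self, analyses):
        for case_id, a in analyses.items():
            keys = {m.key for m in a.mutation_occurrences()}
            keys |= {al.resolved.key for sa in a.sentences.values()
                     for al in sa.alleles if al.resolved}
            keys |= {g.resolved.key for sa in a.sentences.values()
                     for g in sa.genotypes if g.resolved}
            for p in a.pairs:
                assert p.mutation_key in keys, (case_id, p)

    def test_one_pair_per_mutation_disease_and_sentence(self, analyses):
        for a in analyses.values():
            sigs = [(p.mutation_key, p.disease, p.sentence_index)
                    for p in a.pairs]
            assert len(sigs) == len(set(sigs))
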