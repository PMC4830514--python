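"""Mutation detection, conjunction expansion, normalization, allele and
genotype resolution."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutdx.lexicon import AA3_TO_1
from mutdx.mutations import (
    MutationMention,
    NormalizationError,
    detect_alleles,
    detect_format_mutations,
    detect_genotypes,
    detect_mutations,
    detect_nl_mutations,
    expand_conjunctions,
    normalize,
    resolve_allele,
    resolve_genotypes,
)


class TestFormatDetection:
    @pytest.mark.parametrize("text,kind,wild,pos,mutant", [
        ("Asp 327—>Asn", "substitution-protein", "Asp", "327", "Asn"),
        ("Ala282Val", "substitution-protein", "Ala", "282", "Val"),
        ("Phe153——Ala", "substitution-protein", "Phe", "153", "Ala"),
        ("T877A", "substitution-dna", "T", "877", "A"),
        ("R1699W", "substitution-protein", "R", "1699", "W"),
        ("A3537G", "substitution-dna", "A", "3537", "G"),
        ("4304G> A", "substitution-dna", "G", "4304", "A"),
        ("1066-6T> G", "substitution-dna", "T", "1066-6", "G"),
        ("-79C/T", "substitution-dna", "C", "-79", "T"),
        ("+49G/A", "substitution-dna", "G", "+49", "A"),
        ("-37C—> A", "substitution-dna", "C", "-37", "A"),
        ("IVS1 -27G> A", "substitution-dna", "G", "IVS1-27", "A"),
        ("C-2123G", "substitution-dna", "C", "-2123", "G"),
        ("5622C > T", "substitution-dna", "C", "5622", "T"),
    ])
    def test_substitutions(self, text, kind, wild, pos, mutant):
        (m,) = detect_format_mutations(text)
        assert (m.kind, m.wild, m.position, m.mutant) == (kind, wild, pos, mutant)

    @pytest.mark.parametrize("text,kind,pos,seq", [
        ("5382insC", "insertion", "5382", "C"),
        ("IVS9-5insT", "insertion", "IVS9-5", "T"),
        ("9474insA", "insertion", "9474", "A"),
        ("9631delC", "deletion", "9631", "C"),
        ("6886delGAAAA", "deletion", "6886", "GAAAA"),
        ("IVS19+2delT", "deletion", "IVS19+2", "T"),
        ("982del4", "deletion", "982", "4"),
    ])
    def test_indels(self, text, kind, pos, seq):
        (m,) = detect_format_mutations(text)
        assert (m.kind, m.position, m.mutant) == (kind, pos, seq)

    @pytest.mark.parametrize("text", ["rs1800795", "ss984046046"])
    def test_dbsnp(self, text):
        (m,) = detect_format_mutations(text)
        assert m.kind == "dbsnp"
        assert m.raw == text

    def test_plain_text_yields_nothing(self):
        assert detect_format_mutations("plain text with no variants") == []
        assert detect_format_mutations(
            "We used PCR-SSCP methods on exons 2, 5 and 11") == []

    def test_termination(self):
        (m,) = detect_format_mutations("S2834 ter")
        assert m.kind == "termination"
        assert (m.wild, m.position) == ("S", "2834")

    def test_raw_rematches_in_isolation(self):
        text = ("We found T877A, 5382insC, rs1800795 and the 1066-6T> G "
                "substitution in carriers.")
        for m in detect_mutations(text):
            again = detect_mutations(m.raw)
            assert any(x.key == m.key for x in again), m.raw


class TestNLDetection:
    @pytest.mark.parametrize("text,expected", [
        ("A--> C transversion in codon 135", [("A", "135", "C")]),
        ("T to C transition at positions 409 and 412",
         [("T", "409", "C"), ("T", "412", "C")]),
        ("Ser—> Leu change at amino acid 217", [("Ser", "217", "Leu")]),
        ("guanine-adenine point mutation at nucleotide 2185",
         [("guanine", "2185", "adenine")]),
    ])
    def test_pair_plus_anchor(self, text, expected):
        got = [(m.wild, m.position, m.mutant) for m in detect_nl_mutations(text)]
        assert got == expected

    def test_termination_phrase(self):
        (m,) = detect_nl_mutations("termination at codon 3110")
        assert m.kind == "termination"
        assert m.position == "3110"

    def test_generic_references_are_not_mentions(self):
        assert detect_mutations("the VNTR variants in PSGL-1 gene") == []
        assert detect_mutations("several somatic mutations were found") == []


class TestConjunctionExpansion:
    def test_six_mutations(self):
        text = "Ala16 >Cys, Thr, Met, Arg, His and Tyr"
        keys = [m.key for m in detect_mutations(text)]
        assert keys == ["A-16-C", "A-16-T", "A-16-M", "A-16-R", "A-16-H",
                        "A-16-Y"]

    def test_no_trailing_list_returns_seed_only(self):
        (seed,) = detect_format_mutations("Ala282Val")
        assert expand_conjunctions("Ala282Val", seed) == [seed]

    @pytest.mark.parametrize("listing,n", [
        ("Arg to Trp or Gln at codon 194", 2),
        ("Ala16 >Cys, Thr and Met", 3),
    ])
    def test_count_matches_independent_splitter(self, listing, n):
        # oracle: split the mutant listing (after the first separator) on
        # comma/and/or and count fragments holding a residue symbol
        aa = "|".join(AA3_TO_1)
        tail = re.split(r">|\bto\b", listing, maxsplit=1)[1]
        fragments = re.split(r",|\band\b|\bor\b", tail)
        mutants = [f for f in fragments if re.search(rf"\b(?:{aa})\b", f)]
        assert len(mutants) == n
        assert len(detect_mutations(listing)) == n


class TestNormalization:
    @pytest.mark.parametrize("a,b", [
        ("G5557A", "5557G>A"),
        ("Ala282Val", "A282V"),
        ("Arg194Trp", "arginine to tryptophan at residue 194"),
    ])
    def test_surface_variants_share_one_key(self, a, b):
        (ma,) = detect_mutations(a)
        (mb,) = detect_mutations(b)
        assert ma.key == mb.key

    def test_idempotent_across_fixture_mentions(self):
        texts = ["T877A", "Asp 327—>Asn", "5382insC", "982del4", "rs1800795",
                 "IVS1 -27G> A", "-79C/T"]
        for t in texts:
            for m in detect_mutations(t):
                key = normalize(m)
                rendered = MutationMention(m.kind, m.wild, m.position,
                                           m.mutant, key, 0, len(key))
                assert normalize(rendered) == key

    def test_unknown_residue_raises(self):
        bogus = MutationMention("substitution-protein", "Xyz", "5", "Ala",
                                "Xyz5Ala", 0, 7)
        with pytest.raises(NormalizationError):
            normalize(bogus)

    def test_silent_substitution_flagged(self):
        (m,) = detect_mutations("A123A")
        assert m.silent

    @given(
        st.sampled_from(sorted(AA3_TO_1)),
        st.integers(min_value=1, max_value=9999),
        st.sampled_from(sorted(AA3_TO_1)),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_three_letter_and_one_letter_agree(self, w3, pos, m3):
        a = f"{w3}{pos}{m3}"
        b = f"{AA3_TO_1[w3]}{pos}{AA3_TO_1[m3]}"
        da, db = detect_mutations(a), detect_mutations(b)
        assert da and db
        assert da[0].key == db[0].key


class TestAllelesAndGenotypes:
    def test_allele_resolves_to_matching_mutation(self):
        mut = detect_mutations("The Arg194Trp polymorphism was studied.")
        for m in mut:
            m.sentence_index = 0
        (allele,) = detect_alleles("XRCC1 194Trp allele increased the risk")
        allele.sentence_index = 1
        assert resolve_allele(allele, mut).resolved.key == "R-194-W"

    def test_unmatched_allele_stays_unresolved(self):
        (allele,) = detect_alleles("the 194Trp allele")
        assert resolve_allele(allele, []).resolved is None

    def test_closest_preceding_candidate_wins(self):
        a = detect_mutations("Arg194Trp was found.")[0]
        b = detect_mutations("A second Arg194Trp occurred.")[0]
        a.sentence_index, b.sentence_index = 0, 3
        (allele,) = detect_alleles("the 194Trp allele")
        allele.sentence_index = 4
        assert resolve_allele(allele, [a, b]).resolved is b

    def test_genotypes_bind_via_shared_symbols(self):
        prior = detect_mutations("The +49G/A polymorphism was genotyped.")
        for m in prior:
            m.sentence_index = 0
        text = ("the genotype frequency was 40.3% for GG, and 59.7% for "
                "AG+AA, respectively")
        genos = detect_genotypes(text)
        for g in genos:
            g.sentence_index = 1
        resolve_genotypes(genos, prior)
        assert {g.raw for g in genos} == {"GG", "AG", "AA"}
        assert all(g.resolved.key == "G-+49-A" for g in genos)

    def test_genotype_requires_context(self):
        assert detect_genotypes("the AG news agency reported") == []
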