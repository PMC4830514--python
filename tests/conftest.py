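"""Shared fixtures: one Pipeline per session and cached analyses of the
curated example corpus, plus the expectation checker used by both the
example suite and the acceptance suite."""

from __future__ import annotations

import pytest

from mutdx.emit import assemble
from mutdx.fixtures import FixtureCase, paper_corpus
from mutdx.pipeline import DocAnalysis, Pipeline
from mutdx.zones import detect_meta_analysis, extract_population, load_country_gazetteer


@pytest.fixture(scope="session")
def pipe() -> Pipeline:
    return Pipeline()


@pytest.fixture(scope="session")
def corpus() -> dict[str, FixtureCase]:
    return {c.case_id: c for c in paper_corpus()}


@pytest.fixture(scope="session")
def analyses(pipe, corpus) -> dict[str, DocAnalysis]:
    return {cid: pipe.process(c.document()) for cid, c in corpus.items()}


def check_case(case: FixtureCase, analysis: DocAnalysis, pipe: Pipeline) -> None:
    """Assert every expectation recorded for a fixture case."""
    exp = case.expected
    meta = analysis.metadata

    if "patients" in exp:
        assert meta.patients == exp["patients"]
    if "controls" in exp:
        assert meta.controls == exp["controls"]
    if "populations" in exp:
        for pop in exp["populations"]:
            assert pop in meta.populations
    if "pc_sentence_index" in exp:
        assert meta.pc_sentence_index == exp["pc_sentence_index"]
    if "meta" in exp:
        assert detect_meta_analysis(analysis.document) == exp["meta"]
    if "zones" in exp:
        assert analysis.zones == exp["zones"]

    if "primary_type" in exp:
        for sidx, typ in exp["primary_type"].items():
            assert analysis.sentence_types[sidx].primary == typ
    if "pattern" in exp:
        for sidx, src in exp["pattern"].items():
            res = analysis.sentence_types[sidx]
            assert res.match is not None
            assert res.match.pattern.source == src
    if "mutation_found" in exp:
        for sidx, flag in exp["mutation_found"].items():
            assert (analysis.sentence_types[sidx].mutation_found is not None) == flag

    if "mutation_keys" in exp:
        for sidx, keys in exp["mutation_keys"].items():
            got = [m.key for m in analysis.sentences[sidx].mutations]
            assert got == keys
    if "no_mention_of" in exp:
        for needle in exp["no_mention_of"]:
            assert all(
                needle not in m.raw
                for m in analysis.mutation_occurrences()
            )

    pair_set = {(p.mutation_key, p.disease) for p in analysis.pairs}
    if "pairs" in exp:
        for pair in exp["pairs"]:
            assert tuple(pair) in pair_set, (pair, pair_set)
    if "no_pair" in exp:
        for pair in exp["no_pair"]:
            assert tuple(pair) not in pair_set
    if "pair_diseases" in exp:
        diseases = {p.disease for p in analysis.pairs}
        for d in exp["pair_diseases"]:
            assert d in diseases
    if "provenance" in exp:
        prov = {(p.mutation_key, p.disease): p.provenance for p in analysis.pairs}
        for pair, want in exp["provenance"].items():
            assert prov[pair] == want
    if "fallback" in exp:
        from mutdx.disease_link import resolve_disease_fallback

        fb = resolve_disease_fallback(exp["fallback"]["sentence"], analysis)
        assert fb == (exp["fallback"]["disease"], exp["fallback"]["provenance"])
    if "referent" in exp:
        from mutdx.disease_link import NPContext

        sidx = exp["referent"]["sentence"]
        ctx = NPContext(analysis, sidx)
        found: list[str] = []
        for chunk in analysis.sentences[sidx].parsed.chunks:
            if chunk.kind == "NP":
                found.extend(k for k in ctx.referents(chunk) if k not in found)
        for key in exp["referent"]["keys"]:
            assert key in found

    if "gene_of" in exp:
        for key, gene in exp["gene_of"].items():
            assert analysis.gene_associations[key].gene == gene
    if "tier_of" in exp:
        for key, tier in exp["tier_of"].items():
            assert analysis.gene_associations[key].tier == tier
    if "pairing_genes" in exp:
        from mutdx.gene_link import find_pairings

        got = {p.gene for p in find_pairings(analysis)}
        for g in exp["pairing_genes"]:
            assert g in got

    if "allele_resolution" in exp:
        alleles = {
            a.raw: a for sa in analysis.sentences.values() for a in sa.alleles
        }
        for raw, key in exp["allele_resolution"].items():
            assert alleles[raw].resolved is not None
            assert alleles[raw].resolved.key == key
    if "genotype_resolution" in exp:
        genotypes = [
            g for sa in analysis.sentences.values() for g in sa.genotypes
        ]
        for raw, key in exp["genotype_resolution"].items():
            matching = [g for g in genotypes if g.raw == raw]
            assert matching, f"genotype {raw} not detected"
            assert all(
                g.resolved is not None and g.resolved.key == key
                for g in matching
            )

    if "outcomes" in exp:
        got = {(o.mutation_key, o.outcome): o for o in analysis.outcomes}
        for key, outcome, extra in exp["outcomes"]:
            assert (key, outcome) in got, (key, outcome, sorted(got))
            link = got[(key, outcome)]
            assert extra in (link.qualifier, link.drug)

    if "patients_in_sentence" in exp:
        from mutdx.zones import extract_cohort

        for sidx, n in exp["patients_in_sentence"].items():
            patients, _ = extract_cohort(analysis.sentences[sidx].text)
            assert patients == n

    if "base_nps" in exp:
        for sidx, nps in exp["base_nps"].items():
            got = [c.text for c in analysis.sentences[sidx].parsed.base_chunks
                   if c.kind == "NP"]
            for np in nps:
                assert np in got, (np, got)
    if "base_vgs" in exp:
        for sidx, vgs in exp["base_vgs"].items():
            got = [c.text for c in analysis.sentences[sidx].parsed.base_chunks
                   if c.kind == "VG"]
            assert got == vgs
    if "merged_np" in exp:
        for sidx, np in exp["merged_np"].items():
            got = [c.text for c in analysis.sentences[sidx].parsed.chunks
                   if c.kind == "NP"]
            assert np in got
    if "merged_vg" in exp:
        for sidx, vg in exp["merged_vg"].items():
            got = [c.text for c in analysis.sentences[sidx].parsed.chunks
                   if c.kind == "VG"]
            assert vg in got
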