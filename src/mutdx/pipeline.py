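"""End-to-end orchestration: document -> triplets + study metadata.

The Pipeline loads its resources once (gazetteers, pattern config, zone
cues) and processes Documents independently: shallow parse, mutation and
entity detection, allele/genotype resolution, gene association, zone
segmentation, mutation-disease pairing, outcome linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import mutations as mut
from .chunker import ParsedSentence, parse_sentence
from .disease_link import MutationDiseasePair, extract_pairs
from .entities import (
    DictionaryTagger,
    EntityMention,
    Gazetteer,
    filter_disease_acronyms,
    resolve_generic_diseases,
)
from .gene_link import GeneAssociation, associate_genes
from .ingest import Document
from .patterns import Pattern, load_patterns, parse_patterns
from .zones import (
    OutcomeLink,
    StudyMetadata,
    extract_study_metadata,
    link_outcomes,
    load_country_gazetteer,
    segment_zones,
)


def _data_path(name: str):
    return resources.files("mutdx.data").joinpath(name)


@dataclass
class SentenceAnalysis:
    index: int
    text: str
    parsed: ParsedSentence
    mutations: list[mut.MutationMention] = field(default_factory=list)
    alleles: list[mut.AlleleMention] = field(default_factory=list)
    genotypes: list[mut.GenotypeMention] = field(default_factory=list)
    entities: list[EntityMention] = field(default_factory=list)


@dataclass
class DocAnalysis:
    document: Document
    sentences: dict[int, SentenceAnalysis] = field(default_factory=dict)
    zones: list[str] = field(default_factory=list)
    metadata: StudyMetadata = field(default_factory=StudyMetadata)
    gene_associations: dict[str, GeneAssociation] = field(default_factory=dict)
    pairs: list[MutationDiseasePair] = field(default_factory=list)
    outcomes: list[OutcomeLink] = field(default_factory=list)
    sentence_types: dict[int, object] = field(default_factory=dict)

    def mutation_occurrences(self) -> list[mut.MutationMention]:
        return [m for sa in self.sentences.values() for m in sa.mutations]

    def mutation_sentence_map(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for sa in self.sentences.values():
            for m in sa.mutations:
                out.setdefault(m.key, set()).add(sa.index)
            for a in sa.alleles:
                if a.resolved:
                    out.setdefault(a.resolved.key, set()).add(sa.index)
            for g in sa.genotypes:
                if g.resolved:
                    out.setdefault(g.resolved.key, set()).add(sa.index)
        return out


class Pipeline:
    """Loads resources once; ``process`` analyzes one Document."""

    def __init__(
        self,
        gene_gazetteer: Gazetteer | str | Path | None = None,
        disease_gazetteer: Gazetteer | str | Path | None = None,
        country_gazetteer: Gazetteer | str | Path | None = None,
        patterns: list[Pattern] | str | Path | None = None,
        entity_tagger=None,
    ):
        self.genes = self._load_gaz(gene_gazetteer, "genes.tsv", "gene")
        self.diseases = self._load_gaz(disease_gazetteer, "diseases.tsv", "disease")
        if isinstance(country_gazetteer, Gazetteer):
            self.countries = country_gazetteer
        else:
            self.countries = load_country_gazetteer(country_gazetteer)
        if isinstance(patterns, list):
            self.patterns = patterns
        elif patterns is not None:
            self.patterns = load_patterns(patterns)
        else:
            self.patterns = parse_patterns(_data_path("patterns.txt").read_text())
        self.tagger = entity_tagger or DictionaryTagger(self.genes, self.diseases)

    @staticmethod
    def _load_gaz(arg, default_name: str, kind: str) -> Gazetteer:
        if isinstance(arg, Gazetteer):
            return arg
        if arg is not None:
            return Gazetteer.from_tsv(arg, kind)
        gaz = Gazetteer(kind)
        with _data_path(default_name).open() as fh:
            import csv

            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                gaz.add(row[0].strip(), row[1].strip() if len(row) > 1 else None)
        return gaz

    # ------------------------------------------------------------------
    def process(self, document: Document) -> DocAnalysis:
        analysis = DocAnalysis(document)

        # per-sentence: mutations, parse, entities
        all_mutations: list[mut.MutationMention] = []
        for sent in document.sentences:
            mentions = mut.detect_mutations(sent.text)
            alleles = mut.detect_alleles(sent.text)
            genotypes = mut.detect_genotypes(sent.text, mentions)
            for m in mentions:
                m.sentence_index = sent.index
            for a in alleles:
                a.sentence_index = sent.index
            for g in genotypes:
                g.sentence_index = sent.index
            protected = mut.protected_spans(sent.text)
            parsed = parse_sentence(sent.text, protected)
            analysis.sentences[sent.index] = SentenceAnalysis(
                sent.index, sent.text, parsed, mentions, alleles, genotypes
            )
            all_mutations.extend(mentions)

        # entity tagging + refinement
        mentions = self.tagger(document)
        mentions = filter_disease_acronyms(
            mentions, document.acronyms, self.genes, self.diseases
        )
        parsed_by_idx = {i: sa.parsed for i, sa in analysis.sentences.items()}
        mentions = resolve_generic_diseases(mentions, parsed_by_idx)
        for e in mentions:
            if e.sentence_index in analysis.sentences:
                analysis.sentences[e.sentence_index].entities.append(e)

        # allele / genotype resolution against the whole document
        for sa in analysis.sentences.values():
            for a in sa.alleles:
                mut.resolve_allele(a, all_mutations)
        all_genotypes = [g for sa in analysis.sentences.values() for g in sa.genotypes]
        mut.resolve_genotypes(all_genotypes, all_mutations)

        # an allele with no resolvable full mutation anywhere in the
        # abstract stands for the mutation itself (partial key, empty wild)
        for sa in analysis.sentences.values():
            for a in sa.alleles:
                if a.resolved is None:
                    sa.mutations.append(
                        mut.MutationMention(
                            "allele", "", a.position, a.mutant,
                            a.raw, a.start, a.end, sa.index,
                        )
                    )

        # zones, metadata, gene association, pairing, outcomes
        analysis.zones = segment_zones(document)
        analysis.metadata = extract_study_metadata(document, self.countries)
        analysis.gene_associations = associate_genes(analysis)
        analysis.pairs = extract_pairs(analysis, self.patterns)
        analysis.outcomes = link_outcomes(
            document, analysis.mutation_sentence_map()
        )
        return analysis
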