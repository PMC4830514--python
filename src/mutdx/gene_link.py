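"""Mutation-to-gene association.

Tiers, applied in order per normalized mutation key:

1. mutation and gene in the same merged NP (nearest gene after the
   mutation within the NP, else nearest before);
2. propagation of a tier-1 association to every other occurrence of the
   same key in the abstract;
3. the only gene mentioned anywhere in the abstract;
4. the gene of the closest gene-mutation pairing occurring previously in
   text (a pairing = gene + mutation-specific term such as "variant",
   "polymorphism", "SNP" in one merged NP).

Once assigned, an association is propagated to all occurrences of the key;
alleles and genotypes inherit the gene of their resolved mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .lexicon import PAIRING_TERMS

log = logging.getLogger(__name__)


@dataclass
class GeneMutationPairing:
    gene: str               # canonical gene
    term: str               # the mutation-specific term
    sentence_index: int
    offset: int             # char offset of the gene mention in its sentence


@dataclass
class GeneAssociation:
    mutation_key: str
    gene: str               # canonical; "" when no gene could be assigned
    tier: int               # 1..4; 0 when unassigned
    sentence_index: int     # evidence sentence


def find_pairings(analysis) -> list[GeneMutationPairing]:
    """Gene + mutation-specific-term co-occurrences per merged NP, in
    textual order; one pairing per (gene mention, term token)."""
    pairings: list[GeneMutationPairing] = []
    for sidx, sa in sorted(analysis.sentences.items()):
        genes = [e for e in sa.entities if e.kind == "gene"]
        if not genes:
            continue
        for chunk in sa.parsed.chunks:
            if chunk.kind != "NP":
                continue
            terms = [
                t for t in chunk.tokens if t.text.lower() in PAIRING_TERMS
            ]
            if not terms:
                continue
            in_np = [
                g for g in genes if chunk.start <= g.start and g.end <= chunk.end
            ]
            for g in in_np:
                for t in sorted(terms, key=lambda t: t.start):
                    pairings.append(
                        GeneMutationPairing(g.canonical, t.text, sidx, g.start)
                    )
    pairings.sort(key=lambda p: (p.sentence_index, p.offset))
    return pairings


def _tier1_gene(analysis, occ) -> str | None:
    """Gene in the same merged NP as the mutation occurrence: nearest gene
    mention after the mutation within the NP, else nearest before."""
    sa = analysis.sentences[occ.sentence_index]
    genes = [e for e in sa.entities if e.kind == "gene"]
    if not genes:
        return None
    for chunk in sa.parsed.chunks:
        if chunk.kind != "NP":
            continue
        if not (chunk.start <= occ.start and occ.end <= chunk.end):
            continue
        in_np = [g for g in genes if chunk.start <= g.start and g.end <= chunk.end]
        if not in_np:
            return None
        after = [g for g in in_np if g.start >= occ.end]
        if after:
            return min(after, key=lambda g: g.start - occ.end).canonical
        return min(in_np, key=lambda g: occ.start - g.end).canonical
    return None


def _closest_previous_pairing(pairings, occ) -> GeneMutationPairing | None:
    """Tier-4 candidate ranking: same-sentence pairings by character
    proximity (left of the mutation preferred); earlier sentences by
    sentence distance, then by position within the sentence ascending
    (the first pairing carries the sentence topic)."""
    same = [p for p in pairings if p.sentence_index == occ.sentence_index]
    if same:
        left = [p for p in same if p.offset <= occ.start]
        if left:
            return max(left, key=lambda p: p.offset)
        return min(same, key=lambda p: p.offset)
    earlier = [p for p in pairings if p.sentence_index < occ.sentence_index]
    if earlier:
        return min(
            earlier,
            key=lambda p: (occ.sentence_index - p.sentence_index, p.offset),
        )
    return None


def associate_genes(analysis) -> dict[str, GeneAssociation]:
    """One GeneAssociation per normalized mutation key, tiers 1-4 in order;
    a key with no assignable gene yields an empty-gene association."""
    occurrences = analysis.mutation_occurrences()  # list of mentions w/ keys
    by_key: dict[str, list] = {}
    for occ in occurrences:
        by_key.setdefault(occ.key, []).append(occ)
    all_genes = {
        e.canonical
        for sa in analysis.sentences.values()
        for e in sa.entities if e.kind == "gene"
    }
    pairings = find_pairings(analysis)
    out: dict[str, GeneAssociation] = {}
    for key, occs in by_key.items():
        occs.sort(key=lambda o: (o.sentence_index, o.start))
        # tier 1 (and 2 by propagation)
        tier1 = []
        for occ in occs:
            g = _tier1_gene(analysis, occ)
            if g:
                tier1.append((occ, g))
        if tier1:
            genes = {g for _, g in tier1}
            occ, gene = tier1[0]
            if len(genes) > 1:
                log.warning(
                    "conflicting same-NP genes for %s: %s; keeping earliest (%s)",
                    key, sorted(genes), gene,
                )
            out[key] = GeneAssociation(key, gene, 1, occ.sentence_index)
            continue
        # tier 3: only gene in the abstract
        if len(all_genes) == 1:
            out[key] = GeneAssociation(key, next(iter(all_genes)), 3,
                                       occs[0].sentence_index)
            continue
        # tier 4: closest previous gene-mutation pairing
        p = _closest_previous_pairing(pairings, occs[0])
        if p is not None:
            out[key] = GeneAssociation(key, p.gene, 4, occs[0].sentence_index)
            continue
        out[key] = GeneAssociation(key, "", 0, occs[0].sentence_index)
    return out
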