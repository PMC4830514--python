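"""Mutation-to-disease pairing via six sentence structures.

Types: Association and Comparison (pattern-based), Statistical (P/OR
value), Mutation Found (detect/identify/... with an NP<mutation> theme),
Title and Conclusion (position/zone based).  A sentence carries at most
one of {Association, Comparison, Statistical} — patterns are tried in that
order and a sentence matching an association pattern is never marked
Statistical even if it contains a P-value.  Mutation Found, Title and
Conclusion are evaluated independently and may co-occur.

When a covered sentence lacks an in-sentence disease, the central disease
is resolved from the rest of the abstract in the order Patient Context
sentence (only if it precedes the current sentence), title, conclusion
sentences, introduction sentences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .chunker import Chunk
from .lexicon import MUTATION_TERMS
from .patterns import MatchResult, Pattern, match_any

#: P-value / odds-ratio mention (Statistical sentence type)
STAT_RE = re.compile(
    r"\b[Pp]\s*(?:value\s*)?[=<>≤≥]\s*\.?\d"
    r"|\bORs?\s*[=:]\s*\.?\d"
    r"|odds ratios?\s*(?:\(OR\))?\s*(?:of|[=:])\s*\.?\d",
)


@dataclass
class SentenceTypeResult:
    sentence_index: int
    primary: str | None = None      # Association | Comparison | Statistical
    match: MatchResult | None = None
    mutation_found: MatchResult | None = None
    is_title: bool = False
    is_conclusion: bool = False


@dataclass
class MutationDiseasePair:
    mutation_key: str
    disease: str                    # canonical disease
    sentence_index: int
    sentence_type: str              # Association | Comparison | Statistical |
                                    # MutationFound | Title | Conclusion
    provenance: str                 # in-sentence | PC | title | conclusion | introduction


class NPContext:
    """NP<type> tests for the pattern matcher, bound to one sentence."""

    def __init__(self, analysis, sentence_index: int):
        self.analysis = analysis
        self.sidx = sentence_index
        self.sa = analysis.sentences[sentence_index]

    def _span_keys(self, chunk: Chunk) -> list[str]:
        keys = []
        for m in self.sa.mutations:
            if chunk.start <= m.start and m.end <= chunk.end:
                keys.append(m.key)
        for a in self.sa.alleles:
            if a.resolved and chunk.start <= a.start and a.end <= chunk.end:
                keys.append(a.resolved.key)
        for g in self.sa.genotypes:
            if g.resolved and chunk.start <= g.start and g.end <= chunk.end:
                keys.append(g.resolved.key)
        seen, out = set(), []
        for k in keys:
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def _has_generic_head(self, chunk: Chunk) -> bool:
        for base in chunk.base_chunks:
            head = base.tokens[-1].text.lower()
            if head in MUTATION_TERMS:
                return True
        return False

    def np_is_mutation(self, chunk: Chunk) -> bool:
        return bool(self._span_keys(chunk)) or self._has_generic_head(chunk)

    def np_is_disease(self, chunk: Chunk) -> bool:
        return bool(self.diseases_in(chunk))

    def diseases_in(self, chunk: Chunk) -> list[str]:
        out = []
        for e in self.sa.entities:
            if e.kind == "disease" and chunk.start <= e.start and e.end <= chunk.end:
                if e.canonical not in out:
                    out.append(e.canonical)
        return out

    def referents(self, chunk: Chunk) -> list[str]:
        """Mutation keys an NP<mutation> phrase refers to: specific
        mentions inside the NP, else — for a generic phrase naming a gene —
        the mutation(s) of the closest previous sentence already associated
        with that gene."""
        keys = self._span_keys(chunk)
        if keys:
            return keys
        if not self._has_generic_head(chunk):
            return []
        genes = [
            e.canonical for e in self.sa.entities
            if e.kind == "gene" and chunk.start <= e.start and e.end <= chunk.end
        ]
        if not genes:
            return []
        assoc = self.analysis.gene_associations
        best: tuple[int, list[str]] | None = None
        for prev_sidx in range(self.sidx - 1, -1, -1):
            prev = self.analysis.sentences.get(prev_sidx)
            if prev is None:
                continue
            found = []
            for m in prev.mutations:
                ga = assoc.get(m.key)
                if ga and ga.gene in genes and m.key not in found:
                    found.append(m.key)
            if found:
                return found
        return []


def np_is_mutation(chunk: Chunk, analysis, sentence_index: int) -> tuple[bool, list[str]]:
    """Module-level convenience: (is-mutation-NP, referent keys)."""
    ctx = NPContext(analysis, sentence_index)
    return ctx.np_is_mutation(chunk), ctx.referents(chunk)


def classify_sentence(
    analysis, sentence_index: int, patterns: list[Pattern]
) -> SentenceTypeResult:
    """Assign sentence-structure types: Association patterns first, then
    Comparison, then the Statistical P/OR test; Mutation Found evaluated
    independently; Title/Conclusion flagged by position and zone."""
    ctx = NPContext(analysis, sentence_index)
    sa = analysis.sentences[sentence_index]
    res = SentenceTypeResult(sentence_index)
    m = match_any(patterns, sa.parsed, ctx, category="association")
    if m is not None:
        res.primary, res.match = "Association", m
    else:
        m = match_any(patterns, sa.parsed, ctx, category="comparison")
        if m is not None:
            res.primary, res.match = "Comparison", m
        elif STAT_RE.search(sa.text):
            res.primary = "Statistical"
    res.mutation_found = match_any(patterns, sa.parsed, ctx, category="mutation_found")
    res.is_title = sentence_index == 0
    res.is_conclusion = (
        analysis.zones[sentence_index] == "Conclusion"
        if sentence_index < len(analysis.zones) else False
    )
    return res


_FALLBACK_ORDER = ("PC", "title", "conclusion", "introduction")


def resolve_disease_fallback(
    sentence_index: int, analysis
) -> tuple[str, str] | None:
    """(disease, provenance) for a sentence lacking an in-sentence disease,
    scanning Patient Context (only if it precedes this sentence), title,
    conclusion sentences, introduction sentences; None if exhausted."""

    def first_disease(sidx: int) -> str | None:
        sa = analysis.sentences.get(sidx)
        if sa is None:
            return None
        for e in sorted(sa.entities, key=lambda e: e.start):
            if e.kind == "disease":
                return e.canonical
        return None

    pc = analysis.metadata.pc_sentence_index
    if pc is not None and pc < sentence_index:
        d = first_disease(pc)
        if d:
            return d, "PC"
    d = first_disease(0)
    if d:
        return d, "title"
    for sidx, zone in enumerate(analysis.zones):
        if zone == "Conclusion":
            d = first_disease(sidx)
            if d:
                return d, "conclusion"
    for sidx, zone in enumerate(analysis.zones):
        if zone == "Introduction":
            d = first_disease(sidx)
            if d:
                return d, "introduction"
    return None


def _sentence_keys(analysis, sidx: int) -> list[str]:
    sa = analysis.sentences[sidx]
    keys = [m.key for m in sa.mutations]
    keys += [a.resolved.key for a in sa.alleles if a.resolved]
    keys += [g.resolved.key for g in sa.genotypes if g.resolved]
    seen, out = set(), []
    for k in keys:
        if k not in seen:
            seen.add(k)
            out.append(k)
    return out


def _sentence_diseases(analysis, sidx: int) -> list[str]:
    out = []
    for e in analysis.sentences[sidx].entities:
        if e.kind == "disease" and e.canonical not in out:
            out.append(e.canonical)
    return out


def extract_pairs(analysis, patterns: list[Pattern]) -> list[MutationDiseasePair]:
    """Run the six sentence-type extractors over the whole document; one
    pair per (mutation key, disease) with its first supporting evidence."""
    pairs: list[MutationDiseasePair] = []

    def add(key: str, disease: str, sidx: int, stype: str, prov: str) -> None:
        pairs.append(MutationDiseasePair(key, disease, sidx, stype, prov))

    for sidx in sorted(analysis.sentences):
        ctx = NPContext(analysis, sidx)
        res = classify_sentence(analysis, sidx, patterns)
        analysis.sentence_types[sidx] = res

        if res.primary in ("Association", "Comparison") and res.match:
            bound = res.match.bound_nps
            keys: list[str] = []
            for np in bound:
                for k in ctx.referents(np):
                    if k not in keys:
                        keys.append(k)
            diseases: list[str] = []
            for np in bound:
                for d in ctx.diseases_in(np):
                    if d not in diseases:
                        diseases.append(d)
            prov = "in-sentence"
            if keys and not diseases:
                fb = resolve_disease_fallback(sidx, analysis)
                if fb:
                    diseases, prov = [fb[0]], fb[1]
            for k in keys:
                for d in diseases:
                    add(k, d, sidx, res.primary, prov)

        elif res.primary == "Statistical":
            # the mutation must be mentioned in the statistical sentence
            keys = _sentence_keys(analysis, sidx)
            if not keys:
                for chunk in analysis.sentences[sidx].parsed.chunks:
                    if chunk.kind == "NP" and ctx._has_generic_head(chunk):
                        keys.extend(
                            k for k in ctx.referents(chunk) if k not in keys
                        )
            if keys:
                diseases = _sentence_diseases(analysis, sidx)
                prov = "in-sentence"
                if not diseases:
                    fb = resolve_disease_fallback(sidx, analysis)
                    if fb:
                        diseases, prov = [fb[0]], fb[1]
                for k in keys:
                    for d in diseases:
                        add(k, d, sidx, "Statistical", prov)

        if res.mutation_found:
            np = next(
                (b for el, b in res.mutation_found.bindings
                 if el.kind == "np" and el.constraint == "type"),
                None,
            )
            keys = ctx.referents(np) if np is not None else []
            if np is not None and not keys:
                # count-only phrase ("Three different mutations"): the
                # actual mutations are listed in the next one or two sentences
                for look in (sidx + 1, sidx + 2):
                    if look in analysis.sentences:
                        keys = _sentence_keys(analysis, look)
                        if keys:
                            break
            diseases = _sentence_diseases(analysis, sidx)
            prov = "in-sentence"
            if keys and not diseases:
                fb = resolve_disease_fallback(sidx, analysis)
                if fb:
                    diseases, prov = [fb[0]], fb[1]
            for k in keys:
                for d in diseases:
                    add(k, d, sidx, "MutationFound", prov)

        if res.is_title or res.is_conclusion:
            keys = _sentence_keys(analysis, sidx)
            diseases = _sentence_diseases(analysis, sidx)
            stype = "Title" if res.is_title else "Conclusion"
            for k in keys:
                for d in diseases:
                    add(k, d, sidx, stype, "in-sentence")

    # one pair per (key, disease, evidence sentence); cross-sentence
    # duplicates are kept so triplet assembly can rank their zones
    seen = set()
    out = []
    for p in pairs:
        sig = (p.mutation_key, p.disease, p.sentence_index)
        if sig in seen:
            continue
        seen.add(sig)
        out.append(p)
    return out
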