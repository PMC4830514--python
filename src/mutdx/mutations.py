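"""Mutation mention detection, conjunction expansion, normalization, and
allele/genotype resolution.

Detection is two-layered:

* ``detect_format_mutations`` — regular expressions over HGVS-style surface
  formats: protein substitutions (1-letter, 3-letter, full residue names;
  separators ``>``, ``-->``, ``—>``, ``——``, ``→``, ``/`` and the word
  ``to``), DNA substitutions (including intronic ``1066-6`` / ``IVS19+2``
  and negative ``-79`` positions), insertions, deletions, terminations and
  dbSNP ``rs``/``ss`` identifiers.
* ``detect_nl_mutations`` — natural-language descriptions anchored by words
  like *codon*, *position*, *residue*, *amino acid*, *nucleotide*
  ("A--> C transversion in codon 135"), including multi-position lists and
  termination phrases.

All mentions normalize to a canonical key (``W-pos-M`` for substitutions,
``{pos}ins{SEQ}`` / ``{pos}del{SEQ}`` for indels, the lowercased identifier
for dbSNP entries) so that surface variants of one variant compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .lexicon import (
    AA1,
    AA3_TO_1,
    AA_FULL_TO_1,
    BASE_FULL_TO_1,
    BASES,
    to_single_letter,
)


class NormalizationError(ValueError):
    """Raised when a mention carries a residue symbol outside the known
    amino-acid/base alphabet; carries the offending raw string."""

    def __init__(self, raw: str, symbol: str):
        super().__init__(f"cannot normalize {raw!r}: unknown symbol {symbol!r}")
        self.raw = raw
        self.symbol = symbol


@dataclass
class MutationMention:
    kind: str           # substitution-protein | substitution-dna | insertion |
                        # deletion | dbsnp | nl-described | termination
    wild: str           # residue/base symbol or ""
    position: str       # opaque position token ("327", "1066-6", "IVS9-5", "-79")
    mutant: str         # residue/base symbol or ""
    raw: str            # verbatim substring of the sentence
    start: int          # char offsets within the sentence
    end: int
    sentence_index: int = -1
    silent: bool = False        # wild == mutant after normalization
    from_conjunction: bool = False

    @property
    def key(self) -> str:
        return normalize(self)


@dataclass
class AlleleMention:
    raw: str
    position: str
    mutant: str
    start: int
    end: int
    sentence_index: int = -1
    resolved: MutationMention | None = None


@dataclass
class GenotypeMention:
    raw: str
    symbols: tuple[str, str]
    start: int
    end: int
    sentence_index: int = -1
    resolved: MutationMention | None = None


# ---------------------------------------------------------------------------
# Regex building blocks

_AA3 = "|".join(AA3_TO_1)
_AAFULL = "|".join(sorted(AA_FULL_TO_1, key=len, reverse=True))
_BASEFULL = "|".join(BASE_FULL_TO_1)
_RES = rf"(?:{_AA3}|{_AAFULL}|{_BASEFULL})"

# separator glyphs between wild and mutant symbols; single hyphens are NOT
# separators here (they occur inside positions), the word "to" is
_SEP = r"(?:-{2,3}\s?>|[—–]+\s?>|→|>|/)"
_SEPSP = rf"(?:\s*{_SEP}\s*|\s*[—–]{{1,3}}\s*|\s+to\s+)"

_POS = r"[+-]?\d+(?:[+-]\d+)?"
_IVS = r"IVS\s?\d+(?:\s?[+-]\s?\d+)?"

_PATTERNS: list[tuple[str, re.Pattern]] = []


def _add(kind: str, pattern: str, flags: int = 0) -> None:
    _PATTERNS.append((kind, re.compile(pattern, flags)))


# dbSNP / ssSNP identifiers
_add("dbsnp", r"\b(?P<id>(?:rs|ss)\d{3,})\b")

# protein substitution, symbolic or spelled-out residues, wild-first:
# Ala282Val, Asp 327—>Asn, Phe153——Ala, Ala16 >Cys, Ser 1140Gly
_add(
    "substitution-protein",
    rf"\b(?P<w>{_RES})\s?(?P<p>\d+)\s?(?:{_SEPSP})?\s?(?P<m>{_RES})\b",
)

# termination: S2834 ter, R123X, Gln39stop
_add(
    "termination",
    rf"\b(?P<w>[A-Z]|{_AA3})(?P<p>\d+)\s?(?P<m>[Tt]er\b|X\b|\*|[Ss]top\b)",
)

# position-first substitution with separator: 5557G>A, 1066-6T> G, -79C/T,
# +49G/A, IVS1 -27G> A, 5622C > T
_add(
    "sub-posfirst",
    rf"(?P<ivs>{_IVS}\s?)?(?<![\w+-])(?P<p>{_POS})\s?(?P<w>[A-Z])\s?{_SEP}\s?(?P<m>[A-Z])\b",
)

# wild-first 1-letter, no separator: T877A, C-2123G, A3537G, R1699W
_add("sub-nosep", r"\b(?P<w>[A-Z])(?P<p>-?\d+)(?P<m>[A-Z])\b")

# insertions / deletions: 5382insC, IVS9-5insT, 6886delGAAAA, 982del4
_add(
    "insertion",
    rf"\b(?P<p>{_IVS}|{_POS})\s?ins\s?(?P<seq>[ACGT]+\b|\d+)",
)
_add(
    "deletion",
    rf"\b(?P<p>{_IVS}|{_POS})\s?del\s?(?P<seq>[ACGT]+\b|\d+)",
)

# natural-language substitution with position anchor:
# "A--> C transversion in codon 135", "T to C transition at positions 409 and 412",
# "guanine-adenine point mutation at nucleotide 2185",
# "Arg to Trp or Gln at codon 194"
_NLSYM = rf"(?:{_RES}|[ACGT])"
_NL_RE = re.compile(
    rf"(?P<w>{_NLSYM})\s?(?:{_SEPSP}|-)\s?(?P<m>{_NLSYM})"
    rf"(?P<mlist>(?:\s*,\s*{_NLSYM})*(?:\s*,?\s*(?:and|or)\s+{_NLSYM})?)"
    rf"\s+(?:[\w-]+\s+){{0,4}}?(?:in|at)\s+"
    rf"(?:codons?|positions?|residues?|amino\s?acids?|nucleotides?)\s+"
    rf"(?P<plist>\d+(?:\s*(?:,|and|or)\s*\d+)*)"
)

_NL_TERM_RE = re.compile(r"\btermination\s+at\s+codon\s+(?P<p>\d+)")

_NUM_RE = re.compile(r"\d+")
_SYM_RE = re.compile(rf"{_RES}|[ACGT]\b")


def _norm_position(pos: str) -> str:
    return re.sub(r"\s+", "", pos)


def _classify_sub(wild: str, mutant: str) -> str:
    w, m = to_single_letter(wild), to_single_letter(mutant)
    if w in BASES and m in BASES:
        return "substitution-dna"
    return "substitution-protein"


def detect_format_mutations(text: str) -> list[MutationMention]:
    """Detect format-based (HGVS-style) mutation mentions in one sentence.

    Overlapping matches are resolved leftmost-longest, so "5557G>A" yields a
    single position-first substitution rather than fragments.
    """
    candidates: list[MutationMention] = []
    for kind, rx in _PATTERNS:
        for m in rx.finditer(text):
            g = m.groupdict()
            if kind == "dbsnp":
                mm = MutationMention("dbsnp", "", "", "", m.group(0), m.start(), m.end())
            elif kind in ("insertion", "deletion"):
                mm = MutationMention(
                    kind, "", _norm_position(g["p"]), g["seq"].upper(),
                    m.group(0), m.start(), m.end(),
                )
            elif kind == "termination":
                mm = MutationMention(
                    "termination", g["w"], g["p"], "X", m.group(0), m.start(), m.end(),
                )
            else:
                wild, mut = g["w"], g["m"]
                if kind == "sub-posfirst":
                    pos = ((g.get("ivs") or "") + g["p"])
                else:
                    pos = g["p"]
                if to_single_letter(wild) is None or to_single_letter(mut) is None:
                    continue
                mm = MutationMention(
                    _classify_sub(wild, mut), wild, _norm_position(pos), mut,
                    m.group(0), m.start(), m.end(),
                )
            candidates.append(mm)
    return _resolve_overlaps(candidates)


def _resolve_overlaps(mentions: list[MutationMention]) -> list[MutationMention]:
    mentions = sorted(mentions, key=lambda m: (m.start, -(m.end - m.start)))
    chosen: list[MutationMention] = []
    for m in mentions:
        if any(m.start < c.end and c.start < m.end for c in chosen):
            continue
        chosen.append(m)
    for m in chosen:
        if m.kind.startswith("substitution"):
            w, mt = to_single_letter(m.wild), to_single_letter(m.mutant)
            m.silent = w is not None and w == mt
    return chosen


def _split_symbols(listing: str) -> list[str]:
    return _SYM_RE.findall(listing)


def detect_nl_mutations(text: str) -> list[MutationMention]:
    """Detect mutations described in running text via a wild/mutant symbol
    pair plus a position anchor word; one mention per listed position and
    per listed mutant symbol."""
    out: list[MutationMention] = []
    for m in _NL_RE.finditer(text):
        positions = _NUM_RE.findall(m.group("plist"))
        mutants = [m.group("m")] + _split_symbols(m.group("mlist") or "")
        for pos in positions:
            for mut in mutants:
                out.append(
                    MutationMention(
                        "nl-described", m.group("w"), pos, mut,
                        m.group(0), m.start(), m.end(),
                    )
                )
    for m in _NL_TERM_RE.finditer(text):
        if any(o.start <= m.start() < o.end for o in out):
            continue
        out.append(
            MutationMention(
                "termination", "", m.group("p"), "X", m.group(0), m.start(), m.end(),
            )
        )
    return out


# conjunction tail after a substitution: "Ala16 >Cys, Thr, Met, Arg, His and Tyr"
_CONJ_RE = re.compile(
    rf"^(?P<tail>(?:\s*,\s*{_RES}\b)*(?:\s*,?\s*(?:and|or)\s+{_RES}\b)?)"
)


def expand_conjunctions(text: str, seed: MutationMention) -> list[MutationMention]:
    """Expand a trailing conjunction list of mutant symbols after a detected
    substitution into one mention per conjunct (all sharing wild/position)."""
    if not seed.kind.startswith("substitution") and seed.kind != "nl-described":
        return [seed]
    m = _CONJ_RE.match(text[seed.end:])
    if not m or not m.group("tail").strip():
        return [seed]
    out = [seed]
    for sym in re.finditer(rf"{_RES}\b", m.group("tail")):
        end = seed.end + sym.end()
        out.append(
            replace(
                seed,
                mutant=sym.group(0),
                raw=text[seed.start:end],
                end=end,
                from_conjunction=True,
            )
        )
    return out


_PAREN_RE = re.compile(r"\(")


def detect_mutations(text: str) -> list[MutationMention]:
    """All mutation mentions of one sentence: format + natural-language
    detection, conjunction expansion, overlap resolution.

    A mention inside a parenthetical that opens immediately after another
    mention is folded into the preceding mention as an annotation (e.g.
    "A3537G (Ser 1140Gly)" is one mutation, and the listing
    "9474insA (exon 24, termination at codon 3110)" yields one mention).
    """
    fmt = detect_format_mutations(text)
    expanded: list[MutationMention] = []
    for m in fmt:
        expanded.extend(expand_conjunctions(text, m))
    nl = [
        m for m in detect_nl_mutations(text)
        if not any(m.start < f.end and f.start < m.end for f in expanded)
    ]
    mentions = sorted(expanded + nl, key=lambda m: (m.start, m.end))

    # parenthetical-annotation suppression
    suppressed: list[tuple[int, int]] = []
    for m in mentions:
        rest = text[m.end:]
        lead = rest[:2]
        if lead.strip().startswith("("):
            op = m.end + rest.index("(")
            depth, close = 0, None
            for i in range(op, len(text)):
                if text[i] == "(":
                    depth += 1
                elif text[i] == ")":
                    depth -= 1
                    if depth == 0:
                        close = i
                        break
            if close is not None:
                suppressed.append((op, close + 1))
    keep = [
        m for m in mentions
        if not any(s <= m.start and m.end <= e for s, e in suppressed)
    ]
    return keep


def normalize(mention: MutationMention) -> str:
    """Canonical key for a mention: residues folded to single-letter code,
    ``W-pos-M`` for substitutions/terminations, ``{pos}ins{SEQ}`` /
    ``{pos}del{SEQ}`` for indels, the identifier for dbSNP. Idempotent."""
    if mention.kind == "dbsnp":
        return mention.raw.lower() if not mention.wild else mention.raw.lower()
    if mention.kind == "insertion":
        return f"{mention.position}ins{mention.mutant.upper()}"
    if mention.kind == "deletion":
        return f"{mention.position}del{mention.mutant.upper()}"
    wild = ""
    if mention.wild:
        wild = to_single_letter(mention.wild) or ""
        if not wild:
            raise NormalizationError(mention.raw, mention.wild)
    mut = ""
    if mention.mutant:
        mut = to_single_letter(mention.mutant) or ""
        if not mut:
            raise NormalizationError(mention.raw, mention.mutant)
    pos = _norm_position(mention.position)
    return f"{wild}-{pos}-{mut}"


# ---------------------------------------------------------------------------
# Alleles and genotypes

_ALLELE_RE = re.compile(
    rf"\b(?P<p>\d+)\s?(?P<m>{_AA3}|[A-Z])\s+(?=alleles?\b)"
)

_GENOTYPE_RE = re.compile(r"\b(?P<g>[ACGT]{2})\b")
_GENO_CONTEXT_RE = re.compile(
    r"\bgenotypes?\b|\balleles?\b|\bcarriers?\b|\b[ACGT]{2}\s*[+/]\s*[ACGT]{2}\b",
    re.I,
)


def detect_alleles(text: str) -> list[AlleleMention]:
    """Partial variant references of the form "194Trp allele"."""
    out = []
    for m in _ALLELE_RE.finditer(text):
        out.append(
            AlleleMention(
                raw=m.group(0).strip(),
                position=m.group("p"),
                mutant=m.group("m"),
                start=m.start(),
                end=m.start() + len(m.group(0).rstrip()),
            )
        )
    return out


def resolve_allele(
    allele: AlleleMention, mutations: list[MutationMention]
) -> AlleleMention:
    """Bind an allele to the document mutation agreeing on position and
    mutant-type; among several candidates the closest preceding one wins."""
    want = to_single_letter(allele.mutant)
    cands = [
        m for m in mutations
        if _norm_position(m.position) == allele.position
        and to_single_letter(m.mutant) == want
    ]
    if not cands:
        return allele
    def distance(m: MutationMention) -> tuple:
        before = (m.sentence_index, m.start) <= (allele.sentence_index, allele.start)
        return (not before, abs(m.sentence_index - allele.sentence_index),
                abs(m.start - allele.start))
    allele.resolved = min(cands, key=distance)
    return allele


def detect_genotypes(text: str, mutations: list[MutationMention] | None = None) -> list[GenotypeMention]:
    """Two-letter nucleotide pairs (AG, GG, ...) in a genotype context:
    the sentence must mention genotype/allele/carrier or use a +/ grouping."""
    if not _GENO_CONTEXT_RE.search(text):
        return []
    mutation_spans = [(m.start, m.end) for m in (mutations or [])]
    out = []
    for m in _GENOTYPE_RE.finditer(text):
        if any(s <= m.start() < e for s, e in mutation_spans):
            continue
        g = m.group("g")
        out.append(GenotypeMention(g, (g[0], g[1]), m.start(), m.end()))
    return out


def resolve_genotypes(
    genotypes: list[GenotypeMention], mutations: list[MutationMention]
) -> list[GenotypeMention]:
    """Bind genotypes to the nearest DNA mutation whose wild/mutant pair
    matches the genotype nucleotides; homozygous genotypes co-listed with a
    resolved heterozygous one inherit its binding."""
    nuc = [
        m for m in mutations
        if m.kind in ("substitution-dna", "nl-described")
        and to_single_letter(m.wild) in BASES and to_single_letter(m.mutant) in BASES
    ]

    def nearest(g: GenotypeMention, cands: list[MutationMention]):
        return min(
            cands,
            key=lambda m: (abs(m.sentence_index - g.sentence_index), abs(m.start - g.start)),
            default=None,
        )

    for g in genotypes:
        pair = {g.symbols[0], g.symbols[1]}
        exact = [m for m in nuc if {to_single_letter(m.wild), to_single_letter(m.mutant)} == pair]
        if exact:
            g.resolved = nearest(g, exact)
    for g in genotypes:  # homozygous via co-listed sibling
        if g.resolved is not None or g.symbols[0] != g.symbols[1]:
            continue
        sym = g.symbols[0]
        for sib in genotypes:
            if sib.resolved is not None and sib.sentence_index == g.sentence_index:
                wm = {to_single_letter(sib.resolved.wild), to_single_letter(sib.resolved.mutant)}
                if sym in wm:
                    g.resolved = sib.resolved
                    break
    for g in genotypes:  # last resort: symbol subset of the only candidate set
        if g.resolved is None:
            subset = [
                m for m in nuc
                if set(g.symbols) <= {to_single_letter(m.wild), to_single_letter(m.mutant)}
            ]
            if subset:
                g.resolved = nearest(g, subset)
    return genotypes


def protected_spans(text: str) -> list[tuple[int, int]]:
    """Character spans the tokenizer must keep as single tokens so chunking
    never splits a mutation or allele mention."""
    spans = [(m.start, m.end) for m in detect_mutations(text)]
    spans += [(a.start, a.end) for a in detect_alleles(text)]
    spans.sort()
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged
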