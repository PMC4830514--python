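"""Lexico-syntactic pattern language over the chunk stream.

A pattern is a sequence of elements, each a literal word, a comma, an NP or
a VG.  NPs can be constrained: ``NP{head: lexeme}``, ``NP{contains:
lexeme}``, ``NP<mutation>``, ``NP<disease>``; VGs by voice and head:
``VG_active{head: lexeme}`` / ``VG_passive{head: lexeme}``.  Word
alternation (``to/with``) expands at parse time into pattern variants.
Lexeme constraints cover inflectional/derivational variants
(associate/associated/association) via the suffix-family table in
:mod:`mutdx.lexicon`.

Matching walks the sentence's merged chunks and bare tokens.  An NP
element may consume a whole merged NP or any contiguous run of its
constituents (so a merged NP can be split to satisfy consecutive
elements, and a run of constituents re-forms a smaller merged NP).  The
first (leftmost) complete match wins; within a start position the matcher
is greedy-longest with backtracking.

Config file syntax: ``[category]`` section headers, ``trigger: word``
declarations, one pattern per line, ``#`` comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .chunker import Chunk, ParsedSentence, Token, _make_merged, head_words, voice
from .lexicon import matches_lexeme


class PatternSyntaxError(ValueError):
    def __init__(self, line_no: int, line: str, reason: str):
        super().__init__(f"line {line_no}: {reason}: {line!r}")
        self.line_no = line_no


@dataclass(frozen=True)
class Element:
    kind: str                   # "word" | "np" | "vg"
    words: tuple[str, ...] = ()     # literal alternatives (word elements)
    constraint: str | None = None   # "head" | "contains" | "type" | None
    values: tuple[str, ...] = ()    # lexeme alternatives or type name
    voice: str | None = None        # VG voice requirement
    slot: str | None = None         # NP1 / NP2 ... label


@dataclass
class Pattern:
    pattern_id: str
    category: str               # association | comparison | mutation_found | ...
    trigger: str
    elements: tuple[Element, ...]
    source: str = ""

    def __repr__(self):
        return f"Pattern({self.pattern_id}: {self.source})"


_ELEMENT_RE = re.compile(
    r"NP(?P<slot>\d+)?"
    r"(?:<(?P<type>\w+)>|\{(?P<npcon>head|contains):\s*(?P<npval>[^}]+)\})?"
    r"|VG(?:_(?P<voice>active|passive))?"
    r"(?:\{head:\s*(?P<vgval>[^}]+)\})?"
    r"|(?P<comma>,)"
    r"|(?P<word>[\w/'-]+)"
)


def _parse_line(line: str, line_no: int) -> list[list[Element]]:
    """Parse one pattern line; alternation expands into variants."""
    variants: list[list[Element]] = [[]]
    pos = 0
    while pos < len(line):
        if line[pos].isspace():
            pos += 1
            continue
        m = _ELEMENT_RE.match(line, pos)
        if not m:
            raise PatternSyntaxError(line_no, line, f"cannot parse at col {pos}")
        pos = m.end()
        token = m.group(0)
        if token.startswith("NP"):
            slot = f"NP{m.group('slot')}" if m.group("slot") else None
            if m.group("type"):
                el_vars = [Element("np", constraint="type",
                                   values=(m.group("type").lower(),), slot=slot)]
            elif m.group("npcon"):
                vals = tuple(v.strip().lower() for v in m.group("npval").split("/"))
                if m.group("npcon") == "head":
                    el_vars = [Element("np", constraint="head", values=(v,), slot=slot)
                               for v in vals]
                else:
                    el_vars = [Element("np", constraint="contains", values=vals, slot=slot)]
            else:
                el_vars = [Element("np", slot=slot)]
        elif token.startswith("VG"):
            vals = ()
            if m.group("vgval"):
                vals = tuple(v.strip().lower() for v in m.group("vgval").split("/"))
            el_vars = [Element("vg", constraint="head" if vals else None,
                               values=(v,), voice=m.group("voice"))
                       for v in vals] or [Element("vg", voice=m.group("voice"))]
        elif m.group("comma"):
            el_vars = [Element("word", words=(",",))]
        else:
            # word alternation ("to/with") expands into pattern variants
            alts = tuple(w.lower() for w in token.split("/") if w)
            el_vars = [Element("word", words=(w,)) for w in alts]
        variants = [v + [e] for v in variants for e in el_vars]
    return [v for v in variants if v]


def parse_patterns(text: str) -> list[Pattern]:
    """Parse a pattern config; returns one Pattern per expanded variant."""
    patterns: list[Pattern] = []
    category = "association"
    trigger = ""
    counter = 0
    for line_no, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sec = re.match(r"^\[(\w+)\]$", line)
        if sec:
            category = sec.group(1)
            continue
        trg = re.match(r"^trigger:\s*(\S+)$", line)
        if trg:
            trigger = trg.group(1)
            continue
        for variant in _parse_line(line, line_no):
            counter += 1
            patterns.append(
                Pattern(f"{category}-{counter}", category, trigger,
                        tuple(variant), source=line)
            )
    return patterns


def load_patterns(path: str | Path) -> list[Pattern]:
    return parse_patterns(Path(path).read_text())


# ---------------------------------------------------------------------------
# Matching

#: bare punctuation tolerated between pattern elements (appositive commas,
#: parenthetical asides); an explicit "," element still matches one directly
_SKIPPABLE = {",", ";", ":", "(", ")"}


@dataclass
class _Atom:
    kind: str               # "np" | "vg" | "word"
    chunk: Chunk | None
    token: Token | None
    parent: int             # id of the top-level stream item


@dataclass
class MatchResult:
    pattern: Pattern
    bindings: list[tuple[Element, Chunk | Token]]

    @property
    def bound_nps(self) -> list[Chunk]:
        return [b for el, b in self.bindings if el.kind == "np"]

    def slot(self, name: str) -> Chunk | None:
        for el, b in self.bindings:
            if el.slot == name:
                return b
        return None


def _atoms(parsed: ParsedSentence) -> list[_Atom]:
    atoms: list[_Atom] = []
    for top_id, item in enumerate(parsed.stream()):
        if isinstance(item, Chunk):
            if not item.constituents:
                atoms.append(_Atom(item.kind.lower(), item, None, top_id))
            else:
                parts = sorted(
                    [("c", c) for c in item.constituents]
                    + [("t", t) for t in item.connectors],
                    key=lambda p: p[1].start,
                )
                for tag, part in parts:
                    if tag == "c":
                        atoms.append(_Atom(item.kind.lower(), part, None, top_id))
                    else:
                        atoms.append(_Atom("word", None, part, top_id))
        else:
            atoms.append(_Atom("word", None, item, top_id))
    return atoms


def _np_run_chunk(run: list[_Atom]) -> Chunk:
    chunks = [a.chunk for a in run if a.chunk is not None]
    connectors = [a.token for a in run if a.token is not None]
    if len(chunks) == 1 and not connectors:
        return chunks[0]
    return _make_merged("NP", chunks, connectors)


def _np_satisfies(chunk: Chunk, el: Element, context) -> bool:
    if el.constraint is None:
        return True
    if el.constraint == "head":
        return any(
            matches_lexeme(h.text, v) for h in head_words(chunk) for v in el.values
        )
    if el.constraint == "contains":
        return any(
            matches_lexeme(t.text, v)
            for t in chunk.tokens for v in el.values
        )
    if el.constraint == "type":
        typ = el.values[0]
        if context is None:
            return False
        if typ == "mutation":
            return context.np_is_mutation(chunk)
        if typ == "disease":
            return context.np_is_disease(chunk)
        return False
    return False


def _vg_satisfies(chunk: Chunk, el: Element) -> bool:
    if el.voice and voice(chunk) != el.voice:
        return False
    if el.constraint == "head":
        head = head_words(chunk)[0]
        return any(matches_lexeme(head.text, v) for v in el.values)
    return True


def match_pattern(
    pattern: Pattern, parsed: ParsedSentence, context=None
) -> MatchResult | None:
    """Leftmost complete match of a pattern against a parsed sentence;
    None if the sentence does not contain a matching chunk subsequence."""
    atoms = _atoms(parsed)
    n = len(atoms)

    def try_match(ai: int, ei: int, bindings: list) -> list | None:
        if ei == len(pattern.elements):
            return bindings
        if ai >= n:
            return None
        el = pattern.elements[ei]
        atom = atoms[ai]
        if el.kind == "word":
            if atom.kind == "word" and atom.token.text.lower() in el.words:
                return try_match(ai + 1, ei + 1, bindings + [(el, atom.token)])
            if atom.kind == "word" and atom.token.text in _SKIPPABLE:
                return try_match(ai + 1, ei, bindings)
            return None
        if atom.kind == "word" and atom.token.text in _SKIPPABLE:
            return try_match(ai + 1, ei, bindings)
        if el.kind == "vg":
            if atom.kind != "vg":
                return None
            ends = [
                j for j in range(ai, n)
                if atoms[j].kind == "vg" and atoms[j].parent == atom.parent
                and all(atoms[k].kind == "vg" for k in range(ai, j + 1))
            ]
            for j in reversed(ends):
                run = atoms[ai:j + 1]
                vg = _np_run_chunk_vg(run)
                if _vg_satisfies(vg, el):
                    res = try_match(j + 1, ei + 1, bindings + [(el, vg)])
                    if res is not None:
                        return res
            return None
        # NP element
        if atom.kind != "np":
            return None
        ends = [
            j for j in range(ai, n)
            if atoms[j].kind == "np" and atoms[j].parent == atom.parent
        ]
        for j in reversed(ends):
            if any(atoms[k].parent != atom.parent for k in range(ai, j + 1)):
                continue
            run = atoms[ai:j + 1]
            np = _np_run_chunk(run)
            if _np_satisfies(np, el, context):
                res = try_match(j + 1, ei + 1, bindings + [(el, np)])
                if res is not None:
                    return res
        return None

    for start in range(n):
        res = try_match(start, 0, [])
        if res is not None:
            return MatchResult(pattern, res)
    return None


def _np_run_chunk_vg(run: list[_Atom]) -> Chunk:
    chunks = [a.chunk for a in run if a.chunk is not None]
    if len(chunks) == 1:
        return chunks[0]
    return _make_merged("VG", chunks, [])


def match_any(
    patterns: list[Pattern], parsed: ParsedSentence, context=None,
    category: str | None = None,
) -> MatchResult | None:
    for p in patterns:
        if category and p.category != category:
            continue
        m = match_pattern(p, parsed, context)
        if m is not None:
            return m
    return None
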