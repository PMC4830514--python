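"""Shallow parsing: base NP/VG chunks, chunk merging, head words, voice.

The tagger is a compact rule/lexicon system (closed-class word lists plus a
verb lexicon with generated inflections); everything not recognizably
verbal, adverbial or closed-class is treated as nominal, which is the right
default for biomedical noun compounds.  Mutation mentions and rsIDs are
protected as single tokens before tagging so chunks never split a mention.

Merging rules:

* a run of base NPs connected only by prepositions, conjunctions or
  permitted punctuation (comma, slash, parenthesis pairs) becomes one
  merged NP whose base chunks stay retrievable as constituents;
* strictly adjacent base VGs (no intervening words or punctuation) become
  one merged VG.

Heads: rightmost word for a base NP; for a prepositionally merged NP the
head of the leftmost base NP; for conjunctively merged NPs every conjunct
head may satisfy a pattern.  A VG's head is the rightmost word of its
rightmost base VG, which also decides voice: passive iff that base VG
contains a be/get auxiliary and ends in a past participle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import mutations
from .lexicon import (
    AUXILIARIES,
    BE_FORMS,
    COMMON_ADVERBS,
    CONJUNCTIONS,
    DETERMINERS,
    GET_FORMS,
    MODALS,
    PAST_PARTICIPLES,
    PREPOSITIONS,
    PRONOUNS,
    VERB_FORMS,
)


@dataclass
class Token:
    text: str
    start: int
    end: int
    pos: str = ""       # DT IN CC PRP MD AUX VB VBN VBG JJ RB CD NN MUT PUNCT
    protected: bool = False

    def __repr__(self):  # compact debugging
        return f"{self.text}/{self.pos}"


@dataclass
class Chunk:
    kind: str                       # "NP" | "VG"
    level: str                      # "base" | "merged"
    tokens: list[Token]             # all tokens covered, connectors included
    constituents: list["Chunk"] = field(default_factory=list)
    connectors: list[Token] = field(default_factory=list)

    @property
    def text(self) -> str:
        return " ".join(t.text for t in self.tokens)

    @property
    def start(self) -> int:
        return self.tokens[0].start

    @property
    def end(self) -> int:
        return self.tokens[-1].end

    @property
    def base_chunks(self) -> list["Chunk"]:
        return self.constituents if self.constituents else [self]

    def __repr__(self):
        return f"{self.kind}[{self.text}]"


# ---------------------------------------------------------------------------
# Tokenization

_TOKEN_RE = re.compile(
    r"\d[\d,]*\.?\d*%?"                      # numbers incl. 25,703 / 40.3%
    r"|[A-Za-z][A-Za-z0-9]*(?:[-'][A-Za-z0-9]+)*"  # words, hyphen compounds
    r"|\S"                                   # anything else, char by char
)


def tokenize(text: str, protected: list[tuple[int, int]] | None = None) -> list[Token]:
    """Tokenize with protected spans kept whole (mutation mentions etc.)."""
    protected = sorted(protected or [])
    tokens: list[Token] = []
    pos = 0
    for s, e in protected:
        for m in _TOKEN_RE.finditer(text, pos, s):
            tokens.append(Token(m.group(0), m.start(), m.end()))
        tokens.append(Token(text[s:e], s, e, protected=True))
        pos = e
    for m in _TOKEN_RE.finditer(text, pos):
        tokens.append(Token(m.group(0), m.start(), m.end()))
    return tokens


# ---------------------------------------------------------------------------
# POS tagging

_NUM_RE = re.compile(r"^\d[\d,]*\.?\d*%?$")

_NOMINAL = {"NN", "JJ", "CD", "DT", "MUT"}


def pos_tag(tokens: list[Token]) -> list[Token]:
    prev = ""
    for i, tok in enumerate(tokens):
        w = tok.text
        low = w.lower()
        tag = None
        if tok.protected:
            tag = "MUT"
        elif not any(c.isalnum() for c in w):
            tag = "PUNCT"
        elif _NUM_RE.match(w):
            tag = "CD"
        elif low == "to":
            tag = "TO"
        elif low in DETERMINERS:
            tag = "DT"
        elif low in CONJUNCTIONS:
            tag = "CC"
        elif low in PREPOSITIONS:
            tag = "IN"
        elif low in PRONOUNS and w[0].isupper() is not None and low in {"we", "they", "it", "he", "she", "i", "you"}:
            tag = "PRP"
        elif low in MODALS:
            tag = "MD"
        elif low in AUXILIARIES:
            tag = "AUX"
        elif low in VERB_FORMS:
            stem, form = VERB_FORMS[low]
            if form in ("part", "past") and prev in {"DT", "JJ", "CD", "IN"}:
                tag = "JJ"          # prenominal: "an increased risk", "of known ... mutations"
            elif form == "ger":
                # gerund is verbal only in clearly verbal contexts ("we are
                # studying", "and detecting"); elsewhere nominal/adjectival
                # so appositive participials ("..., resulting in truncation
                # of the BRCA2 protein,") stay inside the merged NP
                tag = "VBG" if prev in {"", "PRP", "AUX", "MD", "TO", "VB",
                                        "VBN", "VBG", "RB", "CC"} else "JJ"
            elif form == "base" and prev in {"DT", "JJ", "CD", "NN", "MUT"}:
                tag = "NN"          # noun/verb homographs: "a rare sequence"
            else:
                tag = "VBN" if form == "part" else "VB"
        elif low in ("more", "less", "most", "least"):
            tag = "JJ"          # comparative modifiers stay nominal for NP{contains:}
        elif low in COMMON_ADVERBS or (low.endswith("ly") and len(low) > 4):
            tag = "RB"
        else:
            tag = "NN"
        tok.pos = tag
        prev = tag
    return tokens


# ---------------------------------------------------------------------------
# Base chunking

_NP_START = {"DT", "JJ", "CD", "NN", "MUT", "PRP"}
_NP_CONT = {"JJ", "CD", "NN", "MUT"}
_VG_TAGS = {"VB", "VBN", "VBG", "AUX", "MD"}


def chunk_sentence(sentence_text: str,
                   protected: list[tuple[int, int]] | None = None,
                   tokens: list[Token] | None = None) -> list[Chunk]:
    """Produce base NP/VG chunks in textual order; tokens outside any chunk
    are left bare (returned via :func:`chunk_stream`)."""
    if tokens is None:
        if protected is None:
            protected = mutations.protected_spans(sentence_text)
        tokens = pos_tag(tokenize(sentence_text, protected))
    chunks: list[Chunk] = []
    i = 0
    n = len(tokens)

    def _consume_vg(j: int, group: list[Token]) -> int:
        """Extend a base VG from position j; stops at infinitival 'to'."""
        while j < n:
            t = tokens[j]
            if t.pos in _VG_TAGS or t.pos == "RB":
                group.append(t)
                j += 1
            else:
                break
        while group and group[-1].pos == "RB":
            group.pop()
            j -= 1
        return j

    while i < n:
        tag = tokens[i].pos
        starts_inf = (
            tag == "TO" and i + 1 < n
            and (tokens[i + 1].pos in _VG_TAGS
                 or (tokens[i + 1].pos == "RB" and i + 2 < n and tokens[i + 2].pos in _VG_TAGS))
        )
        if starts_inf:
            # infinitival "to" starts a new base VG: "to be associated"
            group = [tokens[i]]
            j = _consume_vg(i + 1, group)
            if any(t.pos in _VG_TAGS for t in group):
                chunks.append(Chunk("VG", "base", group))
                i = j
                continue
            i += 1
        elif tag in _VG_TAGS:
            group: list[Token] = []
            j = _consume_vg(i, group)
            if group and any(t.pos in _VG_TAGS for t in group):
                chunks.append(Chunk("VG", "base", group))
                i = j
                continue
            i += 1
        elif tag in _NP_START:
            j = i
            group = []
            if tokens[j].pos == "PRP":
                chunks.append(Chunk("NP", "base", [tokens[j]]))
                i = j + 1
                continue
            if tokens[j].pos == "DT":
                group.append(tokens[j])
                j += 1
            while j < n and tokens[j].pos in _NP_CONT:
                group.append(tokens[j])
                j += 1
            if group and any(t.pos in {"NN", "MUT", "CD", "JJ"} for t in group):
                chunks.append(Chunk("NP", "base", group))
                i = j
            else:
                i += 1
        else:
            i += 1
    return chunks


# ---------------------------------------------------------------------------
# Merging

_NP_CONNECT_PUNCT = {",", "/"}


_MAX_PAREN_TOKENS = 14


def merge_chunks(chunks: list[Chunk], tokens: list[Token]) -> list[Chunk]:
    """Merge base chunks per the connector rules; idempotent.

    ``tokens`` is the full token list of the sentence (used to find the
    material between chunks).  A parenthetical immediately following an NP
    (appositive restatement like "NDPK-A (S120G)") is absorbed into the
    merged NP.  Returns merged-level chunks (single base chunks pass
    through unchanged).
    """
    if not chunks:
        return []
    base = []
    for ch in chunks:  # idempotence: re-merging flattens to bases first
        base.extend(ch.base_chunks)
    tok_index = {id(t): k for k, t in enumerate(tokens)}
    starts = [tok_index[id(c.tokens[0])] for c in base]
    ends = [tok_index[id(c.tokens[-1])] for c in base]

    merged: list[Chunk] = []
    i = 0
    nb = len(base)
    while i < nb:
        cur = base[i]
        if cur.kind == "VG":
            group = [cur]
            cursor = ends[i] + 1
            while i + 1 < nb and base[i + 1].kind == "VG" and starts[i + 1] == cursor:
                i += 1
                group.append(base[i])
                cursor = ends[i] + 1
            merged.append(_make_merged("VG", group, []))
            i += 1
            continue
        group = [cur]
        connectors: list[Token] = []
        cursor = ends[i] + 1
        j = i + 1
        while True:
            # parenthetical absorption directly at the cursor
            if cursor < len(tokens) and tokens[cursor].text == "(":
                close = _matching_paren(tokens, cursor)
                if close is not None and close - cursor <= _MAX_PAREN_TOKENS:
                    inside_np: list[Chunk] = []
                    covered: set[int] = set()
                    while j < nb and starts[j] > cursor and ends[j] < close:
                        if base[j].kind == "NP":
                            inside_np.append(base[j])
                        covered.update(range(starts[j], ends[j] + 1))
                        j += 1
                    connectors.extend(
                        t for k, t in enumerate(tokens[cursor:close + 1], cursor)
                        if k not in covered
                    )
                    group.extend(inside_np)
                    cursor = close + 1
                    i = j - 1
                    continue
            if j >= nb or base[j].kind != "NP":
                break
            gap = tokens[cursor:starts[j]]
            if len(gap) <= 4 and all(_is_np_connector(t) for t in gap):
                connectors.extend(gap)
                group.append(base[j])
                cursor = ends[j] + 1
                i = j
                j += 1
                continue
            break
        merged.append(_make_merged("NP", sorted(group, key=lambda c: c.start), connectors))
        i += 1
    return merged


def _matching_paren(tokens: list[Token], open_idx: int) -> int | None:
    depth = 0
    for k in range(open_idx, len(tokens)):
        if tokens[k].text == "(":
            depth += 1
        elif tokens[k].text == ")":
            depth -= 1
            if depth == 0:
                return k
    return None


def _is_np_connector(tok: Token) -> bool:
    return (
        tok.pos in {"IN", "CC", "TO"}
        or tok.text in _NP_CONNECT_PUNCT
        or tok.text in {"-", "–", "—"}
    )


def _make_merged(kind: str, group: list[Chunk], connectors: list[Token]) -> Chunk:
    if len(group) == 1 and not connectors:
        return group[0]
    toks: list[Token] = []
    for g in group:
        toks.extend(g.tokens)
    all_toks = sorted(toks + connectors, key=lambda t: t.start)
    return Chunk(kind, "merged", all_toks, constituents=group, connectors=connectors)


# ---------------------------------------------------------------------------
# Heads and voice

def _rightmost_word(chunk: Chunk) -> Token:
    for t in reversed(chunk.tokens):
        if t.pos != "PUNCT":
            return t
    return chunk.tokens[-1]


def head_word(chunk: Chunk) -> Token:
    """Single canonical head (for head sets use :func:`head_words`)."""
    return head_words(chunk)[0]


def head_words(chunk: Chunk) -> list[Token]:
    """Head(s) of a chunk.

    Base NP: rightmost word.  Prepositionally merged NP: head of the
    leftmost base NP.  Conjunctively merged NP: the heads of all conjuncts
    (any may satisfy a pattern).  VG: rightmost word of the rightmost base
    VG.
    """
    if chunk.kind == "VG":
        return [_rightmost_word(chunk.base_chunks[-1])]
    if chunk.level == "base" or not chunk.constituents:
        return [_rightmost_word(chunk)]
    # split constituents into conjunct groups at CC connectors
    groups: list[list[Chunk]] = [[chunk.constituents[0]]]
    conn_iter = list(chunk.connectors)
    for prev, nxt in zip(chunk.constituents, chunk.constituents[1:]):
        gap = [t for t in conn_iter if prev.end <= t.start <= nxt.start]
        if any(t.pos == "CC" or t.text == "," for t in gap):
            groups.append([nxt])
        else:
            groups[-1].append(nxt)
    return [_rightmost_word(g[0]) for g in groups]


def voice(chunk: Chunk) -> str:
    """Voice of a VG: passive iff the rightmost base VG contains a be/get
    auxiliary (explicit or infinitival) and ends in a past participle."""
    assert chunk.kind == "VG"
    last = chunk.base_chunks[-1]
    words = [t.text.lower() for t in last.tokens]
    has_be = any(w in BE_FORMS or w in GET_FORMS for w in words)
    final = words[-1]
    is_part = final in PAST_PARTICIPLES or last.tokens[-1].pos in ("VBN",) or (
        final.endswith("ed") and final not in VERB_FORMS
    )
    return "passive" if has_be and is_part else "active"


# ---------------------------------------------------------------------------
# Sentence-level convenience

@dataclass
class ParsedSentence:
    text: str
    tokens: list[Token]
    base_chunks: list[Chunk]
    chunks: list[Chunk]             # merged level

    def stream(self) -> list:
        """Merged chunks and bare tokens in textual order (match substrate)."""
        covered = set()
        for ch in self.chunks:
            for t in ch.tokens:
                covered.add(id(t))
        items: list = []
        chunk_iter = iter(sorted(self.chunks, key=lambda c: c.start))
        nxt = next(chunk_iter, None)
        i = 0
        while i < len(self.tokens):
            t = self.tokens[i]
            if nxt is not None and t is nxt.tokens[0]:
                items.append(nxt)
                i += len(nxt.tokens)
                nxt = next(chunk_iter, None)
            else:
                if id(t) not in covered:
                    items.append(t)
                i += 1
        return items


def parse_sentence(text: str, protected: list[tuple[int, int]] | None = None) -> ParsedSentence:
    if protected is None:
        protected = mutations.protected_spans(text)
    tokens = pos_tag(tokenize(text, protected))
    base = chunk_sentence(text, tokens=tokens)
    merged = merge_chunks(base, tokens)
    return ParsedSentence(text, tokens, base, merged)
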