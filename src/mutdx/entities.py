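"""Gene and disease mention tagging.

Taggers are pluggable: anything that maps a Document to EntityMentions can
be used (e.g. standoff annotations from an external NER tool, loaded with
:func:`load_standoff`).  The default is a dictionary tagger over TSV
gazetteers using case-insensitive leftmost-longest matching.

Two refinement rules are applied to disease mentions:

* a disease that is an acronym is discarded when its long form matches the
  gene gazetteer or fails the disease gazetteer (e.g. "AR" defined as
  "Androgen Receptor");
* bare generic terms ("tumor", "cancer") are rebound to the closest
  specific disease mention, preferring one inside the same merged NP, else
  the nearest in preceding text.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .ingest import Document
from .lexicon import GENERIC_DISEASE_TERMS


class GazetteerError(FileNotFoundError):
    pass


@dataclass
class EntityMention:
    kind: str                   # "gene" | "disease"
    text: str                   # surface string
    sentence_index: int
    char_span: tuple[int, int]  # offsets within the sentence
    canonical: str              # gazetteer canonical entry

    @property
    def start(self) -> int:
        return self.char_span[0]

    @property
    def end(self) -> int:
        return self.char_span[1]


class Gazetteer:
    """Term list with canonical names: TSV columns term / canonical / kind
    (canonical and kind optional; kind defaults to the constructor's)."""

    def __init__(self, kind: str, terms: dict[str, str] | None = None):
        self.kind = kind
        self.term_to_canonical: dict[str, str] = {}
        self.original_terms: list[str] = []
        for term, canonical in (terms or {}).items():
            self.add(term, canonical)

    def add(self, term: str, canonical: str | None = None) -> None:
        if term.lower() not in self.term_to_canonical:
            self.original_terms.append(term)
        self.term_to_canonical[term.lower()] = canonical or term

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "Gazetteer":
        path = Path(path)
        if not path.exists():
            raise GazetteerError(f"gazetteer not found: {path}")
        gaz = cls(kind)
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                term = row[0].strip()
                canonical = row[1].strip() if len(row) > 1 and row[1].strip() else term
                if len(row) > 2 and row[2].strip() and row[2].strip() != kind:
                    continue
                gaz.add(term, canonical)
        return gaz

    def canonical(self, term: str) -> str | None:
        return self.term_to_canonical.get(term.lower())

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.term_to_canonical

    def __len__(self) -> int:
        return len(self.term_to_canonical)


def _compile(gaz: Gazetteer) -> list[re.Pattern]:
    """Two scanners per gazetteer: long/multiword terms match
    case-insensitively; short symbols (< 5 chars, single word) match
    case-sensitively so gene symbols like MET or KIT never hit common
    words."""
    long_terms = [t for t in gaz.original_terms if len(t) >= 5 or " " in t]
    short_terms = [t for t in gaz.original_terms if t not in long_terms]
    out = []
    for terms, flags in ((long_terms, re.I), (short_terms, 0)):
        if not terms:
            continue
        alts = "|".join(
            re.escape(t).replace(r"\ ", r"[\s-]+")
            for t in sorted(terms, key=len, reverse=True)
        )
        out.append(re.compile(rf"(?<![\w-])(?:{alts})(?![\w-])", flags))
    return out


class DictionaryTagger:
    """Leftmost-longest dictionary tagger over one or more gazetteers."""

    def __init__(self, *gazetteers: Gazetteer):
        self.gazetteers = gazetteers
        self._patterns = [(g, _compile(g)) for g in gazetteers]

    def tag_sentence(self, text: str, sentence_index: int) -> list[EntityMention]:
        hits: list[EntityMention] = []
        for gaz, rxs in self._patterns:
            for rx, m in ((rx, m) for rx in rxs for m in rx.finditer(text)):
                surface = m.group(0)
                canonical = gaz.canonical(re.sub(r"[\s-]+", " ", surface)) \
                    or gaz.canonical(surface) or surface
                hits.append(
                    EntityMention(gaz.kind, surface, sentence_index,
                                  (m.start(), m.end()), canonical)
                )
        # leftmost-longest across gazetteers
        hits.sort(key=lambda h: (h.start, -(h.end - h.start)))
        chosen: list[EntityMention] = []
        for h in hits:
            if any(h.start < c.end and c.start < h.end for c in chosen):
                continue
            chosen.append(h)
        return chosen

    def __call__(self, document: Document) -> list[EntityMention]:
        out = []
        for sent in document.sentences:
            out.extend(self.tag_sentence(sent.text, sent.index))
        return out


def tag_entities(
    document: Document,
    gene_gazetteer: Gazetteer,
    disease_gazetteer: Gazetteer,
    tagger=None,
) -> list[EntityMention]:
    """Tag gene and disease mentions; an external tagger (document ->
    mentions) may be substituted for the dictionary default."""
    if tagger is None:
        tagger = DictionaryTagger(gene_gazetteer, disease_gazetteer)
    return tagger(document)


def filter_disease_acronyms(
    mentions: list[EntityMention],
    acronyms: dict[str, str],
    gene_gazetteer: Gazetteer,
    disease_gazetteer: Gazetteer | None = None,
) -> list[EntityMention]:
    """Drop disease mentions whose acronym long form indicates a non-disease
    (gene gazetteer hit, or absent from the disease gazetteer)."""
    out = []
    for m in mentions:
        if m.kind == "disease" and m.text in acronyms:
            long_form = acronyms[m.text]
            if long_form in gene_gazetteer:
                continue
            if disease_gazetteer is not None and long_form not in disease_gazetteer:
                continue
        out.append(m)
    return out


def resolve_generic_diseases(
    mentions: list[EntityMention],
    parsed_sentences: dict[int, object] | None = None,
) -> list[EntityMention]:
    """Rebind bare generic disease mentions ("the tumor", "cancer") to the
    closest specific disease: same merged NP first, then minimal token
    distance in preceding text (ties to the earlier mention); a generic
    with no specific disease anywhere stays generic."""
    specifics = [
        m for m in mentions
        if m.kind == "disease" and m.text.lower() not in GENERIC_DISEASE_TERMS
    ]
    for m in mentions:
        if m.kind != "disease" or m.text.lower() not in GENERIC_DISEASE_TERMS:
            continue
        if not specifics:
            continue
        same_np = []
        if parsed_sentences and m.sentence_index in parsed_sentences:
            ps = parsed_sentences[m.sentence_index]
            for ch in ps.chunks:
                if ch.kind == "NP" and ch.start <= m.start and m.end <= ch.end:
                    same_np = [
                        s for s in specifics
                        if s.sentence_index == m.sentence_index
                        and ch.start <= s.start and s.end <= ch.end
                    ]
                    break
        pool = same_np or specifics

        def distance(s: EntityMention) -> tuple:
            before = (s.sentence_index, s.start) <= (m.sentence_index, m.start)
            return (
                not before,
                abs(s.sentence_index - m.sentence_index),
                abs(s.start - m.start),
                s.sentence_index,
                s.start,
            )

        nearest = min(pool, key=distance)
        m.canonical = nearest.canonical
    return mentions


def load_standoff(path: str | Path, kind_filter: str | None = None) -> dict[str, list[EntityMention]]:
    """Load standoff annotations (TSV: pmid / start / end / kind / text),
    PubTator-style offsets, keyed by pmid.  Offsets refer to title+abstract
    and are mapped onto sentences by the caller."""
    by_pmid: dict[str, list] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 5:
                continue
            pmid, start, end, kind, text = row[:5]
            if kind_filter and kind != kind_filter:
                continue
            by_pmid.setdefault(pmid, []).append(
                EntityMention(kind, text, -1, (int(start), int(end)), text)
            )
    return by_pmid
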