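"""Reading Medline/PubMed records or plain text into Documents.

Supports three input formats:

* PubMed XML (``PubmedArticleSet``), parsed with lxml;
* Medline flat format (``PMID-``/``TI-``/``AB-``/``MH-``/``PT-`` fields),
  parsed with Bio.Medline;
* plain text: first line is the title, the rest the abstract body.

Sentence splitting is a rule list (terminal punctuation + following
capitalization + an abbreviation blacklist); character offsets are 0-based
half-open on the raw abstract string and the split never loses or
duplicates characters.  Acronym detection follows the Schwartz–Hearst
letter-alignment contract.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Medline
from lxml import etree


class RecordParseError(ValueError):
    """Malformed input record; message names the PMID when known."""


@dataclass
class Sentence:
    index: int                      # 0-based ordinal; 0 is the title
    text: str
    char_span: tuple[int, int]      # offsets into the abstract body (title: into title)
    is_title: bool = False


@dataclass
class Document:
    pmid: str
    title: str
    body: str = ""
    sentences: list[Sentence] = field(default_factory=list)
    mesh_terms: list[tuple[str, str]] = field(default_factory=list)  # (descriptor, tag)
    acronyms: dict[str, str] = field(default_factory=dict)
    structured_labels: dict[int, str] = field(default_factory=dict)  # sentence idx -> label
    has_abstract: bool = True

    @classmethod
    def from_text(cls, pmid: str, title: str, body: str = "",
                  mesh_terms: list[tuple[str, str]] | None = None) -> "Document":
        doc = cls(pmid=pmid, title=title, body=body,
                  mesh_terms=list(mesh_terms or []),
                  has_abstract=bool(body.strip()))
        doc.sentences = [Sentence(0, title, (0, len(title)), is_title=True)]
        for s in split_sentences(body):
            doc.sentences.append(
                Sentence(len(doc.sentences), s.text, s.char_span)
            )
        doc.acronyms = detect_acronyms(doc)
        return doc

    @classmethod
    def from_sentences(cls, pmid: str, title: str, body_sentences: list[str],
                       mesh_terms: list[tuple[str, str]] | None = None) -> "Document":
        """Build a document from pre-split sentences (fixtures, tests)."""
        return cls.from_text(pmid, title, " ".join(body_sentences), mesh_terms)


# ---------------------------------------------------------------------------
# Sentence splitting

_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "cf", "vs", "al", "fig", "figs", "ref", "refs",
    "no", "nos", "ca", "approx", "dr", "prof", "mr", "mrs", "ms", "st",
    "inc", "ltd", "jr", "sr", "dept", "univ", "resp", "min", "max",
}

_TERMINAL_RE = re.compile(r"[.!?]")


def split_sentences(text: str) -> list[Sentence]:
    """Split an abstract body into sentences.

    Splits at ., ! or ? followed by whitespace and an uppercase letter or
    digit, unless the preceding token is a known abbreviation or a single
    capital letter (initials).  Every input character belongs to exactly one
    sentence span or to inter-sentence whitespace.
    """
    if not text.strip():
        return []
    boundaries = [0]
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in ".!?":
            j = i + 1
            # run of closing quotes/brackets stays with the sentence
            while j < n and text[j] in ")\"']":
                j += 1
            if j >= n:
                break
            if not text[j].isspace():
                i += 1
                continue
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k >= n:
                break
            nxt = text[k]
            if not (nxt.isupper() or nxt.isdigit() or nxt in "(\""):
                i += 1
                continue
            if ch == ".":
                word = re.search(r"([A-Za-z][\w.]*)$", text[:i])
                if word:
                    w = word.group(1).rstrip(".").lower()
                    if w in _ABBREVIATIONS or (len(w) == 1 and word.group(1)[0].isupper()):
                        i += 1
                        continue
            boundaries.append(k)
            i = k
            continue
        i += 1
    sentences = []
    for idx, start in enumerate(boundaries):
        end = boundaries[idx + 1] if idx + 1 < len(boundaries) else n
        raw = text[start:end]
        stripped = raw.rstrip()
        if not stripped:
            continue
        sentences.append(Sentence(idx, stripped, (start, start + len(stripped))))
    for i, s in enumerate(sentences):
        s.index = i
    return sentences


# ---------------------------------------------------------------------------
# Acronym detection (Schwartz–Hearst-style letter alignment)

_PAREN_SF_RE = re.compile(r"\(\s*([^()]{1,12}?)\s*\)")


def _valid_short_form(sf: str) -> bool:
    if not 2 <= len(sf) <= 10 or " " in sf:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    return sf[0].isalnum()


def _best_long_form(sf: str, candidate: str) -> str | None:
    """Right-to-left alignment: every short-form alphanumeric character must
    appear in order in the candidate, and the first one must start a word."""
    s_idx = len(sf) - 1
    l_idx = len(candidate) - 1
    while s_idx >= 0:
        c = sf[s_idx].lower()
        if not c.isalnum():
            s_idx -= 1
            continue
        while l_idx >= 0 and (
            candidate[l_idx].lower() != c
            or (s_idx == 0 and l_idx > 0 and candidate[l_idx - 1].isalnum())
        ):
            l_idx -= 1
        if l_idx < 0:
            return None
        l_idx -= 1
        s_idx -= 1
    start = candidate.rfind(" ", 0, l_idx + 2) + 1
    return candidate[start:].strip() or None


def detect_acronyms(document: Document) -> dict[str, str]:
    """Map parenthesized short forms to their preceding long forms; the
    first definition of a short form wins; unalignable ones are skipped."""
    acronyms: dict[str, str] = {}
    for sent in document.sentences:
        for m in _PAREN_SF_RE.finditer(sent.text):
            sf = m.group(1).strip()
            if not _valid_short_form(sf) or sf in acronyms:
                continue
            before = sent.text[:m.start()].rstrip()
            words = before.split()
            max_words = min(len(sf) + 5, len(sf) * 2)
            candidate = " ".join(words[-max_words:]) if words else ""
            if not candidate:
                continue
            lf = _best_long_form(sf, candidate)
            if lf and lf.lower() != sf.lower():
                acronyms[sf] = lf
    return acronyms


# ---------------------------------------------------------------------------
# Record parsing

_LABEL_RE = re.compile(r"^([A-Z][A-Z /&]{2,30}):\s+")

_LABEL_MAP = {
    "BACKGROUND": "Introduction", "INTRODUCTION": "Introduction",
    "OBJECTIVE": "Introduction", "OBJECTIVES": "Introduction",
    "PURPOSE": "Introduction", "AIM": "Methods", "AIMS": "Methods",
    "METHODS": "Methods", "METHOD": "Methods", "DESIGN": "Methods",
    "MATERIALS AND METHODS": "Methods", "PATIENTS AND METHODS": "Methods",
    "SUBJECTS AND METHODS": "Methods",
    "RESULTS": "Results", "FINDINGS": "Results",
    "CONCLUSION": "Conclusion", "CONCLUSIONS": "Conclusion",
    "INTERPRETATION": "Conclusion",
}


def map_section_label(label: str) -> str | None:
    """Map a declared structured-abstract label to a rhetorical zone."""
    return _LABEL_MAP.get(label.strip().upper())


def _attach_structured_labels(doc: Document, sections: list[tuple[str | None, str]]) -> None:
    """Rebuild the body from labeled sections and record, per sentence
    index, the declared label of the section it falls in."""
    body = " ".join(txt for _, txt in sections if txt)
    doc.body = body
    doc.sentences = [Sentence(0, doc.title, (0, len(doc.title)), is_title=True)]
    for s in split_sentences(body):
        doc.sentences.append(Sentence(len(doc.sentences), s.text, s.char_span))
    # section char ranges in the rebuilt body
    offset = 0
    ranges: list[tuple[str | None, int, int]] = []
    for label, txt in sections:
        if not txt:
            continue
        ranges.append((label, offset, offset + len(txt)))
        offset += len(txt) + 1
    for sent in doc.sentences[1:]:
        mid = (sent.char_span[0] + sent.char_span[1]) // 2
        for label, s, e in ranges:
            if label and s <= mid < e:
                doc.structured_labels[sent.index] = label
                break
    doc.acronyms = detect_acronyms(doc)


def parse_pubmed_xml(raw: str | bytes) -> list[Document]:
    """Parse a PubmedArticleSet XML string into Documents."""
    if isinstance(raw, str):
        raw = raw.encode()
    try:
        root = etree.fromstring(raw)
    except etree.XMLSyntaxError as exc:
        raise RecordParseError(f"malformed PubMed XML: {exc}") from exc
    docs = []
    for art in root.iter("MedlineCitation"):
        pmid = art.findtext("PMID")
        title = art.findtext(".//ArticleTitle")
        if not pmid or title is None:
            raise RecordParseError(f"record missing PMID or title (PMID={pmid!r})")
        sections: list[tuple[str | None, str]] = []
        for node in art.findall(".//Abstract/AbstractText"):
            label = node.get("Label")
            sections.append((label, "".join(node.itertext()).strip()))
        mesh: list[tuple[str, str]] = []
        for mh in art.findall(".//MeshHeading/DescriptorName"):
            mesh.append((mh.text or "", "MH"))
        for pt in art.findall(".//PublicationTypeList/PublicationType"):
            mesh.append((pt.text or "", "PT"))
        doc = Document.from_text(pmid, title.strip(), "", mesh)
        if sections:
            if any(lbl for lbl, _ in sections):
                _attach_structured_labels(doc, sections)
            else:
                body = " ".join(t for _, t in sections)
                doc2 = Document.from_text(pmid, title.strip(), body, mesh)
                doc = doc2
            doc.has_abstract = True
        else:
            doc.has_abstract = False
        docs.append(doc)
    return docs


def parse_medline(raw: str) -> list[Document]:
    """Parse Medline flat-format records (PMID-/TI-/AB-/MH-/PT- fields)."""
    docs = []
    for rec in Medline.parse(io.StringIO(raw)):
        pmid = rec.get("PMID")
        title = rec.get("TI")
        if not pmid or not title:
            raise RecordParseError(f"record missing PMID or title (PMID={pmid!r})")
        body = rec.get("AB", "")
        mesh = [(t, "MH") for t in rec.get("MH", [])]
        mesh += [(t, "PT") for t in rec.get("PT", [])]
        doc = Document.from_text(pmid, title.strip(), body, mesh)
        doc.has_abstract = bool(body.strip())
        # labeled structured abstracts in flat format carry inline labels
        labels = {}
        for sent in doc.sentences[1:]:
            m = _LABEL_RE.match(sent.text)
            if m and m.group(1).strip().upper() in _LABEL_MAP:
                labels[sent.index] = m.group(1).strip()
        doc.structured_labels = labels
        docs.append(doc)
    return docs


def parse_plain_text(raw: str, pmid: str = "NA") -> Document:
    """Plain-text mode: first line is the title, the rest the abstract."""
    lines = raw.strip().splitlines()
    if not lines:
        raise RecordParseError("empty plain-text record")
    title = lines[0].strip()
    body = " ".join(line.strip() for line in lines[1:] if line.strip())
    return Document.from_text(pmid, title, body)


def parse_record(raw: str, fmt: str = "auto", pmid: str = "NA") -> list[Document]:
    """Dispatch on format: pubmed-xml | medline | text | auto."""
    if fmt == "auto":
        stripped = raw.lstrip()
        if stripped.startswith("<"):
            fmt = "pubmed-xml"
        elif re.match(r"^PMID-", stripped):
            fmt = "medline"
        else:
            fmt = "text"
    if fmt == "pubmed-xml":
        return parse_pubmed_xml(raw)
    if fmt == "medline":
        return parse_medline(raw)
    if fmt == "text":
        return [parse_plain_text(raw, pmid)]
    raise ValueError(f"unknown format {fmt!r}")


def read_documents(paths: list[str | Path], fmt: str = "auto") -> list[Document]:
    docs = []
    for p in paths:
        docs.extend(parse_record(Path(p).read_text(), fmt))
    return docs
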