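"""Rhetorical zones, patient context, cohort/population extraction,
outcome linkage, and meta-analysis/review flags.

Zone segmentation is boundary-based over the whole abstract rather than a
per-sentence classifier: the title is sentence 0, the Introduction starts
at sentence 1, the Methods section starts at the first method-cue sentence
(default: after three Introduction sentences), Results at the first
result-cue sentence, and the Conclusion at the first conclusion-cue
sentence (default: the last sentence).  Declared structured-abstract
labels override the heuristics.  Cue lists live in ``data/zone_cues.yaml``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .entities import Gazetteer
from .ingest import Document, map_section_label

ZONES = ("Title", "Introduction", "Methods", "Results", "Conclusion")

#: triplet-provenance ranking, best first
ZONE_RANK = ("Results", "Conclusion", "Title", "Methods", "Introduction")


def _default_cues() -> dict:
    with resources.files("mutdx.data").joinpath("zone_cues.yaml").open() as fh:
        return yaml.safe_load(fh)


_CUES = None


def get_cues() -> dict:
    global _CUES
    if _CUES is None:
        _CUES = _default_cues()
    return _CUES


@dataclass
class StudyMetadata:
    pc_sentence_index: int | None = None
    patients: int | None = None
    controls: int | None = None
    populations: list[str] = field(default_factory=list)
    is_meta_analysis: bool = False
    n_publications: int | None = None
    n_studies: int | None = None
    n_subjects: int | None = None
    is_review: bool = False


@dataclass
class OutcomeLink:
    mutation_key: str
    outcome: str            # overall-survival | disease-free-survival |
                            # progression-free-survival | risk | metastasis |
                            # drug-resistance | drug-sensitivity
    sentence_index: int
    drug: str | None = None
    qualifier: str | None = None


# ---------------------------------------------------------------------------
# Zone segmentation

def _first_cue_index(document: Document, cues: list[str], start: int = 1) -> int | None:
    for sent in document.sentences[start:]:
        low = sent.text.lower()
        if any(c in low for c in cues):
            return sent.index
    return None


def segment_zones(document: Document, cues: dict | None = None) -> list[str]:
    """Zone label per sentence index.  Structured labels, when present,
    override the heuristic boundaries."""
    n = len(document.sentences)
    if n == 0:
        return []
    if document.structured_labels:
        return _zones_from_labels(document)
    cues = cues or get_cues()
    last = n - 1
    methods_start = _first_cue_index(document, cues["method_cues"])
    explicit_methods = methods_start is not None
    if methods_start is None:
        methods_start = 4  # after three Introduction sentences
    results_start = _first_cue_index(
        document, cues["result_cues"],
        start=methods_start if explicit_methods else 1,
    )
    conclusion_start = _first_cue_index(document, cues["conclusion_cues"])
    if conclusion_start is None:
        conclusion_start = last if last >= 1 else None
    zones = []
    for i in range(n):
        if i == 0:
            zones.append("Title")
        elif conclusion_start is not None and i >= conclusion_start:
            zones.append("Conclusion")
        elif results_start is not None and i >= results_start:
            zones.append("Results")
        elif i >= methods_start:
            zones.append("Methods")
        else:
            zones.append("Introduction")
    return zones


def _zones_from_labels(document: Document) -> list[str]:
    zones = ["Title"]
    current = "Introduction"
    for sent in document.sentences[1:]:
        label = document.structured_labels.get(sent.index)
        if label:
            mapped = map_section_label(label)
            if mapped:
                current = mapped
        zones.append(current)
    # enforce the block order T,I,M,R,C (a stray later label cannot move
    # a section backwards)
    order = {z: k for k, z in enumerate(ZONES)}
    for i in range(2, len(zones)):
        if order[zones[i]] < order[zones[i - 1]]:
            zones[i] = zones[i - 1]
    return zones


def rank_zone(zones: set[str] | list[str]) -> str:
    """Top-ranked zone of a triplet's evidence: Results > Conclusion >
    Title > Methods > Introduction."""
    zs = set(zones)
    if not zs:
        raise ValueError("empty zone set")
    for z in ZONE_RANK:
        if z in zs:
            return z
    raise ValueError(f"unknown zones: {zs}")


# ---------------------------------------------------------------------------
# Patient context and cohort

_NUM = r"\d[\d,]*"


def _patient_noun_alt(cues: dict) -> str:
    return "|".join(sorted(cues["patient_nouns"], key=len, reverse=True))


def detect_patient_context(document: Document, cues: dict | None = None) -> int | None:
    """Index of the first body sentence describing the study cohort: a
    patient noun with a nearby count, or a patient noun plus a cohort verb."""
    cues = cues or get_cues()
    noun_alt = _patient_noun_alt(cues)
    with_count = re.compile(
        rf"\b{_NUM}\s+(?:\S+\s+){{0,4}}?(?:{noun_alt})\b", re.I
    )
    noun_rx = re.compile(rf"\b(?:{noun_alt})\b", re.I)
    verb_alt = "|".join(cues["cohort_verbs"])
    verb_rx = re.compile(rf"\b(?:{verb_alt})\b", re.I)
    for sent in document.sentences[1:]:
        if with_count.search(sent.text):
            return sent.index
        if noun_rx.search(sent.text) and verb_rx.search(sent.text):
            return sent.index
    return None


_CONTROL_NOUNS = {"controls", "control"}


def extract_cohort(text: str, cues: dict | None = None) -> tuple[int | None, int | None]:
    """(patients, controls) from one sentence: the number preceding a
    patient noun (up to four intervening words) and the number preceding
    "controls".  Thousands separators are accepted; absent values are None."""
    cues = cues or get_cues()
    noun_alt = _patient_noun_alt(cues)
    rx = re.compile(
        rf"\b({_NUM})\s+(?:\S+\s+){{0,4}}?({noun_alt})\b", re.I
    )
    patients = controls = None
    for m in rx.finditer(text):
        count = int(m.group(1).replace(",", ""))
        noun = m.group(2).lower()
        if noun in _CONTROL_NOUNS:
            if controls is None:
                controls = count
        elif patients is None:
            patients = count
    return patients, controls


def load_country_gazetteer(path: str | Path | None = None) -> Gazetteer:
    """Country/adjectival/demonym TSV -> gazetteer canonicalized to the
    country name."""
    if path is None:
        path = resources.files("mutdx.data").joinpath("countries.tsv")
    gaz = Gazetteer("population")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            country = cols[0]
            for term in cols:
                if term:
                    gaz.add(term, country)
    return gaz


def extract_population(text: str, gazetteer: Gazetteer) -> list[str]:
    """Canonical country names for all country/adjectival/demonym matches,
    deduplicated in order of first occurrence."""
    terms = sorted(gazetteer.term_to_canonical, key=len, reverse=True)
    alts = "|".join(re.escape(t) for t in terms)
    rx = re.compile(rf"\b(?:{alts})\b", re.I)
    out: list[str] = []
    for m in rx.finditer(text):
        canon = gazetteer.canonical(m.group(0))
        if canon and canon not in out:
            out.append(canon)
    return out


# ---------------------------------------------------------------------------
# Outcomes

_OUTCOME_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("overall-survival", re.compile(r"overall survival", re.I)),
    ("disease-free-survival", re.compile(r"disease[- ]free survival|\bDFS\b")),
    ("progression-free-survival", re.compile(r"progression[- ]free survival|\bPFS\b")),
    ("metastasis", re.compile(r"\bmetasta\w+", re.I)),
    ("drug-resistance", re.compile(r"\bresistance\b", re.I)),
    ("drug-sensitivity", re.compile(r"\bsensitivity\b", re.I)),
    ("risk", re.compile(r"\brisk\b", re.I)),
]

_QUALIFIERS = {
    "poor", "poorer", "better", "worse", "improved", "reduced", "shorter",
    "longer", "increased", "decreased", "favorable", "unfavorable", "good",
}

_WORD_RE = re.compile(r"[\w'-]+")


def detect_outcomes(text: str, sentence_index: int = -1) -> list[OutcomeLink]:
    """Outcome trigger phrases of one sentence (mutation key unbound)."""
    links = []
    for outcome, rx in _OUTCOME_PATTERNS:
        m = rx.search(text)
        if not m:
            continue
        qualifier = None
        drug = None
        before = _WORD_RE.findall(text[:m.start()])
        if before and before[-1].lower() in _QUALIFIERS:
            qualifier = before[-1].lower()
        if outcome in ("drug-resistance", "drug-sensitivity"):
            # "MTA sensitivity" / "resistance to cisplatin"
            if before and before[-1].lower() not in {"drug", "the", "a", "an", "its", "their", "of", "chemotherapy"}:
                drug = before[-1]
            else:
                after = re.match(r"\s+to\s+([\w-]+)", text[m.end():])
                if after:
                    drug = after.group(1)
        links.append(OutcomeLink("", outcome, sentence_index, drug, qualifier))
    return links


def link_outcomes(document: Document, mutation_sentences: dict[str, set[int]],
                  pairs=None) -> list[OutcomeLink]:
    """Link outcome phrases to mutations co-occurring in the same sentence.

    ``mutation_sentences`` maps normalized mutation key -> sentence indices
    where the mutation (or a resolved allele/genotype) is mentioned.  When
    ``pairs`` is given, only keys appearing in those pairs are linked.
    """
    keys = mutation_sentences.keys()
    if pairs is not None:
        keys = {p.mutation_key for p in pairs} & set(keys)
    sent_text = {s.index: s.text for s in document.sentences}
    out: list[OutcomeLink] = []
    for key in sorted(keys):
        for sidx in sorted(mutation_sentences[key]):
            for link in detect_outcomes(sent_text[sidx], sidx):
                out.append(
                    OutcomeLink(key, link.outcome, sidx, link.drug, link.qualifier)
                )
    return out


# ---------------------------------------------------------------------------
# Meta-analysis and review

_META_RE = re.compile(r"meta[- ]?analy\w*", re.I)
_PUBS_RE = re.compile(rf"\b({_NUM})\s+publications?\b", re.I)
_STUDIES_RE = re.compile(rf"\b({_NUM})\s+stud(?:ies|y)\b", re.I)
_SUBJECTS_RE = re.compile(rf"\b({_NUM})\s+subjects?\b", re.I)
_CASES_RE = re.compile(rf"\b({_NUM})\s+cases?\b", re.I)
_CONTROLS_RE = re.compile(rf"\b({_NUM})\s+controls?\b", re.I)


def _num(m: re.Match | None) -> int | None:
    return int(m.group(1).replace(",", "")) if m else None


def detect_meta_analysis(document: Document) -> tuple[bool, int | None, int | None, int | None]:
    """(is_meta, n_publications, n_studies, n_subjects).

    n_subjects is the explicit subject count when stated anywhere in the
    abstract, else the sum of cases and controls when both are present.
    """
    full = " ".join(s.text for s in document.sentences)
    if not _META_RE.search(full):
        return (False, None, None, None)
    n_pub = _num(_PUBS_RE.search(full))
    n_stud = _num(_STUDIES_RE.search(full))
    n_subj = _num(_SUBJECTS_RE.search(full))
    if n_subj is None:
        cases = _num(_CASES_RE.search(full))
        controls = _num(_CONTROLS_RE.search(full))
        if cases is not None and controls is not None:
            n_subj = cases + controls
    return (True, n_pub, n_stud, n_subj)


def detect_review(document: Document, match: str = "exact") -> bool:
    """True iff a Publication Type entry equals "Review" (``match="prefix"``
    accepts e.g. "Review of Reported Cases")."""
    for term, tag in document.mesh_terms:
        if tag != "PT":
            continue
        if match == "prefix" and term.lower().startswith("review"):
            return True
        if term.lower() == "review":
            return True
    return False


def extract_study_metadata(
    document: Document,
    country_gazetteer: Gazetteer | None = None,
    cues: dict | None = None,
) -> StudyMetadata:
    """Per-document study metadata: PC sentence, cohort sizes, populations,
    meta-analysis counts and review flag."""
    cues = cues or get_cues()
    meta = StudyMetadata()
    meta.pc_sentence_index = detect_patient_context(document, cues)
    if meta.pc_sentence_index is not None:
        sent = document.sentences[meta.pc_sentence_index]
        meta.patients, meta.controls = extract_cohort(sent.text, cues)
    if country_gazetteer is not None:
        pops: list[str] = []
        for sent in document.sentences:
            for p in extract_population(sent.text, country_gazetteer):
                if p not in pops:
                    pops.append(p)
        meta.populations = pops
    meta.is_meta_analysis, meta.n_publications, meta.n_studies, meta.n_subjects = \
        detect_meta_analysis(document)
    meta.is_review = detect_review(document)
    return meta
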