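"""Triplet assembly, serialization, and scoring.

A Triplet is one <mutation, gene, disease> record per abstract with its
evidence: the surface forms seen, the ranked rhetorical zone, sentence
types, outcome links, and evidence sentence indices.  Outputs are a
triplet-view TSV and a per-PMID JSON (cohort, populations, meta-analysis,
review).  ``score`` compares predicted and gold triplet TSVs with
precision/recall/F-measure; gene/disease comparison is case-insensitive
with optional relaxation for component-level scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .pipeline import DocAnalysis
from .zones import rank_zone

#: fixed, versioned triplet-view column order
TSV_COLUMNS = [
    "pmid", "mutation", "gene", "disease", "location", "outcome",
    "sentence_types", "evidence_sentences", "surface_forms",
]
TSV_VERSION = "mutdx-triplets-v1"


@dataclass
class Triplet:
    pmid: str
    mutation_key: str
    gene: str
    disease: str
    zone: str
    surface_forms: list[str] = field(default_factory=list)
    sentence_types: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    evidence_sentences: list[int] = field(default_factory=list)


def assemble(analysis: DocAnalysis) -> tuple[list[Triplet], dict]:
    """Join mutation-disease pairs with gene associations on the mutation
    key; merge duplicates with zone ranking.  Idempotent on its output.
    Returns (triplets, metadata-record)."""
    doc = analysis.document
    surface: dict[str, list[str]] = {}
    for m in analysis.mutation_occurrences():
        surface.setdefault(m.key, [])
        if m.raw not in surface[m.key]:
            surface[m.key].append(m.raw)
    outcome_by_key: dict[str, list[str]] = {}
    for o in analysis.outcomes:
        label = o.outcome if not o.drug else f"{o.drug} {o.outcome.split('-')[-1]}"
        outcome_by_key.setdefault(o.mutation_key, [])
        if label not in outcome_by_key[o.mutation_key]:
            outcome_by_key[o.mutation_key].append(label)

    grouped: dict[tuple, Triplet] = {}
    for p in analysis.pairs:
        ga = analysis.gene_associations.get(p.mutation_key)
        gene = ga.gene if ga else ""
        sig = (doc.pmid, p.mutation_key, gene, p.disease)
        t = grouped.get(sig)
        if t is None:
            t = Triplet(doc.pmid, p.mutation_key, gene, p.disease, "",
                        surface.get(p.mutation_key, []),
                        outcomes=outcome_by_key.get(p.mutation_key, []))
            grouped[sig] = t
        if p.sentence_type not in t.sentence_types:
            t.sentence_types.append(p.sentence_type)
        if p.sentence_index not in t.evidence_sentences:
            t.evidence_sentences.append(p.sentence_index)
    for t in grouped.values():
        zones = {
            analysis.zones[i] for i in t.evidence_sentences
            if i < len(analysis.zones)
        }
        t.zone = rank_zone(zones) if zones else ""
    triplets = sorted(
        grouped.values(), key=lambda t: (min(t.evidence_sentences or [0]),
                                         t.mutation_key, t.disease)
    )
    meta = analysis.metadata
    meta_record = {
        "pmid": doc.pmid,
        "patients": meta.patients,
        "controls": meta.controls,
        "populations": meta.populations,
        "is_meta_analysis": meta.is_meta_analysis,
        "n_publications": meta.n_publications,
        "n_studies": meta.n_studies,
        "n_subjects": meta.n_subjects,
        "is_review": meta.is_review,
        "pc_sentence_index": meta.pc_sentence_index,
        "n_triplets": len(triplets),
    }
    return triplets, meta_record


def triplets_to_frame(triplets: list[Triplet]) -> pd.DataFrame:
    rows = []
    for t in triplets:
        rows.append({
            "pmid": t.pmid,
            "mutation": t.mutation_key,
            "gene": t.gene,
            "disease": t.disease,
            "location": t.zone,
            "outcome": ";".join(t.outcomes),
            "sentence_types": ";".join(t.sentence_types),
            "evidence_sentences": ";".join(map(str, t.evidence_sentences)),
            "surface_forms": ";".join(t.surface_forms),
        })
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_outputs(
    triplets: list[Triplet],
    metadata: list[dict],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the triplet-view TSV and PMID-view JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "triplets.tsv"
    json_path = out_dir / "metadata.json"
    frame = triplets_to_frame(triplets)
    with open(tsv_path, "w") as fh:
        fh.write(f"# {TSV_VERSION}\n")
        frame.to_csv(fh, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump({m["pmid"]: m for m in metadata}, fh, indent=1)
    return tsv_path, json_path


def read_triplets(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


class ScoringError(ValueError):
    pass


def score(
    predicted: pd.DataFrame | list[Triplet],
    gold: pd.DataFrame,
    relax: str | None = None,
    synonyms: dict[str, str] | None = None,
) -> tuple[float, float, float]:
    """(precision, recall, F) over triplet records.

    A match is equality of (pmid, normalized mutation key, gene, disease),
    case-insensitive for gene and disease with an optional synonym table;
    ``relax="gene"`` or ``relax="disease"`` drops that component for
    component-level scoring.  Empty gold is an error (recall undefined).
    """
    if not isinstance(predicted, pd.DataFrame):
        predicted = triplets_to_frame(predicted)
    if len(gold) == 0:
        raise ScoringError("empty gold set: recall undefined")
    synonyms = {k.lower(): v.lower() for k, v in (synonyms or {}).items()}

    def canon(value: str) -> str:
        v = str(value).strip().lower()
        return synonyms.get(v, v)

    def keyset(df: pd.DataFrame) -> set:
        out = set()
        for _, row in df.iterrows():
            key = [str(row["pmid"]).strip(), canon(row["mutation"])]
            if relax != "gene":
                key.append(canon(row["gene"]))
            if relax != "disease":
                key.append(canon(row["disease"]))
            out.add(tuple(key))
        return out

    pred_set, gold_set = keyset(predicted), keyset(gold)
    tp = len(pred_set & gold_set)
    fp = len(pred_set - gold_set)
    fn = len(gold_set - pred_set)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn)
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
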