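"""Seeded synthetic-abstract generator with planted gold truth.

The generator assembles an abstract from zone templates (title,
introduction, patient-context/methods, one results sentence per planted
mutation, conclusion) and records the planted <mutation, gene, disease>
triplets plus study metadata as gold.  Mutation surface forms are rendered
from an independent template table — the generator shares no code with the
mutation detector, so end-to-end recall on planted truth is a genuine
cross-check, not a tautology.

Distractor knobs exercise precision paths: P-value sentences without
mutations, genes mentioned without any pairing term, and generic-variant
sentences that must not become mutation mentions.

Same seed + spec -> byte-identical abstract and gold.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .ingest import Document
from .lexicon import AA3_TO_1

# ---------------------------------------------------------------------------
# Independent rendering tables (data shared with the detector is limited to
# the standard amino-acid code table)

_AA1 = sorted(set(AA3_TO_1.values()))
_AA3 = {v: k for k, v in AA3_TO_1.items()}
_BASES = ["A", "C", "G", "T"]

#: surface-format templates: name -> (renderer, class)
_FORMATS = {
    "protein-1": (lambda w, p, m: f"{w}{p}{m}", "protein"),
    "protein-3": (lambda w, p, m: f"{_AA3[w]}{p}{_AA3[m]}", "protein"),
    "protein-arrow": (lambda w, p, m: f"{_AA3[w]} {p}-->{_AA3[m]}", "protein"),
    "dna-gt": (lambda w, p, m: f"{p}{w}>{m}", "dna"),
    "dna-slash": (lambda w, p, m: f"{p}{w}/{m}", "dna"),
    "dna-nl": (lambda w, p, m: f"{w} to {m} transition at position {p}", "dna"),
}

_GENE_POOL = [
    "BRCA1", "BRCA2", "TP53", "EGFR", "KRAS", "PTEN", "ATM", "CHEK2",
    "MLH1", "MSH2", "XRCC1", "XRCC3", "ERCC2", "GSTP1", "MTHFR", "CYP1A1",
    "CDH1", "STK11", "PALB2", "RAD51", "TGFB1", "VEGFA", "IL10", "TNF",
]

_DISEASE_POOL = [
    "breast cancer", "prostate cancer", "colorectal cancer", "lung cancer",
    "gastric cancer", "ovarian cancer", "pancreatic cancer",
    "bladder cancer", "esophageal cancer", "hepatocellular carcinoma",
    "melanoma", "glioma",
]

_COUNTRY_POOL = [
    ("China", "Chinese"), ("Japan", "Japanese"), ("Finland", "Finnish"),
    ("Germany", "German"), ("Italy", "Italian"), ("Greece", "Greek"),
    ("Turkey", "Turkish"), ("India", "Indian"), ("South Korea", "Korean"),
    ("Poland", "Polish"),
]


class InfeasibleSpec(ValueError):
    pass


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_mutations: int = 2
    n_genes: int = 2
    n_diseases: int = 1
    format_weights: dict[str, float] = field(default_factory=dict)
    zone_template: str = "default"
    distractor_pvalue: bool = True
    distractor_unlinked_gene: bool = True
    distractor_generic_variant: bool = False

    def validate(self) -> None:
        if self.n_mutations > 0 and self.n_genes < 1:
            raise InfeasibleSpec("planted mutations require at least one gene")
        if self.n_genes > len(_GENE_POOL):
            raise InfeasibleSpec(f"at most {len(_GENE_POOL)} genes supported")
        if self.n_diseases < 1 or self.n_diseases > len(_DISEASE_POOL):
            raise InfeasibleSpec("n_diseases out of range")
        unknown = set(self.format_weights) - set(_FORMATS)
        if unknown:
            raise InfeasibleSpec(f"unknown surface formats: {sorted(unknown)}")


@dataclass
class GoldTriplet:
    mutation_key: str
    gene: str
    disease: str
    surface: str


@dataclass
class GoldRecord:
    pmid: str
    triplets: list[GoldTriplet]
    patients: int
    controls: int
    populations: list[str]
    is_meta_analysis: bool
    distractors: list[str] = field(default_factory=list)  # distractor surfaces


def _render_mutation(rng: random.Random, fmt: str, used_positions: set[int]):
    renderer, cls = _FORMATS[fmt]
    pos = rng.randint(30, 9999)
    while pos in used_positions:
        pos = rng.randint(30, 9999)
    used_positions.add(pos)
    if cls == "protein":
        wild, mutant = rng.sample(_AA1, 2)
    else:
        wild, mutant = rng.sample(_BASES, 2)
    surface = renderer(wild, pos, mutant)
    key = f"{wild}-{pos}-{mutant}"       # generator-side oracle key
    return surface, key


def generate(spec: SyntheticSpec) -> tuple[Document, GoldRecord]:
    """One synthetic abstract plus its planted gold truth."""
    spec.validate()
    rng = random.Random(spec.seed)
    pmid = f"S{rng.randrange(10**7):07d}"
    genes = rng.sample(_GENE_POOL, spec.n_genes)
    diseases = rng.sample(_DISEASE_POOL, spec.n_diseases)
    disease = diseases[0]
    country, demonym = rng.choice(_COUNTRY_POOL)
    weights = spec.format_weights or {f: 1.0 for f in _FORMATS}
    fmt_names = sorted(weights)
    fmt_w = [weights[f] for f in fmt_names]

    used_positions: set[int] = set()
    planted: list[GoldTriplet] = []
    for i in range(spec.n_mutations):
        fmt = rng.choices(fmt_names, weights=fmt_w)[0]
        surface, key = _render_mutation(rng, fmt, used_positions)
        gene = genes[i % len(genes)]
        planted.append(GoldTriplet(key, gene, disease, surface))

    patients = rng.randint(50, 2000)
    controls = rng.randint(50, 2000)

    title = f"{genes[0]} variants and the risk of {disease} in {country}."
    body: list[str] = [
        f"Genetic variation in the {genes[0]} gene has been implicated in "
        f"{disease}.",
        f"A total of {patients} {disease} patients and {controls} healthy "
        f"controls from {country} were analyzed.",
    ]
    result_templates = [
        "The {gene} {mut} variant was significantly associated with {disease}.",
        "Carriers of the {gene} {mut} polymorphism had an increased risk of "
        "{disease} (P = 0.0{p}).",
        "We detected a novel {gene} mutation, {mut}, in the affected group.",
    ]
    distractors: list[str] = []
    for i, t in enumerate(planted):
        tpl = result_templates[i % len(result_templates)]
        body.append(tpl.format(gene=t.gene, mut=t.surface, disease=disease,
                               p=rng.randint(10, 49)))
    if spec.distractor_pvalue:
        body.append(
            "The difference in mean age between the groups was not "
            f"significant (P = 0.{rng.randint(50, 94)})."
        )
        distractors.append("pvalue-no-mutation")
    if spec.distractor_unlinked_gene:
        extra = rng.choice([g for g in _GENE_POOL if g not in genes])
        body.append(f"Expression of {extra} was unchanged in {demonym} "
                    "samples.")
        distractors.append(f"unlinked-gene:{extra}")
    if spec.distractor_generic_variant:
        body.append("Several other sequence variants were observed but not "
                    "characterized.")
        distractors.append("generic-variant")
    if planted:
        last = planted[-1]
        body.append(
            f"In conclusion, the {last.surface} variant in {last.gene} "
            f"contributes to {disease} susceptibility."
        )
    doc = Document.from_sentences(pmid, title, body)
    gold = GoldRecord(
        pmid=pmid,
        triplets=planted,
        patients=patients,
        controls=controls,
        populations=[country],
        is_meta_analysis=False,
        distractors=distractors,
    )
    return doc, gold


def generate_corpus(
    seed: int, n_docs: int, base_spec: SyntheticSpec | None = None
) -> list[tuple[Document, GoldRecord]]:
    """n_docs documents with per-document seeds derived from ``seed``;
    mutation counts cycle 1..3 for variety."""
    out = []
    base = base_spec or SyntheticSpec()
    for i in range(n_docs):
        spec = SyntheticSpec(
            seed=(seed * 100003 + i) % (2**31 - 1),
            n_mutations=1 + (i % 3),
            n_genes=1 + (i % 2),
            n_diseases=base.n_diseases,
            format_weights=base.format_weights,
            distractor_pvalue=base.distractor_pvalue,
            distractor_unlinked_gene=base.distractor_unlinked_gene,
            distractor_generic_variant=(i % 4 == 0),
        )
        out.append(generate(spec))
    return out
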