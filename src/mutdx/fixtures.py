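"""Curated gold mini-corpus.

Each FixtureCase is a miniature document built from example sentences of
published abstracts (source PMIDs noted) with hand-checked expected
outputs per stage.  Some cases need one synthetic context sentence
(marked ``synthetic_context``) because the full source abstract is not
part of the corpus; the expected values for the non-synthetic sentences
are unchanged by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ingest import Document


@dataclass
class FixtureCase:
    case_id: str
    pmid: str
    title: str
    body: list[str]
    expected: dict
    synthetic_context: list[int] = field(default_factory=list)  # body indices
    mesh_terms: list[tuple[str, str]] = field(default_factory=list)

    def document(self) -> Document:
        return Document.from_sentences(self.pmid, self.title, self.body,
                                       self.mesh_terms)


def paper_corpus() -> list[FixtureCase]:
    """The full fixture set, one case per documented example extraction."""
    cases = [
        FixtureCase(
            "ex1", "15330212",
            "BRCA1 mutation screening in Greek and Turkish families.",
            ["A total of 453 breast cancer patients and 382 age- and "
             "sex-matched controls from Greece and Turkey were analyzed."],
            expected={
                "patients": 453, "controls": 382,
                "populations": ["Greece", "Turkey"],
                "pc_sentence_index": 1,
            },
        ),
        FixtureCase(
            "ex2", "12783936", "PON1 variants and prostate cancer.",
            ["The PON1 102V allele appears to be associated with an "
             "increased risk for prostate cancer."],
            expected={
                "primary_type": {1: "Association"},
                "pattern": {1: "NP1 VG_passive{head: associate} with NP2"},
                "pair_diseases": ["prostate cancer"],
                "gene_of": {"-102-V": "PON1"},
                "base_nps": {1: ["The PON1 102V allele", "an increased risk",
                                 "prostate cancer"]},
                "base_vgs": {1: ["appears", "to be associated"]},
                "merged_np": {1: "an increased risk for prostate cancer"},
                "merged_vg": {1: "appears to be associated"},
            },
        ),
        FixtureCase(
            "ex3", "17574969",
            "Association of the BRCA1 missense variant R1699W with a "
            "malignant phyllodes tumor of the breast.",
            [],
            expected={
                "pairs": [("R-1699-W", "phyllodes tumor")],
                "gene_of": {"R-1699-W": "BRCA1"},
            },
        ),
        FixtureCase(
            "ex4", "20863780", "XRCC1 polymorphisms and gastric cancer.",
            ["The XRCC1 Arg194Trp polymorphism has been studied in many "
             "populations.",
             "XRCC1 194Trp allele significantly increased the risk of "
             "gastric cancer and also associated with risk of gastric "
             "cardia carcinoma and promoted distant metastasis of gastric "
             "cancer."],
            synthetic_context=[0],
            expected={"allele_resolution": {"194Trp": "R-194-W"}},
        ),
        FixtureCase(
            "ex5", "20813679", "CTLA-4 +49G/A polymorphism in HCC.",
            ["The +49G/A polymorphism of the CTLA-4 gene was genotyped in "
             "all participants.",
             "In HCC and CHB groups, the genotype frequency was 40.3% and "
             "50.0% for GG, and 59.7% and 50.0% for AG+AA, respectively, "
             "while the genotype frequency was 61.8% for GG and 38.2% for "
             "AG+AA in the control group."],
            synthetic_context=[0],
            expected={"genotype_resolution": {"AG": "G-+49-A", "GG": "G-+49-A",
                                              "AA": "G-+49-A"}},
        ),
        FixtureCase(
            "ex6", "20376705", "SELP and PSGL-1 variants in CHD.",
            ["Our aim was to evaluate the contribution to CHD of the "
             "following SNPs: C-2123G, G-1969A and T715P in SELP, Met62Ile "
             "and the VNTR variants in PSGL-1 gene in a North African "
             "population from Tunisia."],
            expected={
                "gene_of": {"C--2123-G": "SELP", "G--1969-A": "SELP",
                            "T-715-P": "SELP", "M-62-I": "PSGL-1"},
                "tier_of": {"C--2123-G": 1, "G--1969-A": 1, "T-715-P": 1,
                            "M-62-I": 1},
                "no_mention_of": ["VNTR"],
                "populations": ["Tunisia"],
            },
        ),
        FixtureCase(
            "ex7", "11507049", "Prostate cancer susceptibility loci.",
            ["Prostate cancer susceptibility has previously been linked to "
             "the RNASEL gene.",
             "Here, we screened for mutations of the ELAC2/HPC2 gene in 66 "
             "Finnish HPC families.",
             "Several sequence variants, including a new exonic variant "
             "(Glu622Val) were found, but none of the mutations were "
             "truncating."],
            synthetic_context=[0],
            expected={
                "gene_of": {"E-622-V": "ELAC2/HPC2"},
                "tier_of": {"E-622-V": 4},
                "pairing_genes": ["ELAC2/HPC2"],
                "populations": ["Finland"],
            },
        ),
        FixtureCase(
            "ex8", "20630073",
            "Synergistic effect of stromelysin-1 (matrix "
            "metalloproteinase-3) promoter (-1171 5A-> 6A) polymorphism in "
            "oral submucous fibrosis and head and neck lesions.",
            [],
            expected={
                "primary_type": {0: "Association"},
                "pattern": {0: "NP{head: effect} of NP1 in/on NP2"},
            },
        ),
        FixtureCase(
            "ex9", "12783936", "PON1 variants and incident prostate cancer.",
            ["We identified a new PON1 variant, I102V, in the study cohort.",
             "Multivariable analysis was used to investigate the "
             "association of known and new PON1 mutations with incident "
             "prostate cancer in 1569 cancer-free men in the cohort "
             "followed for 9-14 years."],
            synthetic_context=[0],
            expected={
                "pairs": [("I-102-V", "prostate cancer")],
                "referent": {"sentence": 2, "keys": ["I-102-V"]},
                "patients_in_sentence": {2: 1569},
            },
        ),
        FixtureCase(
            "ex10", "15280446", "NDPK-A S120G and neuroblastoma.",
            ["Compared with its wild-type, NDPK-A (S120G) appears more "
             "effective in promoting neuroblastoma metastasis."],
            expected={
                "primary_type": {1: "Comparison"},
                "pair_diseases": ["neuroblastoma"],
            },
        ),
        FixtureCase(
            "ex11", "16503999", "HFE variants in breast cancer.",
            ["Statistical analysis of cases with HFE H63D phenotype showed "
             "significant difference between breast cancer and healthy "
             "volunteers (P = 0.02)."],
            expected={
                "primary_type": {1: "Comparison"},
                "pairs": [("H-63-D", "breast cancer")],
            },
        ),
        FixtureCase(
            "ex12", "20226083",
            "RRM1 single nucleotide polymorphism -37C—>A correlates with "
            "progression-free survival in NSCLC patients after "
            "gemcitabine-based chemotherapy",
            ["For the -37C—> A polymorphism, the median PFS was 30.7 weeks "
             "in the C(-) 37A group, 24.7 weeks in the A(-) 37A group, and "
             "23.3 weeks in the C(-) 37C group (P = 0.043)."],
            expected={
                "primary_type": {1: "Statistical"},
                "pairs": [("C--37-A", "NSCLC")],
                "fallback": {"sentence": 1, "disease": "NSCLC",
                             "provenance": "title"},
            },
        ),
        FixtureCase(
            "ex13", "11260866", "BRCA1 mutations in German families.",
            ["We have investigated German breast- and/or ovarian-cancer "
             "families and detected a recurrent carboxy-terminal BRCA1 "
             "mutation, 5622C > T, using PCR-based restriction assay and "
             "haplotype analysis."],
            expected={
                "mutation_found": {1: True},
                "mutation_keys": {1: ["C-5622-T"]},
                "gene_of": {"C-5622-T": "BRCA1"},
            },
        ),
        FixtureCase(
            "ex14", "9133456", "BRCA2 mutation screening.",
            ["Germline mutations of BRCA2 were examined in 20 Japanese "
             "breast cancer families without BRCA1 mutations, including "
             "one demonstrating cancer development in a male.",
             "Three different mutations, resulting in truncation of the "
             "BRCA2 protein, were detected in 3 different families.",
             "They were 9474insA (exon 24, termination at codon 3110), "
             "C8729A (exon 20, S2834 ter) and 982del4 (exon 9, termination "
             "at codon 275)."],
            expected={
                "mutation_keys": {3: ["9474insA", "C-8729-A", "982del4"]},
                "pairs": [("9474insA", "breast cancer"),
                          ("C-8729-A", "breast cancer"),
                          ("982del4", "breast cancer")],
                "provenance": {("9474insA", "breast cancer"): "PC",
                               ("C-8729-A", "breast cancer"): "PC",
                               ("982del4", "breast cancer"): "PC"},
                "gene_of": {"9474insA": "BRCA2", "C-8729-A": "BRCA2",
                            "982del4": "BRCA2"},
                "pc_sentence_index": 1,
                "populations": ["Japan"],
            },
        ),
        FixtureCase(
            "ex15", "17125911",
            "KLF6 IVS1 -27G> A variant and the risk of prostate cancer in "
            "Finland.",
            [],
            expected={
                "pairs": [("G-IVS1-27-A", "prostate cancer")],
                "gene_of": {"G-IVS1-27-A": "KLF6"},
                "populations": ["Finland"],
            },
        ),
        FixtureCase(
            "ex16", "21483023", "Genome-wide association study of survival.",
            ["The discovery population included 327 non-small cell lung "
             "cancer patients treated with chemotherapy.",
             "SNP rs1878022 in the chemokine-like receptor 1 (CMKLR1) was "
             "statistically significantly associated with poor overall "
             "survival in the MD Anderson discovery population."],
            synthetic_context=[0],
            expected={
                "outcomes": [("rs1878022", "overall-survival", "poor")],
                "gene_of": {"rs1878022": "CMKLR1"},
            },
        ),
        FixtureCase(
            "ex17", "20718756", "ABCC11 and pemetrexed response.",
            ["Cell growth inhibition by MTA was measured in cells grouped "
             "by ABCC11 genotype.",
             "The A/A group showed a significant reduction in the IC (50) "
             "of MTA compared with the combined G/G and G/A groups, "
             "indicating that the SNP (538G> A) in the ABCC11 gene is an "
             "important determinant of MTA sensitivity."],
            synthetic_context=[0],
            expected={
                "outcomes": [("G-538-A", "drug-sensitivity", "MTA")],
                "gene_of": {"G-538-A": "ABCC11"},
            },
        ),
        FixtureCase(
            "ex18", "20043205",
            "Lack of an association between a functional polymorphism in "
            "the interleukin-6 gene promoter and breast cancer risk: a "
            "meta-analysis involving 25,703 subjects.",
            ["A total of 11 publications containing 12 studies including "
             "10,137 cases and 15,566 controls were identified."],
            expected={
                "meta": (True, 11, 12, 25703),
            },
        ),
        FixtureCase(
            "ex19", "15769334", "hMLH1 polymorphisms: a case-control study.",
            ["A case-control study was taken to investigate the role of "
             "Val384Asp in hMLH1 gene in developing these four carcinomas.",
             "233 colorectal, 273 gastric, 90 esophageal and 111 breast "
             "cancer patients were included, as well as 268 healthy "
             "individual served as controls."],
            expected={
                "mutation_keys": {1: ["V-384-D"]},
                "no_pair": [("V-384-D", "breast cancer")],
            },
        ),
        FixtureCase(
            "table1", "10810408",
            "Missense alterations of BRCA1 gene detected in diverse cancer "
            "patients.",
            ["BRCA1 gene mutations may also be related with other types of "
             "cancers such as prostate cancer and colorectal cancer.",
             "We used PCR-NIRCA and PCR-SSCP methods for screening the "
             "BRCA1 mutation hot regions, exons 2, 5, 11, 16 and 20.",
             "We have identified a rare sequence variant, A3537G (Ser "
             "1140Gly) in a B cell lymphoma patient and two polymorphisms, "
             "A1186G (Gln356Arg) in a brain cancer patient and A3667G "
             "(Lys1183Arg) in a germline tumor patient.",
             "In conclusion, 3 missense alterations of BRCA1 gene have "
             "been identified in cancers other than breast cancer."],
            expected={
                "zones": ["Title", "Introduction", "Methods", "Results",
                          "Conclusion"],
            },
        ),
        FixtureCase(
            "conj", "9466928", "Beta-2 adrenergic receptor variants.",
            ["Site-directed mutagenesis was used to change Ala16 >Cys, "
             "Thr, Met, Arg, His and Tyr."],
            expected={
                "mutation_keys": {1: ["A-16-C", "A-16-T", "A-16-M", "A-16-R",
                                      "A-16-H", "A-16-Y"]},
            },
        ),
    ]
    return cases


def get_case(case_id: str) -> FixtureCase:
    for c in paper_corpus():
        if c.case_id == case_id:
            return c
    raise KeyError(case_id)
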