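# mutdx

Rule-based extraction of **mutation–gene–disease associations** from
biomedical abstracts.

Curated variant databases (ClinVar, COSMIC, BioMuta, HGMD, …) depend on
humans reading papers. `mutdx` automates the first pass over
Medline/PubMed abstracts for curators and text-mining researchers: it
finds mutation mentions, normalizes them, attaches each one to its gene
and to the disease the study links it with, and records study metadata
(cohort sizes, populations, rhetorical zone of the evidence,
meta-analysis/review status, disease outcomes such as survival or drug
sensitivity).

## Method

The pipeline is a sequence of deterministic NLP stages:

1. **Ingest** — PubMed XML, Medline flat format, or plain text; sentence
   splitting; Schwartz–Hearst-style acronym detection.
2. **Shallow parsing** — base noun phrases (NPs) and verb groups (VGs)
   from a rule/lexicon tagger; adjacent base VGs merge into one VG, and
   runs of base NPs connected by prepositions, conjunctions or
   punctuation merge into one NP.  Heads: rightmost word of a base NP;
   head of the leftmost constituent for a prepositionally merged NP;
   rightmost base VG decides a VG's head and voice.
3. **Mutation detection** — regular-expression grammar for protein and
   DNA substitutions (`Ala282Val`, `5557G>A`, `IVS1 -27G>A`, `-79C/T`),
   insertions/deletions (`5382insC`, `982del4`), dbSNP IDs, terminations,
   natural-language descriptions ("A→C transversion in codon 135"), and
   conjunction expansion ("Ala16>Cys, Thr, … and Tyr" → six mentions).
   Every mention normalizes to a canonical key `W-pos-M`, so `G5557A`
   and `5557G>A` compare equal.  Allele ("194Trp allele") and genotype
   ("AG") references resolve to the full mutation mentioned elsewhere
   in the abstract.
4. **Gene association** — four tiers: same merged NP; propagation of
   that evidence to all occurrences of the key; the only gene in the
   abstract; the closest previous *gene–mutation pairing* (gene +
   "variant"/"mutation"/"SNP"… in one merged NP).
5. **Disease association** — lexico-syntactic patterns over the chunk
   stream (`NP1 VG_passive{head: associate} with NP2`, …) classify each
   sentence as Association, Comparison, Statistical (P/OR value),
   Mutation-Found, Title, or Conclusion type and extract one pair per
   mutation and disease.  A sentence with no in-sentence disease falls
   back to the Patient-Context sentence, the title, conclusion, then
   introduction.
6. **Metadata and assembly** — rhetorical zones (Title, Introduction,
   Methods, Results, Conclusion; ranked Results > Conclusion > Title >
   Methods > Introduction for triplet provenance), cohort sizes,
   populations (country/demonym gazetteer), outcome links, meta-analysis
   and review flags; deduplicated `<M,G,D>` triplets with evidence.

Precision/recall/F (P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R)) are
available through a scoring harness that consumes gold TSVs in the same
triplet schema.

## Worked example

```sh
$ cat abstract.txt
KLF6 variants and the risk of prostate cancer in Finland.
Prostate cancer is a common malignancy in Western countries. A total of
418 prostate cancer patients and 500 controls from Finland were
analyzed. We found that the KLF6 IVS1 -27G> A variant was significantly
associated with prostate cancer (P = 0.01). In conclusion, the IVS1
-27G> A variant contributes to prostate cancer risk.

$ mutdx run --out out/ abstract.txt
wrote out/triplets.tsv (1 triplets) and out/metadata.json
```

`out/triplets.tsv`:

```
pmid  mutation     gene  disease          location  outcome  sentence_types  evidence_sentences  surface_forms
NA    G-IVS1-27-A  KLF6  prostate cancer  Results   risk     Association     3;4                 IVS1 -27G> A
```

The intronic variant `IVS1 -27G> A` was normalized to the key
`G-IVS1-27-A`, associated with KLF6 (same merged NP), and paired with
prostate cancer by an association pattern; the strongest evidence
sentence lies in the Results zone, and a "risk" outcome phrase co-occurs
with the mutation.  `out/metadata.json` records patients=418,
controls=500, population Finland, and the Patient-Context sentence
index.

Other entry points: `mutdx detect` (mutation mentions as TSV,
comparable to MutationFinder/tmVar-style gold files), `mutdx score
--gold gold.tsv --pred pred.tsv [--relax gene|disease]`, `mutdx synth
--seed 7 --n-docs 100 --out dir` (synthetic abstracts + gold), and
`mutdx debug-chunks` / `mutdx debug-genes` for inspection.

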