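# Methods

This note documents the models, rules and numerical choices behind
`mutdx`, the assumptions they rest on, and what the shipped tests do and
do not demonstrate.

## Scope and design stance

`mutdx` is a deterministic, rule-based information-extraction pipeline:
no statistical model is fitted anywhere, so identical input always
yields identical output.  The design optimizes for *auditable
precision* — every extraction can be traced to a specific rule, pattern
or gazetteer row — at the cost of recall on phrasings outside the rule
inventory.  All rule inventories (patterns, zone cues, gazetteers) are
externalized as plain-text config so extending coverage needs no code
change.

## Shallow parsing

Tokenization protects mutation mentions and rsIDs as single tokens
before tagging, so a chunk can never split a mention.  The POS tagger is
a closed-class/lexicon system: determiners, prepositions, conjunctions,
modals and auxiliaries are table-driven; a ~100-stem verb lexicon with
generated inflections covers the verbs that matter for chunking and
voice; everything else defaults to nominal, which is the right prior
for biomedical noun compounds.  Ambiguity rules that matter:

* a participle after a determiner/adjective/preposition is adjectival
  ("an **increased** risk", "of **known** … mutations"); after a noun or
  auxiliary it is verbal ("phenotype **showed**", "were **detected**");
* a gerund is verbal only in clearly verbal contexts ("we are
  **studying**"); elsewhere it is nominal, which keeps appositive
  participials ("…, resulting in truncation of the BRCA2 protein,")
  inside the enclosing NP where pattern matching needs them;
* base-form verb/noun homographs after a nominal are nouns ("a rare
  **sequence** variant").

Merging: strictly adjacent base VGs form one VG (an infinitival *to*
starts a new base VG, so "appears | to be associated" merges to one VG
whose rightmost base VG carries head and voice).  Base NPs connected by
up to four tokens of prepositions, conjunctions, commas, slashes or
dashes form one merged NP; a parenthetical immediately following an NP
(up to 14 tokens) is absorbed as an appositive ("NDPK-A (S120G)").
Voice is passive iff the rightmost base VG contains a be/get form and
ends in a past participle.

## Mutation grammar and normalization

The format grammar accepts the separator glyphs `>`, `-->`, `—>`, `——`,
`→`, `/` and the word "to"; positions are opaque tokens so intronic
(`IVS9-5`, `1066-6`) and negative (`-79`) positions survive unchanged.
Overlaps resolve leftmost-longest.  Natural-language detection requires
a wild/mutant symbol pair *and* an anchor word (codon, position,
residue, amino acid, nucleotide), with multi-position and multi-mutant
lists expanded one mention per combination.  Generic references
("mutations", "VNTR variants") are deliberately not mentions; they are,
however, recognized as mutation-denoting NP heads during pattern
matching.

Normalization folds 3-letter and full residue names to one-letter code
and renders `W-pos-M` (indels: `{pos}ins{SEQ}` / `{pos}del{SEQ}`; dbSNP:
the lowercased identifier).  A silent change (`A123A`) is still reported
and flagged; downstream filtering is the caller's choice.  The kind
label of a one-letter substitution is heuristic (both symbols in
{A,C,G,T} → DNA), since surface form alone cannot distinguish `T877A`
the protein change from a nucleotide change; keys are unaffected.

Two extensions beyond the format classes:

* a mention inside a parenthetical that opens immediately after another
  mention is folded into it as an annotation ("A3537G (Ser 1140Gly)" is
  one mutation; a listing like "9474insA (exon 24, termination at codon
  3110)" yields one mention, which keeps listing sentences at their
  stated mutation count);
* an allele with no resolvable full mutation anywhere in the abstract is
  promoted to a partial mutation mention (empty wild-type, key
  `-pos-M`), so single-sentence documents still yield their documented
  pair.

## Gene association tiers

Tier 1 picks, within the merged NP containing the mutation, the nearest
gene mention after it (else before) — this resolves listing NPs where
several mutations and two genes share one NP.  Conflicting tier-1
evidence for one key keeps the earliest occurrence and logs a warning.
Tier 3 (only gene in the abstract) is applied before tier 4, following
the order the tiers are defined in.  Tier 4 ranks gene–mutation
pairings: same-sentence pairings by character proximity with leftward
preference; pairings in earlier sentences by sentence distance and then
by position within the sentence ascending, on the rationale that the
first pairing of a sentence carries its topic ("Germline mutations of
BRCA2 were examined … without BRCA1 mutations" should contribute BRCA2,
not the oblique BRCA1).  Associations propagate to every occurrence of
the normalized key; alleles and genotypes inherit through their
resolved mutation.

## Pattern language and matching

Patterns are element sequences (literal words, comma, `NP`,
`NP{head:}`, `NP{contains:}`, `NP<mutation>`, `NP<disease>`,
`VG_active{head:}`, `VG_passive{head:}`); `a/b` alternation expands at
parse time.  Lexeme constraints match inflectional and derivational
variants through a suffix-family table (associate → associated,
association, …) — deterministic and auditable, not a lemmatizer.
Matching walks merged chunks and bare tokens; an NP element may consume
a whole merged NP or any contiguous run of its constituents, so one
merged NP can satisfy several consecutive elements.  The matcher is
leftmost-first and greedy-longest with backtracking; bare commas,
colons and parentheses between elements are skippable (appositives),
while an explicit `,` element still consumes one.

The shipped config contains every pattern of the documented inventory
(association triggers associate/correlate/contribute/relationship/
effect; comparison triggers compare/difference; mutation-found triggers
detect/identify/find/analyze/screen).  The inventory is known to be a
subset of the full production pattern set, which is the main recall
limitation on real abstracts.

## Sentence types and disease fallback

Association patterns are tried first, then Comparison, then the
Statistical test (regex for `P =/</≤ number` and `OR =/: number`,
written so prose "or" never fires); a sentence matching an association
pattern is never labeled Statistical even when it contains a P-value.
Statistical extraction requires an in-sentence mutation.  Mutation-Found
sentences whose `NP<mutation>` is count-only ("Three different
mutations") take the specific mentions listed in the following one or
two sentences.  Title and Conclusion types fire independently of
patterns when both a mutation and a disease are present.  The fallback
chain for a missing in-sentence disease is Patient Context (only when
the PC sentence precedes the current one), title, conclusion sentences,
introduction sentences; the same chain serves all covered types.
Negation is not modeled: "no association was found" still yields a
pair, by design.

## Zones and study metadata

Zone boundaries are computed abstract-wide: Introduction starts at
sentence 1; Methods at the first method-cue sentence, defaulting to
sentence 4 (three Introduction sentences); Results at the first
result-cue sentence (searched from the Methods boundary when one was
found explicitly, else from the start of the body); Conclusion at the
first conclusion-cue sentence, defaulting to the last sentence.  When
boundaries collide, later sections claim sentences first (Conclusion,
then Results, then Methods), keeping the blocks contiguous in canonical
order.  Declared structured-abstract labels override all heuristics.
Zone ranking for triplet provenance is Results > Conclusion > Title >
Methods > Introduction.

The Patient-Context sentence is the first body sentence with a patient
noun (patients, controls, cases, subjects, participants, families,
volunteers, men, women, individuals — config-extendable) near a count
or with a cohort verb; the exact definition of a "patient mention" is a
documented choice pinned by fixtures.  Cohort counts must literally
occur as numerals (thousands separators accepted) within four tokens
before the noun.  Meta-analysis subject counts prefer an explicit
"N subjects" statement and otherwise sum cases and controls when both
are present.  The review flag requires a Publication-Type entry exactly
equal to "Review" (prefix matching is opt-in).

## Synthetic data: what it shows and what it does not

The generator plants mutations, genes, diseases, cohort sentences and
distractors into zone templates and records the planted truth as gold.
Surface forms are rendered from the generator's own template table —
six format families covering one-letter, three-letter, arrow, `>`,
slash and natural-language renderings — which shares no code with the
detector, so end-to-end recall on planted truth is a genuine
cross-check.  Default conditions: 100 documents per run, 1–3 mutations
and 1–2 genes per document cycling deterministically, one central
disease, cohort sizes uniform in 50–2000, every document carrying a
P-value distractor and an unlinked-gene distractor, every fourth
document a generic-variant distractor.  The generator targets rule
coverage, not linguistic realism: sentences are short, unambiguous and
free of anaphora, negation and cross-sentence ellipsis, so a passing
synthetic run demonstrates the mechanics of detection, association and
assembly — not performance on real Medline prose, where the published
benchmark corpora (BioMuta, prostate/breast sets, MutationFinder,
Variome, tmVar) remain the honest yardstick.  Those corpora are
external; the `score` harness accepts them in the documented TSV
schema but no shipped test depends on them.

## Numerical and procedural choices

* Character offsets are 0-based half-open on the raw sentence string;
  Unicode dashes/arrows are preserved in text and folded only inside
  the mutation matcher.
* Sentence splitting: terminal punctuation + following capital/digit +
  abbreviation blacklist; decimals and single-initial abbreviations
  never split.
* Acronym detection follows the right-to-left letter-alignment
  contract; the first definition of a short form wins per document.
* Dictionary entity tagging is leftmost-longest; terms shorter than
  five characters match case-sensitively so gene symbols (MET, KIT)
  never hit common words.  "Closest" in generic-disease resolution is
  same-merged-NP first, then minimal distance with ties to the earlier
  mention.
* Determinism: the only randomness in the package is the synthetic
  generator's seeded RNG; the pipeline itself is pure.

## Known limitations

Cross-sentence mutation components (position in one sentence, symbols
in the next) are not assembled; repeat-length alleles (`5A/6A`) and
frameshift/copy-number nomenclature are out of grammar; diseases and
genes are not normalized to ontology identifiers; full-text articles
are out of scope.  These boundaries are deliberate scope choices, not
oversights.
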