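"""Shared lexical resources.

Amino-acid / nucleotide symbol tables, closed-class word lists, a compact
verb lexicon with generated inflections, and lexeme-variant expansion used
by the pattern matcher.  The tagger and chunker are rule/lexicon based, so
these tables define most of their behaviour; the hand-annotated fixture
corpus pins the rest.
"""

from __future__ import annotations

from functools import lru_cache

# ---------------------------------------------------------------------------
# Residue and base symbol tables

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

AA_FULL_TO_1 = {
    "alanine": "A", "arginine": "R", "asparagine": "N",
    "aspartate": "D", "aspartic acid": "D", "cysteine": "C",
    "glutamine": "Q", "glutamate": "E", "glutamic acid": "E",
    "glycine": "G", "histidine": "H", "isoleucine": "I",
    "leucine": "L", "lysine": "K", "methionine": "M",
    "phenylalanine": "F", "proline": "P", "serine": "S",
    "threonine": "T", "tryptophan": "W", "tyrosine": "Y", "valine": "V",
}

BASE_FULL_TO_1 = {
    "adenine": "A", "cytosine": "C", "guanine": "G",
    "thymine": "T", "uracil": "U",
}

AA1 = set("ACDEFGHIKLMNPQRSTVWY")
BASES = set("ACGT")

# stop/termination symbols accepted as a mutant-type
STOP_SYMBOLS = {"X", "Ter", "ter", "TER", "stop", "Stop", "STOP", "*", "Term", "term"}


def to_single_letter(symbol: str) -> str | None:
    """Fold a residue/base symbol (1-letter, 3-letter or full name) to its
    canonical single-letter code; None if the symbol is unknown."""
    s = symbol.strip()
    if len(s) == 1 and s.upper() in AA1:
        return s.upper()
    if s.capitalize() in AA3_TO_1:
        return AA3_TO_1[s.capitalize()]
    low = s.lower()
    if low in AA_FULL_TO_1:
        return AA_FULL_TO_1[low]
    if low in BASE_FULL_TO_1:
        return BASE_FULL_TO_1[low]
    if s in STOP_SYMBOLS:
        return "X"
    return None


# ---------------------------------------------------------------------------
# Closed-class word lists for the tagger

DETERMINERS = {
    "the", "a", "an", "this", "that", "these", "those", "its", "their",
    "our", "his", "her", "each", "every", "no", "any", "some", "all",
    "both", "several", "such", "another", "other", "one",
}

PREPOSITIONS = {
    "of", "in", "on", "for", "with", "from", "by", "at", "as", "between",
    "among", "after", "before", "during", "against", "via", "within",
    "without", "under", "over", "than", "into", "upon", "through",
    "towards", "toward", "across", "per", "like",
}

CONJUNCTIONS = {"and", "or", "and/or", "nor", "but", "while", "whereas"}

PRONOUNS = {"we", "they", "it", "he", "she", "i", "you", "who", "which", "that"}

MODALS = {"may", "might", "can", "could", "will", "would", "shall", "should", "must"}

BE_FORMS = {"be", "is", "are", "was", "were", "been", "being", "am"}
HAVE_FORMS = {"have", "has", "had", "having"}
DO_FORMS = {"do", "does", "did"}
GET_FORMS = {"get", "gets", "got", "gotten", "getting"}
AUXILIARIES = BE_FORMS | HAVE_FORMS | DO_FORMS | GET_FORMS

NEGATIONS = {"not", "n't", "never"}

COMMON_ADVERBS = {
    "not", "also", "significantly", "statistically", "usually", "often",
    "still", "again", "here", "thus", "however", "moreover", "furthermore",
    "respectively", "together", "only", "already", "previously", "more",
    "less", "most", "least", "very", "too",
}

# ---------------------------------------------------------------------------
# Verb lexicon.  Limited to verbs that matter for chunking/voice/patterns so
# that noun/verb homographs ("control", "study" as nouns) stay nominal.

_VERB_STEMS = [
    "associate", "appear", "detect", "identify", "analyze", "analyse",
    "screen", "find", "show", "see", "observe", "report", "investigate",
    "examine", "study", "compare", "correlate", "contribute", "relate",
    "link", "increase", "decrease", "reduce", "promote", "lead", "yield",
    "suggest", "indicate", "demonstrate", "reveal", "conclude", "perform",
    "conduct", "use", "apply", "include", "evaluate", "assess", "measure",
    "genotype", "sequence", "test", "confirm", "describe", "mention",
    "extract", "match", "truncate", "result", "involve", "affect",
    "cause", "predict", "occur", "remain", "become", "carry", "harbor",
    "enroll", "recruit", "follow", "assign", "consider", "determine",
    "take", "give", "know", "make", "provide", "present", "display",
    "exhibit", "express", "play", "serve",
]

_IRREGULAR = {
    "find": {"past": "found", "part": "found"},
    "show": {"part": "shown"},
    "see": {"past": "saw", "part": "seen"},
    "lead": {"past": "led", "part": "led"},
    "take": {"past": "took", "part": "taken"},
    "give": {"past": "gave", "part": "given"},
    "know": {"past": "knew", "part": "known"},
    "make": {"past": "made", "part": "made"},
    "become": {"past": "became", "part": "become"},
    "occur": {"past": "occurred", "part": "occurred", "ger": "occurring"},
    "enroll": {"past": "enrolled", "part": "enrolled", "ger": "enrolling"},
}

_VOWELS = set("aeiou")


def _third_person(stem: str) -> str:
    if stem.endswith(("s", "x", "z", "ch", "sh")):
        return stem + "es"
    if stem.endswith("y") and stem[-2] not in _VOWELS:
        return stem[:-1] + "ies"
    return stem + "s"


def _past(stem: str) -> str:
    if stem.endswith("e"):
        return stem + "d"
    if stem.endswith("y") and stem[-2] not in _VOWELS:
        return stem[:-1] + "ied"
    return stem + "ed"


def _gerund(stem: str) -> str:
    if stem.endswith("e") and not stem.endswith(("ee", "ye")):
        return stem[:-1] + "ing"
    return stem + "ing"


def _build_verb_forms() -> dict[str, tuple[str, str]]:
    forms: dict[str, tuple[str, str]] = {}
    for stem in _VERB_STEMS:
        irr = _IRREGULAR.get(stem, {})
        table = {
            "base": stem,
            "3sg": _third_person(stem),
            "past": irr.get("past", _past(stem)),
            "part": irr.get("part", _past(stem)),
            "ger": irr.get("ger", _gerund(stem)),
        }
        for form, word in table.items():
            forms.setdefault(word, (stem, form))
    return forms


#: surface form -> (stem, form); form in {base, 3sg, past, part, ger}
VERB_FORMS = _build_verb_forms()

#: all past-participle surface forms (voice detection)
PAST_PARTICIPLES = {w for w, (_, f) in VERB_FORMS.items() if f in ("past", "part")}

# ---------------------------------------------------------------------------
# Lexeme variant families for pattern matching.  Patterns name a lexeme
# ("associate") and must match its inflectional and derivational variants
# ("associated", "association").  A suffix-family table keeps this
# deterministic and auditable; it is not a lemmatizer.

_DERIVED = {
    "associate": ["association", "associations"],
    "correlate": ["correlation", "correlations"],
    "contribute": ["contribution", "contributions"],
    "compare": ["comparison", "comparisons"],
    "detect": ["detection", "detections"],
    "identify": ["identification", "identifications"],
    "analyze": ["analysis", "analyses", "analysed", "analyse", "analysing"],
    "analyse": ["analysis", "analyses", "analyzed", "analyze", "analyzing"],
    "screen": ["screening", "screenings"],
    "relate": ["relation", "relations", "relationship", "relationships"],
    "relationship": ["relationships", "relation", "relations"],
    "effect": ["effects"],
    "difference": ["differences"],
    "find": ["finding", "findings"],
    "observe": ["observation", "observations"],
    "examine": ["examination", "examinations"],
    "investigate": ["investigation", "investigations"],
}


@lru_cache(maxsize=None)
def lexeme_variants(lexeme: str) -> frozenset[str]:
    lexeme = lexeme.lower()
    out = {lexeme}
    if lexeme in VERB_FORMS and VERB_FORMS[lexeme][1] == "base" or lexeme in _VERB_STEMS:
        stem = lexeme
    else:
        stem = VERB_FORMS.get(lexeme, (lexeme, None))[0]
    # inflections
    irr = _IRREGULAR.get(stem, {})
    out.update({
        stem,
        _third_person(stem),
        irr.get("past", _past(stem)),
        irr.get("part", _past(stem)),
        irr.get("ger", _gerund(stem)),
    })
    # plain plural for noun lexemes
    out.add(_third_person(lexeme))
    out.update(_DERIVED.get(lexeme, []))
    out.update(_DERIVED.get(stem, []))
    return frozenset(out)


def matches_lexeme(word: str, lexeme: str) -> bool:
    return word.lower() in lexeme_variants(lexeme)


# ---------------------------------------------------------------------------
# Domain word lists shared by several modules

#: heads that mark an NP as mutation-denoting even without a specific mention
MUTATION_TERMS = {
    "mutation", "mutations", "polymorphism", "polymorphisms",
    "variant", "variants", "variation", "variations",
    "mutant", "mutants", "alteration", "alterations",
    "snp", "snps", "allele", "alleles", "genotype", "genotypes",
    "substitution", "substitutions", "deletion", "deletions",
    "insertion", "insertions",
}

#: mutation-specific terms forming a gene-mutation pairing (narrower set)
PAIRING_TERMS = {
    "variant", "variants", "mutant", "mutants", "variation", "variations",
    "mutation", "mutations", "polymorphism", "polymorphisms",
    "alteration", "alterations", "snp", "snps",
}

#: bare generic disease words eligible for nearest-specific resolution
GENERIC_DISEASE_TERMS = {
    "tumor", "tumors", "tumour", "tumours", "cancer", "cancers",
    "carcinoma", "carcinomas", "disease", "diseases", "malignancy",
    "malignancies",
}
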