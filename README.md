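# medlex

A toolkit for building and using a **concept-anchored medical lexicon for
Spanish clinical NLP**. Each lexical entry ties a lemma and its inflected
surface forms (gender/number variants, full verb conjugations) to one or
more UMLS Concept Unique Identifiers (CUIs, `C` + 7 digits) with their
semantic types and groups (ANAT, CHEM, DISO, PROC, ...), so that synonymous
terms — *viriasis* / *viriosis*, *EV* / *enterovirus*, *hígado* / *hepático* —
cluster under the same concept. Unlike a plain gazetteer, the lexicon
carries part-of-speech and morphology, which makes it usable for PoS
tagging, lemmatization and annotation rule development, not just string
matching.

It is aimed at biomedical text-mining practitioners who need to
pre-annotate Spanish health corpora with normalized concepts, adapt
general-purpose taggers to clinical vocabulary, or maintain/extend a
terminology with new variants (spelling, derivational, word-order and
embedding-mined neologisms).

## What is inside

| module | role |
|---|---|
| `lexicon_core` | data model, validation, statistics; pipe-delimited DSV and Lexical Markup Framework (LMF) XML formats; Lexical Record tables |
| `morph_engine` | nominal gender/number inflection, regular `-ar/-er/-ir` conjugation with an irregular-verb exception table, word-order variants, head-word morphology for multiwords, CUI propagation across derivational pairs |
| `variant_linker` | unit-cost Levenshtein variant discovery (threshold ≤ 2), acronym/full-form linking with ambiguity flagging, affix lookup |
| `embedding_expansion` | seed-term expansion by cosine nearest neighbours, `cos(s,w) = s·w / (‖s‖‖w‖)`, depth 50, with lexicon OOV filtering |
| `annotator` | trie-based longest matching, nested/crossing entity pruning, BRAT standoff output, term frequencies |
| `tagger_lemmatizer` | lexicon override layer over any base tagger; identity-fallback lemmatization; P/R/F1 evaluation over open lexical categories with lenient lemma comparison |
| `fixtures` | deterministic synthetic lexicons, corpora and vector models (real UMLS-derived content is license-gated) |

## Worked example

```python
from medlex import *

lex = Lexicon([
    LexicalEntry("dolor", PoS.N, frozenset({"C0030193"}), semantic_group="DISO"),
    LexicalEntry("dolor de cabeza", PoS.N, frozenset({"C0018681"}), semantic_group="DISO"),
    LexicalEntry("administración de vacunas", PoS.N, frozenset({"C1533734"}), semantic_group="PROC"),
    LexicalEntry("vacunas vivas", PoS.N, frozenset({"C0042210"}), semantic_group="CHEM"),
])
text = "tuvo dolor de cabeza tras administración de vacunas vivas"
for a in annotate_document(text, lex):
    print(a.start, a.end, a.surface, a.group, sorted(a.cuis))
```

prints

```
5 20 dolor de cabeza DISO ['C0018681']
26 51 administración de vacunas PROC ['C1533734']
52 57 vivas CHEM ['C0042210']
```

Three things happened: the raw matcher found four candidate entities, the
nested pruning rule dropped *dolor* (properly contained in the more
specific *dolor de cabeza*, same group), and the crossing pair
*administración de vacunas* / *vacunas vivas* was corrected to independent
entities by splitting at the overlap boundary, leaving *vivas*.

Morphology and a few CLI equivalents:

```bash
$ medlex inflect pulmón --pos N     # → pulmón, pulmones
$ medlex inflect toser --pos V      # → tose, tosa, tosió, toserá, tosiendo, tosido, ...
$ medlex fixtures --out fx --seed 1 # synthetic lexicon + corpus + vectors
$ medlex stats fx/lexicon.dsv
lemmas: 63
forms:  371
CUIs:   63
mean lemmas/CUI: 1.00
mean forms/CUI:  5.89
```

## Formats

DSV is a six-field pipe-delimited file
(`CUI(s)|lemma|form;form;...|PoS|semantic type(s)|group`); it cannot carry
per-form morphology, so LMF-XML is the lossless interchange format — every
gender/number/person/tense/mood/variant-type attribute is encoded as an LMF
`feat` pair. See `docs/methods.md` for the full dialect description and
design rationale.

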