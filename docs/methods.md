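# Methods

This note documents the model behind the toolkit, the file dialects, the
numerical and design choices that were genuinely open, what the synthetic
fixtures do and do not emulate, and known limitations.

## The lexicon model

A `LexicalEntry` is a lemma (citation form) with a part of speech from a
nine-category set (`N, ADJ, NPR, ADJ/N, AFF, V, N/NPR, ADV, ADJ/ADV`; the
slashed categories mark context-dependent ambiguity), a set of UMLS CUIs
(`C` + 7 digits), semantic types and one semantic group, and a set of
`WordForm`s. Each form carries morphological features: grammatical gender
(`commonGender / masculine / feminine`), number
(`singular / plural / singular_and_plural`), and for verb forms person,
tense (`present, imperfect, past, future, conditional, presentPerfect`)
and mood (`indicative, subjunctive, imperative, infinitive, gerund,
participle`); a `variant_type` distinguishes abbreviations (*Dr.*) from
acronyms (*SIDA*). Invariants enforced at construction: the lemma is
always among the forms; verbal features appear only on verb entries; every
main-lexicon entry is concept-mapped (an explicit `allow_no_cui` flag
relaxes this for work-in-progress data). The lexicon is deliberately **not
an ontology**: no is_a or other inter-concept relations are modelled.

Entries sharing `(lemma, pos, cuis)` are merged by form-set union on
insertion; merging is idempotent and commutative, and merge counts are
reported rather than silently dropping duplicates.

## File dialects

**DSV.** Six pipe-delimited fields:
`CUI(s) | lemma | forms | PoS | semantic type(s) | group`. The pipe
delimiter follows the MRCONSO.RRF tradition for this kind of file and is
configurable; semicolons separate multiple values inside a field (several
CUIs per entry are real — the body-part sense of *radio* carries both
C0034627 and C1279083). Six fields cannot carry per-form morphology, so
**DSV is lossy on morphology by design** and the round-trip identity
guarantee for DSV is stated on the morphology-free projection of the
lexicon. Writing is deterministic: entries sorted by (smallest CUI, lemma),
forms in codepoint order with the citation form first.

**LMF-XML.** The lossless format. Standard Lexical Markup Framework
elements (`LexicalResource / Lexicon / LexicalEntry / Lemma / WordForm /
Sense`) with all attributes as `feat` name/value pairs
(`grammaticalGender`, `grammaticalNumber`, `person`, `grammaticalTense`,
`verbFormMood`, `variantType`, `cui`, `semanticType`, `semanticGroup`).
Affix entries additionally carry an `attachment` feature (`prefix` for
*reno-*, `suffix` for *-cilina*) derived from the hyphen position.

**Lexical Records.** Two/three-column delimited tables:
abbreviation ↔ full form, affix ↔ gloss (optional CUI; the affix must carry
its attachment hyphen), deverbal noun ↔ verb, denominal adjective ↔ noun.

All text is NFC-normalized on load so accent comparisons are stable.

## Morphology generation

*Nominal inflection.* Adjective-like lemmas in the regular `-o` paradigm
yield four gender/number forms (*-scópico, -scópica, -scópicos,
-scópicas*); other lemmas yield singular/plural with their lexical gender.
Pluralization: unstressed vowel → `+s`; stressed `-í/-ú` → `+es`;
`-z` → `-ces`; paroxytones in `-s/-x` are number-invariant (*análisis*);
other consonants → `+es` with the now-redundant written accent dropped by
an explicit rewrite (*pulmón → pulmones*). Lemmas marked
`singular_and_plural` (*diabetes*) stay invariant. Prefix affixes
(*reno-*) do not inflect.

*Conjugation.* Regular `-ar/-er/-ir` paradigms fill the full grid:
indicative present/imperfect/preterite/future/conditional, present
subjunctive, second-person imperative, present perfect (auxiliary *haber* +
masculine-singular participle), infinitive, gerund and the four participle
variants. Orthography-preserving stem rules cover `-car/-gar/-zar` before
*e* (*diagnostiqué*), `-ger/-gir` before *a/o* (*protejo*) and the *i → y*
shift after vowel-final stems (*creyendo*). Everything else goes through a
maintainable exception table shipped as a TSV data file (`doler`, `morir`,
`sentir` are included as worked irregulars); an override maps a cell key
like `indicative.present.3s` to its surface. This rule-plus-exceptions
engine is a deliberate design choice: it reproduces the observable
behaviour of conjugation-by-lookup on regular verbs without depending on
any licensed tagger lexicon. Pronominal infinitives (*atragantarse*) are
conjugated on their base; clitic pronouns are **not** included in generated
surfaces (the present-perfect cell stores `has atragantado`, not *te has
atragantado*) — pronominal surfaces are a review question, not generated
data. Compound tenses beyond the present perfect and full irregular
coverage are out of scope.

*Multiwords.* Spanish noun phrases are head-initial, so the head of a
multiword term is the first token, skipping a fixed function-word list
(`de, del, la, el, en, para, por, con, y`), that the lexicon knows as a
noun/proper noun; its category and gender/number label the whole term
(*síndrome de Asperger* → noun, masculine, singular). Unresolvable heads
raise an error so the term is routed to review instead of being guessed.
Word-order variants swap adjacent non-function post-head modifiers and are
emitted as review proposals, never auto-accepted.

*Concept propagation* unions CUI sets across derivational pairs
(noun ↔ adjective, noun ↔ deverbal verb) and copies types/group onto the
previously unmapped entry; it is idempotent and records a `DerivationLink`.

## Variant discovery and linking

Edit distance is unit-cost Levenshtein on NFC strings, case-sensitive by
default, with spaces and hyphens as ordinary characters — this keeps the
three beta-blocker tokenization variants (*betabloqueante /
beta-bloqueante / beta bloqueante*) pairwise within distance 2. An
optional accent-folding flag exists but defaults off, because the variant
pairs this step targets differ by letters and hyphens, not accents. The
threshold (default 2) applies to the whole string, not per token.
Candidates are returned as `proposed` pairs carrying the known term's CUIs;
**no pair is ever auto-accepted** — status transitions belong to an
explicit review file, preserving the audit trail of the manual revision
this procedure requires.

Acronym linking is bidirectional (short → full and full → short CUI
propagation) and flags short forms that resolve to more than one concept
(*IM*) while letting unambiguous, language-invariant items (*kg*) pass
without a flag. Context-based disambiguation is explicitly out of scope:
flagging only.

## Embedding expansion

Vectors are consumed from the plain-text word2vec format (header
`vocab dim`); no training happens in-repo since the training corpora are
not redistributable. Nearest-neighbour retrieval is exact (full-vocabulary
cosine scan), depth k = 50 by default — shallow neighbourhoods are
dominated by misspellings of the seed itself. Ties on similarity break by
codepoint order (a documented arbitrary choice). OOV filtering against the
lexicon matches case-folded NFC surfaces, since uncased embedding models
are common. The report exposes both the raw OOV count (what the headline
~70 % OOV-rate style figure is computed on) and the deduplicated token
list, because whether repeated neighbours across seeds should be counted
once is genuinely open; a `reference_cuis` mapping file stands in for the
manual UMLS lookup of candidates so the mappable-fraction step is
reproducible and auditable.

## Pre-annotation

Matching is a token-sequence trie over all (group-filtered) lexicon forms.
Non-acronym forms are indexed case-folded; acronym-typed forms are indexed
case-sensitively so *EV* never fires on *ev*. Offsets are 0-based,
end-exclusive, and the tokenizer (word runs with intra-token hyphens kept
whole, punctuation split off) is shared with the embedding-corpus
normalizer so the two pipelines agree. `match_all` reports **every**
dictionary match, overlapping and ambiguous alike, with all candidate CUIs
(the *radio* problem is resolved by human revision, not by the toolkit).
Pruning then (1) removes annotations properly contained in a longer
annotation of the same group, and (2) corrects crossing pairs to
independent entities. The exact correction algorithm for crossing spans is
not standardized anywhere; the implemented choice is to truncate the
later-starting span to begin where the earlier one ends (so
*administración de vacunas* + *vacunas vivas* becomes *administración de
vacunas* + *vivas*), iterated to a fixpoint. After pruning, no same-group
proper nesting and no crossing pairs remain — both properties are checked
exhaustively in the tests.

## Tagging, lemmatization, evaluation

The base tagger is an injected callable (the layer over an existing tagger
is the contribution; a trivial all-`OTHER` base ships for dependency-free
use). A lexicon form with a single lexical category overrides the base tag
(N→NOUN, NPR→PROPN, V→VERB, ADJ→ADJ, ADV→ADV); ambiguous categories
(ADJ/N, N/NPR, ADJ/ADV) defer to the base tag when compatible — context
decides participle/adjective cases like *ulcerada* — and otherwise take
the first alternative (the mapping of slashed categories to a single
evaluation tag is not standardized; defer-to-base is the documented
choice). Lemmatization is folded lookup with a PoS-hint preference and,
for OOV surfaces, the identity fallback — the lemma is the surface itself,
never an invented string (the failure mode that makes seq2seq lemmatizers
produce non-words on medical compounds).

Evaluation restricts to tokens whose gold tag is an open lexical category
(ADJ, ADV, NOUN, PROPN, VERB), computes per-category one-vs-rest
precision/recall/F1 with scikit-learn, and aggregates micro (macro is also
emitted; the micro/macro choice is documented since reported averages
rarely name one). Lemma comparison is lenient: NFD accent stripping plus
case folding, nothing broader (*cardíaco* ≡ *cardiaco*); what else might
count as a "minor variation" is undefined, so nothing else is folded. In
lemma mode the per-category figure is the exact-match rate over that
category's gold tokens.

## Synthetic fixtures

The generators emulate the *structural* properties the algorithms depend
on, not the content or statistics of any real lexicon. Pseudo-Spanish
lemmas are built from CV/CVC syllable templates so the inflection rules
apply naturally; CUIs are unique synthetic codes; the lexicon plants
duplicates (merge handling), multiwords with known noun heads, acronym
pairs mirrored in an abbreviation record, distance-1 spelling variants,
and nested plus crossing multiword pairs for the pruning rules. Corpora
embed forms at recorded offsets among filler tokens guaranteed absent from
the lexicon, so gold spans equal document slices by construction. Vector
models plant, per seed, a fixed number of synonyms at cosine > 0.95 with
distractors below 0.5 and seeds mutually below 0.4. Everything is a pure
function of a `FixtureSpec`; the same seed regenerates byte-identical
files.

Consequently, passing tests demonstrate correctness of the machinery
(parsing, generation, matching, pruning, retrieval, scoring) under clean
conditions; they say nothing about coverage or ambiguity rates on real
clinical Spanish, where surface collisions, spelling noise and
out-of-lexicon vocabulary dominate error budgets.

Problem sizes used by the default suite and the acceptance script —
100 round-trip lexicons of ~10 concepts, a 260-concept closure lexicon
(~2000 generated forms), a 2000-token vector model with 20 seeds × 5
planted synonyms at depth 50, ~10-document corpora plus a dense
overlap document, 100 nearest-neighbour oracle queries over a
1000-token vocabulary — were chosen so the whole cycle completes in
seconds while every code path and invariant is still exercised at
non-trivial scale.

## Numerical and degenerate-input choices

* Unicode: NFC everywhere on load; case folding via `str.casefold`;
  accent stripping via NFD mark removal.
* Statistics: per-CUI means and percentages rounded to two decimals;
  PoS percentages sum to 100 ± 0.1; an empty lexicon raises an explicit
  error instead of dividing by zero.
* Cosine similarity on a zero vector is an error, not 0 or NaN.
* Single-token input to word-order variant generation yields the empty
  set (not an error); function-word-only multiwords raise an
  unresolved-head error.
* Deterministic ordering: entries by (CUI, lemma), forms and neighbour
  ties by codepoint order.

## Known limitations

* Spanish morphology coverage is deliberately partial: no clitic
  handling, no compound tenses beyond the present perfect, irregular
  verbs only as far as the exception table reaches.
* The crossing-entity correction truncates rather than re-running the
  matcher on the residue; a residue that is itself a shorter lexicon form
  is not re-annotated.
* Acronym ambiguity is flagged, never resolved.
* The DSV format cannot round-trip morphology (use LMF).
* No embedding training, corpus crawling, or visualization; vectors and
  corpora are inputs.
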