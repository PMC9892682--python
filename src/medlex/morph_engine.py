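"""Inflection, conjugation and concept propagation.

Medical events surface both as nouns (*sangrado*) and verbs (*sangrar*), and
Spanish nominal terms inflect for gender and number, so a concept-anchored
lexicon must carry inflected variants and share CUIs across derivationally
related lemmas.  This module generates:

* gender/number variants of nouns, adjectives and affixes (``inflect_nominal``),
* full regular conjugation tables for -ar/-er/-ir verbs with an exception
  table for irregulars (``conjugate_verb``),
* word-order variants of multiword terms (``generate_word_order_variants``),
* head-word morphology for multiword terms (``assign_multiword_morphology``),

and propagates CUIs between related entries (``propagate_concept``), e.g.
*hígado* (N) ↔ *hepático* (ADJ) both carrying C0023884.

Conjugation covers the tense/mood grid of the lexicon's morphological
schema: indicative present / imperfect / past (preterite) / future /
conditional / present perfect, present subjunctive, second-person
imperative, and the nonfinite forms (infinitive, gerund, participle with its
four gender/number variants).  Compound tenses beyond the present perfect,
and clitic pronouns, are out of scope; pronominal infinitives (-arse) are
conjugated on their base without the pronoun.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

from .lexicon_core import (
    Gender,
    LexicalEntry,
    Lexicon,
    MedLexError,
    Mood,
    MorphFeatures,
    Number,
    Person,
    PoS,
    Tense,
    WordForm,
    nfc,
)

logger = logging.getLogger("medlex")

#: Function words skipped when locating the head of a Spanish noun phrase
#: (head-initial: *síndrome de Asperger* → head *síndrome*).
FUNCTION_WORDS = frozenset({"de", "del", "la", "el", "en", "para", "por", "con", "y"})

VOWELS = "aeiouáéíóú"
ACCENTED = {"á": "a", "é": "e", "í": "i", "ó": "o", "ú": "u"}


class WrongCategoryError(MedLexError):
    """An inflection operation received an incompatible part of speech."""


class UnconjugatableError(MedLexError):
    """A lemma is neither verb-shaped (-ar/-er/-ir) nor in the exception table."""


class UnresolvedHeadError(MedLexError):
    """No token of a multiword term resolves to a known noun head."""


# ---------------------------------------------------------------------------
# Nominal inflection (gender / number)
# ---------------------------------------------------------------------------

def _deaccent_final_syllable(word: str) -> str:
    """Drop the written accent that becomes redundant when adding -es.

    *pulmón* → *pulmon* (then + *es*): the stress stays on the same syllable
    but no longer needs a tilde once the word ends in -es.
    """
    for i in range(len(word) - 1, -1, -1):
        if word[i] in ACCENTED:
            return word[:i] + ACCENTED[word[i]] + word[i + 1:]
        if word[i] in "aeiou":
            break
    return word


def pluralize(singular: str) -> str:
    """Regular Spanish plural of a single orthographic word."""
    w = nfc(singular)
    if not w:
        return w
    last = w[-1]
    if last in "aeiouáéó":
        return w + "s"
    if last in "íú":
        return w + "es"
    if last == "z":
        return w[:-1] + "ces"
    if last in "sx":
        # vowel+s with final-syllable stress (interés) takes -es; otherwise
        # the word is number-invariant (diabetes) and handled upstream
        if len(w) >= 2 and w[-2] in ACCENTED:
            return _deaccent_final_syllable(w) + "es"
        return w
    return _deaccent_final_syllable(w) + "es"


def _feminine_of(masculine: str) -> str | None:
    """Feminine counterpart for the regular -o paradigm, else ``None``."""
    if masculine.endswith("o"):
        return masculine[:-1] + "a"
    return None


def inflect_nominal(
    lemma: str, pos: PoS, morph: MorphFeatures = MorphFeatures()
) -> set[WordForm]:
    """Generate gender/number variants of a nominal or adjectival lemma.

    Adjectives, adjective-like affixes and slashed adjectival categories in
    the regular -o paradigm yield four forms (*-scópico, -scópica, -scópicos,
    -scópicas*); nouns keep their lexical gender and yield singular/plural;
    lemmas marked ``singular_and_plural`` (e.g. *diabetes*) stay invariant.
    Affix lemmas keep their attachment hyphen.  The lemma itself is returned
    as the citation form.
    """
    lemma = nfc(lemma).strip()
    if not lemma:
        raise MedLexError("empty lemma")
    if pos not in {PoS.N, PoS.ADJ, PoS.ADJ_N, PoS.AFF, PoS.NPR, PoS.N_NPR, PoS.ADJ_ADV}:
        raise WrongCategoryError(
            f"inflect_nominal cannot inflect {pos.value} lemma {lemma!r}"
        )

    prefix = ""
    stem = lemma
    if pos is PoS.AFF:
        if lemma.endswith("-"):  # prefix affixes (reno-) do not inflect
            return {WordForm(lemma, replace(morph, number=Number.UNSPECIFIED))}
        if lemma.startswith("-"):
            prefix, stem = "-", lemma[1:]

    if morph.number is Number.SINGULAR_AND_PLURAL:
        return {WordForm(lemma, morph)}

    gender = morph.gender
    adjectival = pos in {PoS.ADJ, PoS.ADJ_N, PoS.AFF, PoS.ADJ_ADV}
    out: set[WordForm] = set()

    def add(surface: str, g: Gender, n: Number) -> None:
        out.add(WordForm(prefix + surface, replace(morph, gender=g, number=n)))

    feminine = _feminine_of(stem) if adjectival else None
    if feminine is not None:
        add(stem, Gender.MASCULINE, Number.SINGULAR)
        add(feminine, Gender.FEMININE, Number.SINGULAR)
        add(pluralize(stem), Gender.MASCULINE, Number.PLURAL)
        add(pluralize(feminine), Gender.FEMININE, Number.PLURAL)
    else:
        g = gender if gender is not Gender.UNSPECIFIED else (
            Gender.COMMON if adjectival else Gender.UNSPECIFIED
        )
        plural = pluralize(stem)
        if plural == stem:  # s/x-final paroxytones are number-invariant
            add(stem, g, Number.SINGULAR_AND_PLURAL)
        else:
            add(stem, g, Number.SINGULAR)
            add(plural, g, Number.PLURAL)
    return out


# ---------------------------------------------------------------------------
# Verb conjugation
# ---------------------------------------------------------------------------

_PERSONS = [
    (Person.FIRST, Number.SINGULAR, "1s"),
    (Person.SECOND, Number.SINGULAR, "2s"),
    (Person.THIRD, Number.SINGULAR, "3s"),
    (Person.FIRST, Number.PLURAL, "1p"),
    (Person.SECOND, Number.PLURAL, "2p"),
    (Person.THIRD, Number.PLURAL, "3p"),
]

# person-ending tables per conjugation class, in 1s..3p order
_ENDINGS: dict[str, dict[tuple[Tense, Mood], list[str]]] = {
    "ar": {
        (Tense.PRESENT, Mood.INDICATIVE): ["o", "as", "a", "amos", "áis", "an"],
        (Tense.IMPERFECT, Mood.INDICATIVE): ["aba", "abas", "aba", "ábamos", "abais", "aban"],
        (Tense.PAST, Mood.INDICATIVE): ["é", "aste", "ó", "amos", "asteis", "aron"],
        (Tense.PRESENT, Mood.SUBJUNCTIVE): ["e", "es", "e", "emos", "éis", "en"],
    },
    "er": {
        (Tense.PRESENT, Mood.INDICATIVE): ["o", "es", "e", "emos", "éis", "en"],
        (Tense.IMPERFECT, Mood.INDICATIVE): ["ía", "ías", "ía", "íamos", "íais", "ían"],
        (Tense.PAST, Mood.INDICATIVE): ["í", "iste", "ió", "imos", "isteis", "ieron"],
        (Tense.PRESENT, Mood.SUBJUNCTIVE): ["a", "as", "a", "amos", "áis", "an"],
    },
    "ir": {
        (Tense.PRESENT, Mood.INDICATIVE): ["o", "es", "e", "imos", "ís", "en"],
        (Tense.IMPERFECT, Mood.INDICATIVE): ["ía", "ías", "ía", "íamos", "íais", "ían"],
        (Tense.PAST, Mood.INDICATIVE): ["í", "iste", "ió", "imos", "isteis", "ieron"],
        (Tense.PRESENT, Mood.SUBJUNCTIVE): ["a", "as", "a", "amos", "áis", "an"],
    },
}

_FUTURE = ["é", "ás", "á", "emos", "éis", "án"]       # infinitive + ending
_CONDITIONAL = ["ía", "ías", "ía", "íamos", "íais", "ían"]
_HABER_PRESENT = ["he", "has", "ha", "hemos", "habéis", "han"]
_IMPERATIVE_2P = {"ar": "ad", "er": "ed", "ir": "id"}

CellKey = tuple[Person, Number, Tense, Mood]


@dataclass
class ConjugationTable:
    """Conjugated forms of one verb lemma.

    ``cells`` maps (person, number, tense, mood) to a surface; ``nonfinite``
    holds the infinitive, gerund and the four gender/number participle
    variants.  Every surface derives from the lemma by the regular rules or
    an exception-table override.
    """

    lemma: str
    cells: dict[CellKey, str] = field(default_factory=dict)
    nonfinite: dict[Mood, tuple[str, ...]] = field(default_factory=dict)

    def word_forms(self) -> set[WordForm]:
        """All conjugated surfaces tagged with their full features."""
        out: set[WordForm] = set()
        for (person, number, tense, mood), surface in self.cells.items():
            out.add(WordForm(surface, MorphFeatures(
                number=number, person=person, tense=tense, mood=mood)))
        out.add(WordForm(self.nonfinite[Mood.INFINITIVE][0],
                         MorphFeatures(mood=Mood.INFINITIVE)))
        out.add(WordForm(self.nonfinite[Mood.GERUND][0],
                         MorphFeatures(mood=Mood.GERUND)))
        participles = self.nonfinite[Mood.PARTICIPLE]
        part_feats = [
            (Gender.MASCULINE, Number.SINGULAR), (Gender.FEMININE, Number.SINGULAR),
            (Gender.MASCULINE, Number.PLURAL), (Gender.FEMININE, Number.PLURAL),
        ]
        for surface, (g, n) in zip(participles, part_feats):
            out.add(WordForm(surface, MorphFeatures(
                gender=g, number=n, mood=Mood.PARTICIPLE)))
        return out

    def surfaces(self) -> set[str]:
        return {wf.surface for wf in self.word_forms()}


def _orthographic_stem(stem: str, conj: str, ending: str) -> str:
    """Spelling-preserving stem adjustments at the stem/ending boundary.

    -car/-gar/-zar keep their consonant sound before e (saqué-type: c→qu,
    g→gu, z→c); -ger/-gir soften before a/o (protejo-type: g→j).
    """
    if not ending:
        return stem
    first = ending[0]
    if conj == "ar" and first in "eé":
        if stem.endswith("c"):
            return stem[:-1] + "qu"
        if stem.endswith("g"):
            return stem + "u"
        if stem.endswith("z"):
            return stem[:-1] + "c"
    if conj in ("er", "ir") and first in "aoó":
        if stem.endswith("g"):
            return stem[:-1] + "j"
    return stem


def _i_to_y(stem: str, ending: str) -> str:
    """Vowel-final -er/-ir stems turn unstressed i into y (creyendo-type)."""
    if stem and stem[-1] in "aeou" and ending and ending[0] == "i":
        return "y" + ending[1:]
    return ending


def _load_exception_table() -> dict[str, dict[str, str]]:
    """Irregular-verb overrides shipped as a delimited data file.

    Rows: ``lemma<TAB>cell<TAB>surface`` where cell is either
    ``mood.tense.PN`` (e.g. ``indicative.present.3s``) or one of
    ``gerund`` / ``participle``.
    """
    table: dict[str, dict[str, str]] = {}
    data = resources.files("medlex.data").joinpath("irregular_verbs.tsv").read_text("utf-8")
    for line in data.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lemma, cell, surface = line.split("\t")
        table.setdefault(nfc(lemma), {})[cell] = nfc(surface)
    return table


_EXCEPTIONS: dict[str, dict[str, str]] | None = None


def _exceptions() -> dict[str, dict[str, str]]:
    global _EXCEPTIONS
    if _EXCEPTIONS is None:
        _EXCEPTIONS = _load_exception_table()
    return _EXCEPTIONS


def conjugate_verb(
    lemma: str, exceptions: Mapping[str, Mapping[str, str]] | None = None
) -> ConjugationTable:
    """Conjugate a Spanish verb by the regular -ar/-er/-ir paradigms.

    Pronominal infinitives (*atragantarse*) are conjugated on their base
    without clitic pronouns.  Cells of verbs listed in the exception table
    (shipped with the package, or passed explicitly) override the regular
    output.  A lemma that is not verb-shaped and has no exception entry
    raises :class:`UnconjugatableError`.
    """
    lemma = nfc(lemma).strip()
    overrides_all = dict(_exceptions())
    if exceptions:
        for verb, cells in exceptions.items():
            overrides_all.setdefault(nfc(verb), {}).update(cells)
    overrides = overrides_all.get(lemma, {})

    base = lemma
    if base.endswith("se") and base[:-2].endswith(("ar", "er", "ir")):
        base = base[:-2]
    if base.endswith(("ar", "er", "ir")):
        conj = base[-2:]
        stem = base[:-2]
    elif overrides:
        conj, stem = "ar", base  # shape irrelevant: every cell is overridden
    else:
        raise UnconjugatableError(
            f"{lemma!r} is not an -ar/-er/-ir verb and has no exception entry"
        )

    table = ConjugationTable(lemma=lemma)

    def cell_name(mood: Mood, tense: Tense, pn: str) -> str:
        return f"{mood.value}.{tense.value}.{pn}"

    # simple finite tenses
    for (tense, mood), endings in _ENDINGS[conj].items():
        for (person, number, pn), ending in zip(_PERSONS, endings):
            ending = _i_to_y(stem, ending)
            surface = _orthographic_stem(stem, conj, ending) + ending
            surface = overrides.get(cell_name(mood, tense, pn), surface)
            table.cells[(person, number, tense, mood)] = surface

    # future and conditional build on the infinitive
    for tense, endings in ((Tense.FUTURE, _FUTURE), (Tense.CONDITIONAL, _CONDITIONAL)):
        for (person, number, pn), ending in zip(_PERSONS, endings):
            surface = overrides.get(
                cell_name(Mood.INDICATIVE, tense, pn), base + ending
            )
            table.cells[(person, number, tense, Mood.INDICATIVE)] = surface

    # nonfinite forms
    if conj == "ar":
        gerund, part = stem + "ando", stem + "ado"
    else:
        ger_ending = _i_to_y(stem, "iendo")
        part_ending = _i_to_y(stem, "ido")
        gerund, part = stem + ger_ending, stem + part_ending
    gerund = overrides.get("gerund", gerund)
    part = overrides.get("participle", part)
    table.nonfinite[Mood.INFINITIVE] = (base,)
    table.nonfinite[Mood.GERUND] = (gerund,)
    if part.endswith("o"):
        fem = part[:-1] + "a"
        table.nonfinite[Mood.PARTICIPLE] = (part, fem, part + "s", fem + "s")
    else:
        table.nonfinite[Mood.PARTICIPLE] = (part,) * 4

    # present perfect: haber (present) + masculine singular participle
    for (person, number, pn), aux in zip(_PERSONS, _HABER_PRESENT):
        surface = overrides.get(
            cell_name(Mood.INDICATIVE, Tense.PRESENT_PERFECT, pn),
            f"{aux} {part}",
        )
        table.cells[(person, number, Tense.PRESENT_PERFECT, Mood.INDICATIVE)] = surface

    # imperative: second person only
    imp_2s = table.cells[(Person.THIRD, Number.SINGULAR, Tense.PRESENT, Mood.INDICATIVE)]
    imp_2s = overrides.get(cell_name(Mood.IMPERATIVE, Tense.PRESENT, "2s"), imp_2s)
    imp_2p = overrides.get(
        cell_name(Mood.IMPERATIVE, Tense.PRESENT, "2p"), stem + _IMPERATIVE_2P[conj]
    )
    table.cells[(Person.SECOND, Number.SINGULAR, Tense.PRESENT, Mood.IMPERATIVE)] = imp_2s
    table.cells[(Person.SECOND, Number.PLURAL, Tense.PRESENT, Mood.IMPERATIVE)] = imp_2p

    return table


# ---------------------------------------------------------------------------
# Concept propagation across derivationally related lemmas
# ---------------------------------------------------------------------------

class DerivationRelation(str, Enum):
    NOUN_VERB = "noun_verb"
    ADJ_NOUN = "adj_noun"


@dataclass(frozen=True)
class DerivationLink:
    """A recorded derivational pair whose entries now share CUIs."""

    source_lemma: str
    target_lemma: str
    relation: DerivationRelation
    shared_cuis: frozenset[str]


def propagate_concept(
    entry_a: LexicalEntry,
    entry_b: LexicalEntry,
    links: list[DerivationLink] | None = None,
) -> tuple[LexicalEntry, LexicalEntry]:
    """Share CUIs between two derivationally related entries.

    Both returned entries carry the union of the CUI sets; semantic types
    and group are copied onto the entry that lacked them.  If neither entry
    has a CUI the pair is returned unchanged with a warning.  Idempotent.
    A :class:`DerivationLink` is appended to *links* when provided.
    """
    if not entry_a.cuis and not entry_b.cuis:
        warnings.warn(
            f"neither {entry_a.lemma!r} nor {entry_b.lemma!r} has a CUI; "
            "nothing to propagate",
            stacklevel=2,
        )
        return entry_a, entry_b
    shared = entry_a.cuis | entry_b.cuis
    types = entry_a.semantic_types | entry_b.semantic_types
    group = entry_a.semantic_group or entry_b.semantic_group
    new_a = replace(entry_a, cuis=shared, semantic_types=types,
                    semantic_group=entry_a.semantic_group or group)
    new_b = replace(entry_b, cuis=shared, semantic_types=types,
                    semantic_group=entry_b.semantic_group or group)
    if links is not None:
        relation = (
            DerivationRelation.NOUN_VERB
            if PoS.V in (entry_a.pos, entry_b.pos)
            else DerivationRelation.ADJ_NOUN
        )
        links.append(DerivationLink(
            source_lemma=entry_a.lemma, target_lemma=entry_b.lemma,
            relation=relation, shared_cuis=frozenset(shared),
        ))
    return new_a, new_b


# ---------------------------------------------------------------------------
# Multiword terms: word-order variants and head-word morphology
# ---------------------------------------------------------------------------

def generate_word_order_variants(
    term: str, function_words: frozenset[str] = FUNCTION_WORDS
) -> set[str]:
    """Variants of a multiword term made by swapping post-head modifiers.

    Adjacent non-function-word tokens after the head are swapped pairwise
    (*virus respiratorio sincitial* → *virus sincitial respiratorio*); the
    original term is never returned and every variant preserves the token
    multiset.  The outputs are proposals that carry the concept of the
    original term and are meant for manual review, not automatic acceptance.
    A single-token term yields the empty set.
    """
    tokens = nfc(term).split()
    if len(tokens) < 2:
        return set()
    head_idx = next(
        (i for i, t in enumerate(tokens) if t.lower() not in function_words), 0
    )
    variants: set[str] = set()
    for i in range(head_idx + 1, len(tokens) - 1):
        a, b = tokens[i], tokens[i + 1]
        if a.lower() in function_words or b.lower() in function_words:
            continue
        swapped = tokens[:i] + [b, a] + tokens[i + 2:]
        variant = " ".join(swapped)
        if variant != " ".join(tokens):
            variants.add(variant)
    return variants


def assign_multiword_morphology(
    term: str,
    lexicon: Lexicon,
    function_words: frozenset[str] = FUNCTION_WORDS,
) -> tuple[PoS, MorphFeatures]:
    """PoS and gender/number of a multiword term, taken from its head word.

    Spanish noun phrases are head-initial, so the head is the first token
    (skipping function words) that the lexicon knows as a noun or proper
    noun; its category and the gender/number of the matched form label the
    whole term (*síndrome de Asperger* → noun, masculine, singular).  Terms
    whose tokens resolve to nothing raise :class:`UnresolvedHeadError` so
    they can be routed to manual review instead of being guessed.
    """
    tokens = nfc(term).split()
    if len(tokens) < 2:
        raise MedLexError(f"{term!r} is not a multiword term")
    nounish = {PoS.N, PoS.NPR, PoS.N_NPR}
    for token in tokens:
        if token.lower() in function_words:
            continue
        candidates = [
            e for e in lexicon.by_form(token, folded=True) if e.pos in nounish
        ]
        if not candidates:
            continue
        entry = sorted(candidates, key=LexicalEntry.sort_key)[0]
        matched = next(
            (wf for wf in entry.forms
             if wf.surface.casefold() == token.casefold()),
            None,
        )
        morph = matched.morph if matched is not None else MorphFeatures()
        return entry.pos, MorphFeatures(gender=morph.gender, number=morph.number)
    raise UnresolvedHeadError(
        f"no token of {term!r} resolves to a known noun head "
        f"(tokens: {', '.join(tokens)})"
    )


def entry_with_generated_forms(entry: LexicalEntry) -> LexicalEntry:
    """Convenience: extend an entry with its rule-generated inflections."""
    if entry.pos is PoS.V:
        forms = conjugate_verb(entry.lemma).word_forms()
    elif entry.pos in {PoS.N, PoS.ADJ, PoS.ADJ_N, PoS.AFF, PoS.NPR, PoS.N_NPR}:
        base = next((wf.morph for wf in entry.forms if wf.surface == entry.lemma),
                    MorphFeatures())
        forms = inflect_nominal(entry.lemma, entry.pos, base)
    else:
        forms = set()
    return replace(entry, forms=entry.forms | frozenset(forms))
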