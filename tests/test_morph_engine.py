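"""Inflection, conjugation, concept propagation, multiword morphology."""

import pytest

from medlex import (
    Gender,
    LexicalEntry,
    Lexicon,
    Mood,
    MorphFeatures,
    Number,
    Person,
    PoS,
    Tense,
    UnconjugatableError,
    UnresolvedHeadError,
    WordForm,
    WrongCategoryError,
    assign_multiword_morphology,
    conjugate_verb,
    generate_word_order_variants,
    inflect_nominal,
    propagate_concept,
)
from medlex.morph_engine import DerivationLink, DerivationRelation, pluralize


class TestInflectNominal:
    def test_masculine_noun_singular_plural(self):
        forms = inflect_nominal("pulmón", PoS.N,
                                MorphFeatures(gender=Gender.MASCULINE))
        assert {f.surface for f in forms} == {"pulmón", "pulmones"}
        plural = next(f for f in forms if f.surface == "pulmones")
        assert plural.morph.number is Number.PLURAL

    def test_number_invariant_noun(self):
        forms = inflect_nominal(
            "diabetes", PoS.N,
            MorphFeatures(number=Number.SINGULAR_AND_PLURAL))
        assert {f.surface for f in forms} == {"diabetes"}

    def test_adjectival_affix_four_forms(self):
        forms = inflect_nominal("-scópico", PoS.AFF)
        assert {f.surface for f in forms} == {
            "-scópico", "-scópica", "-scópicos", "-scópicas"}

    def test_prefix_affix_is_invariant(self):
        forms = inflect_nominal("reno-", PoS.AFF)
        assert {f.surface for f in forms} == {"reno-"}

    def test_verb_category_rejected(self):
        with pytest.raises(WrongCategoryError):
            inflect_nominal("sangrar", PoS.V)

    @pytest.mark.parametrize("singular,plural", [
        ("hígado", "hígados"),       # unstressed vowel: +s
        ("corazón", "corazones"),    # stressed -ón: +es, tilde dropped
        ("vez", "veces"),            # -z → -ces
        ("análisis", "análisis"),    # paroxytone in -s: invariant
        ("bisturí", "bisturíes"),    # stressed -í: +es
    ])
    def test_pluralization_rules(self, singular, plural):
        assert pluralize(singular) == plural


# hand-built expected paradigms, one verb per conjugation class, used as an
# independent cross-check of the rule engine
_REGULAR_PARADIGMS = {
    "sangrar": {
        (Tense.PRESENT, Mood.INDICATIVE):
            ["sangro", "sangras", "sangra", "sangramos", "sangráis", "sangran"],
        (Tense.IMPERFECT, Mood.INDICATIVE):
            ["sangraba", "sangrabas", "sangraba", "sangrábamos", "sangrabais",
             "sangraban"],
        (Tense.PAST, Mood.INDICATIVE):
            ["sangré", "sangraste", "sangró", "sangramos", "sangrasteis",
             "sangraron"],
        (Tense.FUTURE, Mood.INDICATIVE):
            ["sangraré", "sangrarás", "sangrará", "sangraremos", "sangraréis",
             "sangrarán"],
        (Tense.CONDITIONAL, Mood.INDICATIVE):
            ["sangraría", "sangrarías", "sangraría", "sangraríamos",
             "sangraríais", "sangrarían"],
        (Tense.PRESENT, Mood.SUBJUNCTIVE):
            ["sangre", "sangres", "sangre", "sangremos", "sangréis", "sangren"],
    },
    "toser": {
        (Tense.PRESENT, Mood.INDICATIVE):
            ["toso", "toses", "tose", "tosemos", "toséis", "tosen"],
        (Tense.PAST, Mood.INDICATIVE):
            ["tosí", "tosiste", "tosió", "tosimos", "tosisteis", "tosieron"],
        (Tense.PRESENT, Mood.SUBJUNCTIVE):
            ["tosa", "tosas", "tosa", "tosamos", "tosáis", "tosan"],
    },
    "vivir": {
        (Tense.PRESENT, Mood.INDICATIVE):
            ["vivo", "vives", "vive", "vivimos", "vivís", "viven"],
        (Tense.IMPERFECT, Mood.INDICATIVE):
            ["vivía", "vivías", "vivía", "vivíamos", "vivíais", "vivían"],
        (Tense.PAST, Mood.INDICATIVE):
            ["viví", "viviste", "vivió", "vivimos", "vivisteis", "vivieron"],
    },
}

_PERSON_ORDER = [
    (Person.FIRST, Number.SINGULAR), (Person.SECOND, Number.SINGULAR),
    (Person.THIRD, Number.SINGULAR), (Person.FIRST, Number.PLURAL),
    (Person.SECOND, Number.PLURAL), (Person.THIRD, Number.PLURAL),
]


class TestConjugateVerb:
    def test_sangrar_key_cells(self):
        table = conjugate_verb("sangrar")
        assert table.cells[(Person.THIRD, Number.SINGULAR,
                            Tense.PRESENT, Mood.INDICATIVE)] == "sangra"
        assert table.nonfinite[Mood.GERUND] == ("sangrando",)
        assert table.nonfinite[Mood.PARTICIPLE][0] == "sangrado"
        # participle yields the four gender/number variants
        assert set(table.nonfinite[Mood.PARTICIPLE]) == {
            "sangrado", "sangrada", "sangrados", "sangradas"}

    def test_toser_cells_across_tenses_and_moods(self):
        surfaces = conjugate_verb("toser").surfaces()
        assert {"tose", "tosa", "tosió", "toserá", "tosería", "tosían",
                "tosiendo", "tosido"} <= surfaces

    def test_sudar_person_cells(self):
        table = conjugate_verb("sudar")
        cells = table.cells
        assert cells[(Person.FIRST, Number.SINGULAR, Tense.PRESENT,
                      Mood.INDICATIVE)] == "sudo"
        assert cells[(Person.SECOND, Number.SINGULAR, Tense.PRESENT,
                      Mood.INDICATIVE)] == "sudas"
        assert cells[(Person.THIRD, Number.SINGULAR, Tense.PRESENT,
                      Mood.INDICATIVE)] == "suda"

    @pytest.mark.parametrize("verb", sorted(_REGULAR_PARADIGMS))
    def test_regular_paradigms_match_independent_tables(self, verb):
        table = conjugate_verb(verb)
        for (tense, mood), expected in _REGULAR_PARADIGMS[verb].items():
            got = [table.cells[(p, n, tense, mood)] for p, n in _PERSON_ORDER]
            assert got == expected, (verb, tense, mood)

    def test_present_perfect_uses_auxiliary_plus_participle(self):
        table = conjugate_verb("atragantarse")
        cell = table.cells[(Person.SECOND, Number.SINGULAR,
                            Tense.PRESENT_PERFECT, Mood.INDICATIVE)]
        assert cell == "has atragantado"

    def test_orthographic_stem_adjustments(self):
        table = conjugate_verb("diagnosticar")
        assert table.cells[(Person.FIRST, Number.SINGULAR, Tense.PAST,
                            Mood.INDICATIVE)] == "diagnostiqué"
        table = conjugate_verb("proteger")
        assert table.cells[(Person.FIRST, Number.SINGULAR, Tense.PRESENT,
                            Mood.INDICATIVE)] == "protejo"

    def test_exception_table_overrides_cells(self):
        table = conjugate_verb("morir")
        assert table.cells[(Person.THIRD, Number.SINGULAR, Tense.PRESENT,
                            Mood.INDICATIVE)] == "muere"
        assert table.nonfinite[Mood.PARTICIPLE][0] == "muerto"
        assert table.nonfinite[Mood.GERUND] == ("muriendo",)

    def test_non_verb_shape_rejected(self):
        with pytest.raises(UnconjugatableError):
            conjugate_verb("pulmón")

    def test_every_cell_carries_full_features(self):
        for wf in conjugate_verb("toser").word_forms():
            morph = wf.morph
            assert morph.mood is not Mood.NONE


class TestPropagateConcept:
    def test_noun_adjective_pair_shares_cui(self):
        noun = LexicalEntry("hígado", PoS.N, frozenset({"C0023884"}),
                            frozenset({"Body Part"}), "ANAT")
        adj = LexicalEntry("hepático", PoS.ADJ)
        a, b = propagate_concept(noun, adj)
        assert a.cuis == b.cuis == {"C0023884"}
        assert b.semantic_group == "ANAT"

    def test_deverbal_pair_records_link(self):
        noun = LexicalEntry("diálisis", PoS.N, frozenset({"C4551529"}))
        verb = LexicalEntry("dializar", PoS.V)
        links: list[DerivationLink] = []
        a, b = propagate_concept(noun, verb, links)
        assert a.cuis == b.cuis == {"C4551529"}
        assert links[0].relation is DerivationRelation.NOUN_VERB

    def test_both_cui_less_is_a_warned_no_op(self):
        a = LexicalEntry("xeno", PoS.N)
        b = LexicalEntry("xénico", PoS.ADJ)
        with pytest.warns(UserWarning):
            out_a, out_b = propagate_concept(a, b)
        assert (out_a, out_b) == (a, b)

    def test_idempotent(self):
        noun = LexicalEntry("hígado", PoS.N, frozenset({"C0023884"}))
        adj = LexicalEntry("hepático", PoS.ADJ)
        a1, b1 = propagate_concept(noun, adj)
        a2, b2 = propagate_concept(a1, b1)
        assert (a1, b1) == (a2, b2)


class TestWordOrderVariants:
    def test_postnominal_modifier_swap(self):
        variants = generate_word_order_variants("virus respiratorio sincitial")
        assert "virus sincitial respiratorio" in variants

    def test_single_token_yields_empty_set(self):
        assert generate_word_order_variants("dolor") == set()

    def test_function_words_never_swapped(self):
        variants = generate_word_order_variants("dolor de cabeza")
        assert variants == set()

    @pytest.mark.parametrize("term", [
        "virus respiratorio sincitial",
        "insuficiencia cardíaca congestiva aguda",
        "cáncer de pulmón microcítico",
    ])
    def test_token_multiset_preserved_and_input_excluded(self, term):
        for variant in generate_word_order_variants(term):
            assert sorted(variant.split()) == sorted(term.split())
            assert variant != term


class TestMultiwordMorphology:
    @pytest.fixture()
    def head_lexicon(self):
        return Lexicon([
            LexicalEntry(
                "síndrome", PoS.N, frozenset({"C0039082"}),
                forms=frozenset({WordForm("síndrome", MorphFeatures(
                    gender=Gender.MASCULINE, number=Number.SINGULAR))}),
            ),
            LexicalEntry("enfermedad", PoS.N, frozenset({"C0012634"}),
                         forms=frozenset({WordForm("enfermedad", MorphFeatures(
                             gender=Gender.FEMININE, number=Number.SINGULAR))})),
        ])

    def test_head_labels_the_full_term(self, head_lexicon):
        pos, morph = assign_multiword_morphology("síndrome de Asperger",
                                                 head_lexicon)
        assert pos is PoS.N
        assert morph.gender is Gender.MASCULINE
        assert morph.number is Number.SINGULAR

    def test_category_from_head(self, head_lexicon):
        pos, _ = assign_multiword_morphology("enfermedad de Lyme", head_lexicon)
        assert pos is PoS.N

    def test_function_words_only_raises_unresolved_head(self, head_lexicon):
        with pytest.raises(UnresolvedHeadError, match="de"):
            assign_multiword_morphology("de la", head_lexicon)
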