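"""Data model, DSV/LMF formats, Lexical Records and statistics."""

import logging

import pytest
from lxml import etree

from medlex import (
    EmptyLexiconError,
    Gender,
    LexicalEntry,
    Lexicon,
    MalformedRecordError,
    MorphFeatures,
    Number,
    PoS,
    SchemaError,
    StatsReport,
    ValidationError,
    VariantType,
    WordForm,
    lexicon_stats,
    parse_dsv_record,
    read_lexical_records,
    read_lexicon,
    write_lexicon,
)
from medlex.lexicon_core import affix_attachment


class TestParseDsvRecord:
    def test_verb_record_with_conjugated_forms(self):
        line = "C0019080|sangrar|sangrar;sangra;sangrando;sangrado|V|Pathologic Function|DISO"
        entry = parse_dsv_record(line)
        assert entry.lemma == "sangrar"
        assert entry.pos is PoS.V
        assert entry.cuis == {"C0019080"}
        assert entry.surfaces == {"sangrar", "sangra", "sangrando", "sangrado"}
        assert entry.semantic_group == "DISO"

    def test_noun_record(self):
        line = "C0023884|hígado|hígado;hígados|N|Body Part, Organ, or Organ Component|ANAT"
        entry = parse_dsv_record(line)
        assert entry.surfaces == {"hígado", "hígados"}
        assert entry.semantic_types == {"Body Part, Organ, or Organ Component"}

    def test_wrong_field_count_rejected_with_line_number(self):
        with pytest.raises(MalformedRecordError, match="line 42"):
            parse_dsv_record("C0000001|x|x|N|Type", line_number=42)

    def test_unknown_pos_named_in_error(self):
        with pytest.raises(SchemaError, match="VERB"):
            parse_dsv_record("C0000001|x|x|VERB|Type|DISO")

    def test_missing_cui_rejected_unless_allowed(self):
        line = "|x|x|N|Type|DISO"
        with pytest.raises(ValidationError):
            parse_dsv_record(line)
        entry = parse_dsv_record(line, allow_no_cui=True)
        assert entry.cuis == frozenset()

    def test_duplicate_forms_deduplicated(self):
        entry = parse_dsv_record("C0000001|x|x;x;y|N|T|DISO")
        assert entry.surfaces == {"x", "y"}

    def test_multiple_cuis_in_field_one(self):
        entry = parse_dsv_record("C0034627;C1279083|radio|radio|N|Body Part|ANAT")
        assert entry.cuis == {"C0034627", "C1279083"}


class TestEntryInvariants:
    def test_lemma_always_among_forms(self):
        entry = LexicalEntry("hígado", PoS.N, frozenset({"C0023884"}),
                             forms=frozenset({WordForm("hígados")}))
        assert "hígado" in entry.surfaces

    def test_bad_cui_rejected(self):
        with pytest.raises(SchemaError):
            LexicalEntry("x", PoS.N, frozenset({"X123"}))

    def test_verbal_features_rejected_on_nouns(self):
        from medlex import Mood
        with pytest.raises(ValidationError):
            LexicalEntry("x", PoS.N, frozenset({"C0000001"}),
                         forms=frozenset({WordForm("xo", MorphFeatures(mood=Mood.GERUND))}))

    def test_merge_is_idempotent_and_commutative(self):
        a = LexicalEntry("x", PoS.N, frozenset({"C0000001"}),
                         forms=frozenset({WordForm("xs")}))
        b = LexicalEntry("x", PoS.N, frozenset({"C0000001"}),
                         forms=frozenset({WordForm("xa")}))
        assert a.merged_with(b) == b.merged_with(a)
        assert a.merged_with(a) == a


class TestLexiconIO:
    def test_duplicates_merged_on_read(self, tmp_path):
        lines = [
            "C0000001|termo|termo;termos|N|T|DISO",
            "C0000001|termo|termo;termitos|N|T|DISO",  # duplicate key
            "C0000002|otra|otra|N|T|ANAT",
        ]
        path = tmp_path / "l.dsv"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        lexicon = read_lexicon(path)
        assert len(lexicon) == 2
        assert lexicon.n_merged == 1
        merged = lexicon.by_lemma("termo")[0]
        assert merged.surfaces == {"termo", "termos", "termitos"}

    def test_empty_file_yields_empty_lexicon_with_warning(self, tmp_path, caplog):
        path = tmp_path / "empty.dsv"
        path.write_text("", encoding="utf-8")
        with caplog.at_level(logging.WARNING, logger="medlex"):
            lexicon = read_lexicon(path)
        assert len(lexicon) == 0
        assert any("empty" in r.message for r in caplog.records)

    @pytest.mark.parametrize("fmt", ["dsv", "lmf"])
    def test_round_trip_identity(self, toy_lexicon, tmp_path, fmt):
        path = tmp_path / f"lex.{fmt}"
        write_lexicon(toy_lexicon, path, fmt)
        back = read_lexicon(path, fmt)
        if fmt == "lmf":
            assert back == toy_lexicon
        else:
            # DSV carries no per-form morphology: identity on the projection
            assert back == Lexicon(
                e.without_morphology() for e in toy_lexicon)

    def test_deterministic_output(self, toy_lexicon, tmp_path):
        p1, p2 = tmp_path / "a.dsv", tmp_path / "b.dsv"
        write_lexicon(toy_lexicon, p1)
        write_lexicon(toy_lexicon, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_lmf_encodes_variant_and_category_features(self, tmp_path):
        """The diabetes concept as adjective, noun and acronym in LMF."""
        cui = frozenset({"C0011849"})
        entries = [
            LexicalEntry("diabético", PoS.ADJ, cui, semantic_group="DISO"),
            LexicalEntry("diabetes mellitus", PoS.N, cui, semantic_group="DISO"),
            LexicalEntry("dm", PoS.N, cui, semantic_group="DISO",
                         forms=frozenset({WordForm("dm", MorphFeatures(
                             variant_type=VariantType.ACRONYM))})),
        ]
        path = tmp_path / "diabetes.xml"
        write_lexicon(Lexicon(entries), path, "lmf")
        root = etree.parse(str(path)).getroot()
        lex_entries = root.findall(".//LexicalEntry")
        assert len(lex_entries) == 3
        cats = {f.get("val") for f in root.findall(".//LexicalEntry/feat")
                if f.get("att") == "partOfSpeech"}
        assert cats == {"ADJ", "N"}
        variant_feats = [f.get("val") for f in root.findall(".//WordForm/feat")
                         if f.get("att") == "variantType"]
        assert variant_feats == ["acronym"]

    def test_lmf_affix_entry_carries_attachment_side(self, tmp_path):
        entry = LexicalEntry("-cilina", PoS.AFF, frozenset({"C0030842"}),
                             semantic_group="CHEM")
        path = tmp_path / "affix.xml"
        write_lexicon(Lexicon([entry]), path, "lmf")
        root = etree.parse(str(path)).getroot()
        feats = {(f.get("att"), f.get("val"))
                 for f in root.findall(".//LexicalEntry/feat")}
        assert ("attachment", "suffix") in feats
        assert affix_attachment("reno-") == "prefix"

    def test_every_form_reachable_through_form_index(self, toy_lexicon):
        for entry in toy_lexicon:
            for wf in entry.forms:
                assert entry in toy_lexicon.by_form(wf.surface)


class TestLexicalRecords:
    def test_abbreviation_pair(self, tmp_path):
        path = tmp_path / "abr.dsv"
        path.write_text("Dr.|doctor\n", encoding="utf-8")
        records = read_lexical_records({"abbreviations": path})
        assert records.abbreviations == [("Dr.", "doctor")]

    def test_affix_rows_require_hyphen(self, tmp_path):
        path = tmp_path / "aff.dsv"
        path.write_text("cilina|penicillins\n", encoding="utf-8")
        with pytest.raises(MalformedRecordError, match="hyphen"):
            read_lexical_records({"affixes": path})

    def test_affix_optional_cui_column(self, tmp_path):
        path = tmp_path / "aff.dsv"
        path.write_text("-cilina|penicillins|C0030842\nreno-|kidney\n",
                        encoding="utf-8")
        records = read_lexical_records({"affixes": path})
        assert records.affixes == [("-cilina", "penicillins", "C0030842"),
                                   ("reno-", "kidney", None)]

    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "aff.dsv"
        path.write_text("", encoding="utf-8")
        records = read_lexical_records({"affixes": path})
        assert records.affixes == []

    def test_unknown_kind_rejected(self, tmp_path):
        path = tmp_path / "x.dsv"
        path.write_text("a|b\n", encoding="utf-8")
        with pytest.raises(SchemaError):
            read_lexical_records({"synonyms": path})


class TestStats:
    def test_hand_computed_fixture(self):
        """4 lemmas, 10 distinct (lemma, surface) pairs, 2 CUIs."""
        entries = [
            LexicalEntry("aaa", PoS.N, frozenset({"C0000001"}),
                         forms=frozenset({WordForm("aaa"), WordForm("aaas")})),
            LexicalEntry("bbb", PoS.N, frozenset({"C0000001"}),
                         forms=frozenset({WordForm("bbb"), WordForm("bbbs"),
                                          WordForm("bbbx")})),
            LexicalEntry("ccc", PoS.ADJ, frozenset({"C0000002"}),
                         forms=frozenset({WordForm("ccc"), WordForm("cccs")})),
            LexicalEntry("ddd", PoS.V, frozenset({"C0000002"}),
                         forms=frozenset({WordForm("ddd"), WordForm("ddds"),
                                          WordForm("dddx")})),
        ]
        report = lexicon_stats(Lexicon(entries))
        assert (report.n_lemmas, report.n_forms, report.n_cuis) == (4, 10, 2)
        assert report.mean_lemmas_per_cui == 2.00
        assert report.mean_forms_per_cui == 5.00

    def test_reference_scale_totals(self):
        report = StatsReport.from_counts(100_887, 302_543, 42_958)
        assert report.mean_lemmas_per_cui == 2.35
        assert report.mean_forms_per_cui == 7.04

    def test_single_entry_means_are_one(self):
        lexicon = Lexicon([LexicalEntry("x", PoS.N, frozenset({"C0000001"}))])
        report = lexicon_stats(lexicon)
        assert report.mean_lemmas_per_cui == 1.00
        assert report.mean_forms_per_cui == 1.00

    def test_pos_distribution_sums(self, toy_lexicon):
        report = lexicon_stats(toy_lexicon)
        assert sum(c for c, _ in report.pos_distribution.values()) == report.n_lemmas
        assert abs(sum(p for _, p in report.pos_distribution.values()) - 100.0) <= 0.1

    def test_empty_lexicon_is_an_explicit_error(self):
        with pytest.raises(EmptyLexiconError):
            lexicon_stats(Lexicon())
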