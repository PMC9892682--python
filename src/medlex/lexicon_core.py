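"""Core lexicon data model and interchange formats.

A medical lexicon for NLP anchors every lemma to one or more UMLS Concept
Unique Identifiers (CUIs, ``C`` + 7 digits) so that synonymous terms cluster
under the same concept, and records the linguistic data (part of speech,
inflected forms, gender/number/tense features) that plain gazetteers lack.
This module defines the in-memory model (:class:`LexicalEntry`,
:class:`Lexicon`), the two distribution formats — a pipe-delimited DSV file
and a Lexical Markup Framework (LMF) XML file — the complementary Lexical
Record tables (abbreviation, affix and derivation equivalences), validation,
and descriptive statistics.

The DSV dialect has six fields per line::

    CUI(s) | lemma | form;form;... | PoS | semantic type(s) | semantic group

Multiple CUIs or semantic types within a field are separated by semicolons.
DSV carries no per-form morphology; LMF is the lossless format.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from lxml import etree

logger = logging.getLogger("medlex")

#: Default DSV field delimiter (the file is modelled on MRCONSO.RRF).
DSV_DELIMITER = "|"
#: Separator for multiple values inside one DSV field (forms, CUIs, types).
DSV_MULTI_SEP = ";"

CUI_PATTERN = re.compile(r"^C\d{7}$")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MedLexError(Exception):
    """Base class for all toolkit errors."""


class MalformedRecordError(MedLexError):
    """A delimited record has the wrong shape (field or row count)."""


class SchemaError(MedLexError):
    """A value violates the lexicon schema (unknown PoS, bad CUI...)."""


class ValidationError(MedLexError):
    """An entry or lexicon violates a model invariant."""


class EmptyLexiconError(MedLexError):
    """An operation that needs a non-empty lexicon received an empty one."""


# ---------------------------------------------------------------------------
# Enumerations (morphological feature value sets)
# ---------------------------------------------------------------------------

class Gender(str, Enum):
    COMMON = "commonGender"
    MASCULINE = "masculine"
    FEMININE = "feminine"
    UNSPECIFIED = "unspecified"


class Number(str, Enum):
    SINGULAR = "singular"
    PLURAL = "plural"
    SINGULAR_AND_PLURAL = "singular_and_plural"
    UNSPECIFIED = "unspecified"


class Person(str, Enum):
    FIRST = "firstPerson"
    SECOND = "secondPerson"
    THIRD = "thirdPerson"
    NONE = "none"


class Tense(str, Enum):
    PRESENT = "present"
    IMPERFECT = "imperfect"
    PAST = "past"
    FUTURE = "future"
    CONDITIONAL = "conditional"
    PRESENT_PERFECT = "presentPerfect"
    NONE = "none"


class Mood(str, Enum):
    INDICATIVE = "indicative"
    SUBJUNCTIVE = "subjunctive"
    IMPERATIVE = "imperative"
    INFINITIVE = "infinitive"
    GERUND = "gerund"
    PARTICIPLE = "participle"
    NONE = "none"


class VariantType(str, Enum):
    ABBREVIATION = "abbreviation"
    ACRONYM = "acronym"
    NONE = "none"


class PoS(str, Enum):
    """The nine part-of-speech categories of the lexicon.

    Slashed categories (ADJ/N, N/NPR, ADJ/ADV) mark context-dependent
    ambiguity, e.g. *neonato* can be adjective or noun.
    """

    N = "N"
    ADJ = "ADJ"
    NPR = "NPR"
    ADJ_N = "ADJ/N"
    AFF = "AFF"
    V = "V"
    N_NPR = "N/NPR"
    ADV = "ADV"
    ADJ_ADV = "ADJ/ADV"


#: PoS categories that inflect like nouns/adjectives (gender/number).
NOMINAL_POS = frozenset({PoS.N, PoS.ADJ, PoS.ADJ_N, PoS.AFF, PoS.NPR, PoS.N_NPR})


def nfc(text: str) -> str:
    """NFC-normalize *text* so accent comparisons are stable."""
    return unicodedata.normalize("NFC", text)


def fold(text: str) -> str:
    """Case-folded NFC form used for case-insensitive lookups."""
    return nfc(text).casefold()


def strip_accents(text: str) -> str:
    """Remove combining marks (NFD decomposition) — lenient comparisons."""
    decomposed = unicodedata.normalize("NFD", text)
    return unicodedata.normalize(
        "NFC", "".join(c for c in decomposed if not unicodedata.combining(c))
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphFeatures:
    """Morphological attributes of one surface form.

    Person, tense and mood apply only to verb forms; ``variant_type`` marks
    shortened forms (*Dr.* abbreviation, *SIDA* acronym) and is ``NONE`` for
    fully spelled forms.
    """

    gender: Gender = Gender.UNSPECIFIED
    number: Number = Number.UNSPECIFIED
    person: Person = Person.NONE
    tense: Tense = Tense.NONE
    mood: Mood = Mood.NONE
    variant_type: VariantType = VariantType.NONE

    def is_verbal(self) -> bool:
        return (
            self.person is not Person.NONE
            or self.tense is not Tense.NONE
            or self.mood is not Mood.NONE
        )


UNSPECIFIED_MORPH = MorphFeatures()


@dataclass(frozen=True)
class WordForm:
    """A surface form with its morphological features."""

    surface: str
    morph: MorphFeatures = UNSPECIFIED_MORPH

    def __post_init__(self) -> None:
        surface = nfc(self.surface).strip()
        if not surface:
            raise ValidationError("word form surface is empty")
        object.__setattr__(self, "surface", surface)


@dataclass(frozen=True)
class LexicalEntry:
    """One lemma with its concept identifiers and inflected forms.

    The lemma (citation form) always appears among ``forms``; it is added
    automatically on construction if missing.  Entries in the main lexicon
    must be mapped to at least one CUI — the lexicon is concept-anchored —
    unless loaded with an explicit ``allow_no_cui`` flag.
    """

    lemma: str
    pos: PoS
    cuis: frozenset[str] = frozenset()
    semantic_types: frozenset[str] = frozenset()
    semantic_group: str = ""
    forms: frozenset[WordForm] = frozenset()

    def __post_init__(self) -> None:
        lemma = nfc(self.lemma).strip()
        if not lemma:
            raise ValidationError("entry lemma is empty")
        object.__setattr__(self, "lemma", lemma)
        cuis = frozenset(nfc(c).strip() for c in self.cuis)
        for cui in cuis:
            if not CUI_PATTERN.match(cui):
                raise SchemaError(f"invalid CUI {cui!r} (expected C + 7 digits)")
        object.__setattr__(self, "cuis", cuis)
        object.__setattr__(
            self, "semantic_types",
            frozenset(nfc(t).strip() for t in self.semantic_types),
        )
        object.__setattr__(self, "semantic_group", nfc(self.semantic_group).strip())
        forms = set(self.forms)
        if lemma not in {wf.surface for wf in forms}:
            forms.add(WordForm(lemma))
        object.__setattr__(self, "forms", frozenset(forms))
        for wf in forms:
            if self.pos is not PoS.V and wf.morph.is_verbal():
                raise ValidationError(
                    f"non-verb entry {lemma!r} has verbal features on {wf.surface!r}"
                )

    @property
    def surfaces(self) -> frozenset[str]:
        return frozenset(wf.surface for wf in self.forms)

    def merge_key(self) -> tuple[str, PoS, frozenset[str]]:
        return (self.lemma, self.pos, self.cuis)

    def merged_with(self, other: "LexicalEntry") -> "LexicalEntry":
        """Form-set union of two entries sharing (lemma, pos, cuis)."""
        if self.merge_key() != other.merge_key():
            raise ValidationError(
                f"cannot merge entries with different keys: {self.lemma!r}/{other.lemma!r}"
            )
        return replace(
            self,
            semantic_types=self.semantic_types | other.semantic_types,
            semantic_group=self.semantic_group or other.semantic_group,
            forms=self.forms | other.forms,
        )

    def without_morphology(self) -> "LexicalEntry":
        """Projection used by the (morphology-lossy) DSV format."""
        return replace(
            self, forms=frozenset(WordForm(wf.surface) for wf in self.forms)
        )

    def sort_key(self) -> tuple[str, str, str]:
        return (min(self.cuis, default=""), self.lemma, self.pos.value)


class Lexicon:
    """A collection of lexical entries with form, lemma and CUI indexes.

    Entries sharing ``(lemma, pos, cuis)`` are merged on insertion (form-set
    union); the merge count is tracked so duplicates are reported, not
    silently dropped.  Indexes are rebuilt incrementally and always resolve
    to entries that actually contain the key.
    """

    def __init__(self, entries: Iterable[LexicalEntry] = ()) -> None:
        self._entries: dict[tuple, LexicalEntry] = {}
        self._by_form: dict[str, list[LexicalEntry]] = defaultdict(list)
        self._by_form_folded: dict[str, list[LexicalEntry]] = defaultdict(list)
        self._by_lemma: dict[str, list[LexicalEntry]] = defaultdict(list)
        self._by_cui: dict[str, list[LexicalEntry]] = defaultdict(list)
        self.n_merged = 0
        for entry in entries:
            self.add(entry)

    # -- mutation -----------------------------------------------------------

    def add(self, entry: LexicalEntry) -> LexicalEntry:
        key = entry.merge_key()
        old = self._entries.get(key)
        if old is not None:
            self._unindex(old)
            entry = old.merged_with(entry)
            self.n_merged += 1
        self._entries[key] = entry
        self._index(entry)
        return entry

    def replace_entry(self, old: LexicalEntry, new: LexicalEntry) -> LexicalEntry:
        """Swap *old* for *new* (used by concept propagation / linking)."""
        key = old.merge_key()
        if key not in self._entries:
            raise ValidationError(f"entry {old.lemma!r} not in lexicon")
        self._unindex(self._entries.pop(key))
        return self.add(new)

    def _index(self, entry: LexicalEntry) -> None:
        for wf in entry.forms:
            self._by_form[wf.surface].append(entry)
            self._by_form_folded[fold(wf.surface)].append(entry)
        self._by_lemma[entry.lemma].append(entry)
        for cui in entry.cuis:
            self._by_cui[cui].append(entry)

    def _unindex(self, entry: LexicalEntry) -> None:
        for wf in entry.forms:
            self._by_form[wf.surface].remove(entry)
            self._by_form_folded[fold(wf.surface)].remove(entry)
        self._by_lemma[entry.lemma].remove(entry)
        for cui in entry.cuis:
            self._by_cui[cui].remove(entry)

    # -- access -------------------------------------------------------------

    @property
    def entries(self) -> list[LexicalEntry]:
        return sorted(self._entries.values(), key=LexicalEntry.sort_key)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return self._entries == other._entries

    def by_form(self, surface: str, folded: bool = False) -> list[LexicalEntry]:
        if folded:
            return list(self._by_form_folded.get(fold(surface), ()))
        return list(self._by_form.get(nfc(surface), ()))

    def by_lemma(self, lemma: str) -> list[LexicalEntry]:
        return list(self._by_lemma.get(nfc(lemma), ()))

    def by_cui(self, cui: str) -> list[LexicalEntry]:
        return list(self._by_cui.get(cui, ()))

    def has_form(self, surface: str, folded: bool = True) -> bool:
        return bool(self.by_form(surface, folded=folded))

    def all_surfaces(self) -> set[str]:
        return set(self._by_form)

    def validate(self, allow_no_cui: bool = False) -> None:
        for entry in self._entries.values():
            if not entry.cuis and not allow_no_cui:
                raise ValidationError(
                    f"entry {entry.lemma!r} has no CUI (main-lexicon entries "
                    "must be concept-mapped; pass allow_no_cui to keep it)"
                )


# ---------------------------------------------------------------------------
# Lexical Record tables (complementary LR files)
# ---------------------------------------------------------------------------

@dataclass
class LexicalRecords:
    """Equivalence tables distributed alongside the lexicon.

    ``abbreviations``: (short form, full form) pairs; ``affixes``:
    (affix-with-hyphen, gloss, optional CUI) triples where the hyphen marks
    the attachment side (*reno-* prefix, *-cilina* suffix); ``deverbal``:
    (noun, verb) pairs; ``denominal_adj``: (adjective, noun) pairs.
    """

    abbreviations: list[tuple[str, str]] = field(default_factory=list)
    affixes: list[tuple[str, str, str | None]] = field(default_factory=list)
    deverbal: list[tuple[str, str]] = field(default_factory=list)
    denominal_adj: list[tuple[str, str]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "abbreviations": len(self.abbreviations),
            "affixes": len(self.affixes),
            "deverbal": len(self.deverbal),
            "denominal_adj": len(self.denominal_adj),
        }


RECORD_KINDS = ("abbreviations", "affixes", "deverbal", "denominal_adj")


def read_lexical_records(
    paths: Mapping[str, str | Path], delimiter: str = DSV_DELIMITER
) -> LexicalRecords:
    """Load Lexical Record tables from two/three-column delimited files.

    *paths* maps a record kind (``abbreviations``, ``affixes``, ``deverbal``,
    ``denominal_adj``) to a file path.  Affix rows may carry an optional
    third CUI column and must have a leading and/or trailing hyphen.
    """
    records = LexicalRecords()
    for kind, path in paths.items():
        if kind not in RECORD_KINDS:
            raise SchemaError(
                f"unknown lexical-record kind {kind!r} (expected one of {RECORD_KINDS})"
            )
        rows = getattr(records, kind)
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                cells = [nfc(c).strip() for c in line.split(delimiter)]
                if kind == "affixes":
                    if len(cells) not in (2, 3):
                        raise MalformedRecordError(
                            f"{path}:{i}: affix row needs 2-3 columns, got {len(cells)}"
                        )
                    affix = cells[0]
                    if not (affix.startswith("-") or affix.endswith("-")):
                        raise MalformedRecordError(
                            f"{path}:{i}: affix {affix!r} lacks an attachment hyphen"
                        )
                    cui = cells[2] if len(cells) == 3 and cells[2] else None
                    if cui and not CUI_PATTERN.match(cui):
                        raise SchemaError(f"{path}:{i}: invalid CUI {cui!r}")
                    rows.append((affix, cells[1], cui))
                else:
                    if len(cells) != 2:
                        raise MalformedRecordError(
                            f"{path}:{i}: {kind} row needs 2 columns, got {len(cells)}"
                        )
                    rows.append((cells[0], cells[1]))
    logger.info("lexical records loaded: %s", records.counts())
    return records


# ---------------------------------------------------------------------------
# DSV reader/writer
# ---------------------------------------------------------------------------

def parse_dsv_record(
    line: str,
    line_number: int = 0,
    delimiter: str = DSV_DELIMITER,
    allow_no_cui: bool = False,
) -> LexicalEntry:
    """Parse one six-field DSV line into a :class:`LexicalEntry`.

    Field order: CUI(s), lemma, semicolon-separated forms, PoS, semantic
    type(s), semantic group.  Whitespace is trimmed and duplicate forms are
    deduplicated.
    """
    fields = line.rstrip("\n").split(delimiter)
    if len(fields) != 6:
        raise MalformedRecordError(
            f"line {line_number}: expected 6 fields, got {len(fields)}: {line!r}"
        )
    raw_cuis, lemma, raw_forms, raw_pos, raw_types, group = fields
    raw_pos = raw_pos.strip()
    try:
        pos = PoS(raw_pos)
    except ValueError:
        raise SchemaError(
            f"line {line_number}: unknown part-of-speech tag {raw_pos!r}"
        ) from None
    cuis = frozenset(c.strip() for c in raw_cuis.split(DSV_MULTI_SEP) if c.strip())
    if not cuis and not allow_no_cui:
        raise ValidationError(
            f"line {line_number}: entry {lemma.strip()!r} has no CUI"
        )
    forms = frozenset(
        WordForm(s.strip())
        for s in raw_forms.split(DSV_MULTI_SEP)
        if s.strip()
    )
    types = frozenset(t.strip() for t in raw_types.split(DSV_MULTI_SEP) if t.strip())
    return LexicalEntry(
        lemma=lemma, pos=pos, cuis=cuis, semantic_types=types,
        semantic_group=group, forms=forms,
    )


def _format_dsv_record(entry: LexicalEntry, delimiter: str = DSV_DELIMITER) -> str:
    cuis = DSV_MULTI_SEP.join(sorted(entry.cuis))
    surfaces = sorted(entry.surfaces)
    # citation form first, then the rest in codepoint order
    if entry.lemma in surfaces:
        surfaces.remove(entry.lemma)
        surfaces.insert(0, entry.lemma)
    forms = DSV_MULTI_SEP.join(surfaces)
    types = DSV_MULTI_SEP.join(sorted(entry.semantic_types))
    return delimiter.join(
        [cuis, entry.lemma, forms, entry.pos.value, types, entry.semantic_group]
    )


# ---------------------------------------------------------------------------
# LMF reader/writer
# ---------------------------------------------------------------------------

_FEAT = "feat"


def _feat(parent: etree._Element, att: str, val: str) -> None:
    etree.SubElement(parent, _FEAT, att=att, val=val)


def _feats(element: etree._Element) -> dict[str, list[str]]:
    out: dict[str, list[str]] = defaultdict(list)
    for child in element.findall(_FEAT):
        out[child.get("att")].append(child.get("val"))
    return out


def affix_attachment(lemma: str) -> str | None:
    """Attachment side encoded by the hyphen(s) of an affix lemma."""
    leading, trailing = lemma.startswith("-"), lemma.endswith("-")
    if leading and trailing:
        return "infix"
    if leading:
        return "suffix"
    if trailing:
        return "prefix"
    return None


def _entry_to_lmf(entry: LexicalEntry) -> etree._Element:
    el = etree.Element("LexicalEntry")
    _feat(el, "partOfSpeech", entry.pos.value)
    if entry.pos is PoS.AFF:
        side = affix_attachment(entry.lemma)
        if side:
            _feat(el, "attachment", side)
    lemma_el = etree.SubElement(el, "Lemma")
    _feat(lemma_el, "writtenForm", entry.lemma)
    for wf in sorted(entry.forms, key=lambda w: (w.surface, w.morph.gender.value,
                                                 w.morph.number.value, w.morph.person.value,
                                                 w.morph.tense.value, w.morph.mood.value)):
        wf_el = etree.SubElement(el, "WordForm")
        _feat(wf_el, "writtenForm", wf.surface)
        m = wf.morph
        if m.gender is not Gender.UNSPECIFIED:
            _feat(wf_el, "grammaticalGender", m.gender.value)
        if m.number is not Number.UNSPECIFIED:
            _feat(wf_el, "grammaticalNumber", m.number.value)
        if m.person is not Person.NONE:
            _feat(wf_el, "person", m.person.value)
        if m.tense is not Tense.NONE:
            _feat(wf_el, "grammaticalTense", m.tense.value)
        if m.mood is not Mood.NONE:
            _feat(wf_el, "verbFormMood", m.mood.value)
        if m.variant_type is not VariantType.NONE:
            _feat(wf_el, "variantType", m.variant_type.value)
    sense = etree.SubElement(el, "Sense")
    for cui in sorted(entry.cuis):
        _feat(sense, "cui", cui)
    for st in sorted(entry.semantic_types):
        _feat(sense, "semanticType", st)
    if entry.semantic_group:
        _feat(sense, "semanticGroup", entry.semantic_group)
    return el


def _entry_from_lmf(el: etree._Element, allow_no_cui: bool) -> LexicalEntry:
    entry_feats = _feats(el)
    pos_vals = entry_feats.get("partOfSpeech")
    if not pos_vals:
        raise SchemaError("LexicalEntry without partOfSpeech feature")
    try:
        pos = PoS(pos_vals[0])
    except ValueError:
        raise SchemaError(f"unknown part-of-speech tag {pos_vals[0]!r}") from None
    lemma_el = el.find("Lemma")
    if lemma_el is None:
        raise SchemaError("LexicalEntry without Lemma element")
    lemma = _feats(lemma_el).get("writtenForm", [""])[0]
    forms = set()
    for wf_el in el.findall("WordForm"):
        f = _feats(wf_el)
        surface = f.get("writtenForm", [""])[0]
        morph = MorphFeatures(
            gender=Gender(f.get("grammaticalGender", [Gender.UNSPECIFIED.value])[0]),
            number=Number(f.get("grammaticalNumber", [Number.UNSPECIFIED.value])[0]),
            person=Person(f.get("person", [Person.NONE.value])[0]),
            tense=Tense(f.get("grammaticalTense", [Tense.NONE.value])[0]),
            mood=Mood(f.get("verbFormMood", [Mood.NONE.value])[0]),
            variant_type=VariantType(f.get("variantType", [VariantType.NONE.value])[0]),
        )
        forms.add(WordForm(surface, morph))
    sense_el = el.find("Sense")
    sense = _feats(sense_el) if sense_el is not None else {}
    cuis = frozenset(sense.get("cui", []))
    if not cuis and not allow_no_cui:
        raise ValidationError(f"LMF entry {lemma!r} has no CUI")
    return LexicalEntry(
        lemma=lemma, pos=pos, cuis=cuis,
        semantic_types=frozenset(sense.get("semanticType", [])),
        semantic_group=sense.get("semanticGroup", [""])[0],
        forms=frozenset(forms),
    )


# ---------------------------------------------------------------------------
# Lexicon-level I/O
# ---------------------------------------------------------------------------

def read_lexicon(
    path: str | Path,
    format: str = "dsv",
    delimiter: str = DSV_DELIMITER,
    allow_no_cui: bool = False,
) -> Lexicon:
    """Read a lexicon from a DSV or LMF-XML file.

    Records sharing ``(lemma, pos, cuis)`` are merged with form-set union;
    the number of merged duplicates is logged, never silently dropped.
    An empty file yields an empty lexicon with a warning.
    """
    path = Path(path)
    lexicon = Lexicon()
    if format == "dsv":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                lexicon.add(
                    parse_dsv_record(line, i, delimiter, allow_no_cui=allow_no_cui)
                )
    elif format == "lmf":
        if path.stat().st_size > 0:
            tree = etree.parse(str(path))
            for el in tree.getroot().iter("LexicalEntry"):
                lexicon.add(_entry_from_lmf(el, allow_no_cui=allow_no_cui))
    else:
        raise ValueError(f"unknown lexicon format {format!r}")
    if len(lexicon) == 0:
        logger.warning("read empty lexicon from %s", path)
    if lexicon.n_merged:
        logger.info("merged %d duplicate records while reading %s",
                    lexicon.n_merged, path)
    return lexicon


def write_lexicon(
    lexicon: Lexicon,
    path: str | Path,
    format: str = "dsv",
    delimiter: str = DSV_DELIMITER,
    allow_no_cui: bool = False,
) -> Path:
    """Write a lexicon deterministically (entries sorted by CUI, lemma).

    DSV drops per-form morphology (six fields cannot carry it); LMF encodes
    every morphological attribute as LMF ``feat`` name/value pairs and is
    lossless.
    """
    path = Path(path)
    lexicon.validate(allow_no_cui=allow_no_cui)
    entries = lexicon.entries  # already sorted (CUI, lemma)
    if format == "dsv":
        with open(path, "w", encoding="utf-8") as fh:
            for entry in entries:
                fh.write(_format_dsv_record(entry, delimiter) + "\n")
    elif format == "lmf":
        root = etree.Element("LexicalResource", dtdVersion="16")
        gi = etree.SubElement(root, "GlobalInformation")
        _feat(gi, "languageCoding", "ISO 639-3")
        lex_el = etree.SubElement(root, "Lexicon")
        _feat(lex_el, "language", "spa")
        for entry in entries:
            lex_el.append(_entry_to_lmf(entry))
        etree.ElementTree(root).write(
            str(path), encoding="utf-8", xml_declaration=True, pretty_print=True
        )
    else:
        raise ValueError(f"unknown lexicon format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Descriptive statistics of a lexicon.

    ``n_forms`` counts distinct (lemma, surface) pairs; the per-CUI means are
    rounded to two decimals, and the PoS distribution carries counts and
    percentages of ``n_lemmas``.
    """

    n_lemmas: int
    n_forms: int
    n_cuis: int
    mean_lemmas_per_cui: float
    mean_forms_per_cui: float
    pos_distribution: dict[str, tuple[int, float]]
    group_distribution: dict[str, float]

    @classmethod
    def from_counts(cls, n_lemmas: int, n_forms: int, n_cuis: int) -> "StatsReport":
        """Per-CUI means from bare totals (no distributions)."""
        if n_cuis <= 0:
            raise EmptyLexiconError("cannot compute per-CUI means without CUIs")
        return cls(
            n_lemmas=n_lemmas, n_forms=n_forms, n_cuis=n_cuis,
            mean_lemmas_per_cui=round(n_lemmas / n_cuis, 2),
            mean_forms_per_cui=round(n_forms / n_cuis, 2),
            pos_distribution={}, group_distribution={},
        )


def lexicon_stats(lexicon: Lexicon) -> StatsReport:
    """Compute the descriptive-statistics report for a non-empty lexicon."""
    if len(lexicon) == 0:
        raise EmptyLexiconError("cannot compute statistics of an empty lexicon")
    entries = lexicon.entries
    n_lemmas = len(entries)
    form_pairs = {(e.lemma, wf.surface) for e in entries for wf in e.forms}
    cuis = {c for e in entries for c in e.cuis}
    n_forms = len(form_pairs)
    n_cuis = len(cuis)
    report = StatsReport.from_counts(n_lemmas, n_forms, n_cuis)
    pos_counts: dict[str, int] = defaultdict(int)
    group_counts: dict[str, int] = defaultdict(int)
    for e in entries:
        pos_counts[e.pos.value] += 1
        if e.semantic_group:
            group_counts[e.semantic_group] += 1
    report.pos_distribution = {
        p: (c, round(100.0 * c / n_lemmas, 2))
        for p, c in sorted(pos_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    n_grouped = sum(group_counts.values())
    report.group_distribution = {
        g: round(100.0 * c / n_grouped, 2)
        for g, c in sorted(group_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    } if n_grouped else {}
    return report
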