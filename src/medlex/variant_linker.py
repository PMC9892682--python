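"""Edit-distance variant discovery, acronym linking and affix lookup.

Character-level spelling variants (*viriasis* ↔ *viriosis*), hyphenation and
tokenization variants (*betabloqueante* ↔ *beta-bloqueante* ↔ *beta
bloqueante*) are found by unit-cost Levenshtein distance (threshold ≤ 2 by
default) between concept-mapped lexicon forms and unattested strings; a
distance of 0 is the exact-match CUI assignment used to seed the lexicon.
Candidates are never auto-accepted: each pair carries a review status and
transitions only through an explicit review file, keeping a human-in-the-loop
audit trail.

Acronym/abbreviation linking propagates CUIs bidirectionally between short
forms and full forms (*EV* ↔ *enterovirus*, C0014383), flagging ambiguous
short forms (e.g. *IM*) that map to several distinct concepts.  Affix lookup
matches a token's start/end against hyphen-marked prefixes and suffixes
(*reno-* 'kidney'; *-cilina* → C0030842, penicillins), longest match first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

from .lexicon_core import (
    EmptyLexiconError,
    LexicalRecords,
    Lexicon,
    MorphFeatures,
    VariantType,
    WordForm,
    fold,
    nfc,
    strip_accents,
)

logger = logging.getLogger("medlex")


# ---------------------------------------------------------------------------
# Levenshtein distance
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str, fold_accents: bool = False) -> int:
    """Unit-cost Levenshtein distance between two NFC-normalized strings.

    Insertions, deletions and substitutions each cost 1; comparison is
    case-sensitive and spaces/hyphens count as ordinary characters (so the
    three beta-blocker tokenization variants are pairwise within distance 2).
    With ``fold_accents`` combining marks are removed before comparison.
    """
    a, b = nfc(a), nfc(b)
    if fold_accents:
        a, b = strip_accents(a), strip_accents(b)
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(min(
                previous[j] + 1,           # deletion
                current[j - 1] + 1,        # insertion
                previous[j - 1] + (ca != cb),  # substitution
            ))
        previous = current
    return previous[-1]


# ---------------------------------------------------------------------------
# Variant candidates
# ---------------------------------------------------------------------------

class ReviewStatus(str, Enum):
    PROPOSED = "proposed"
    ACCEPTED = "accepted"
    REJECTED = "rejected"


@dataclass(frozen=True)
class CandidatePair:
    """A (known term, unattested candidate) pair awaiting manual review."""

    known_term: str
    candidate: str
    distance: int
    cuis: frozenset[str] = frozenset()
    status: ReviewStatus = ReviewStatus.PROPOSED


def find_variant_candidates(
    lexicon: Lexicon,
    unattested: list[str],
    max_dist: int = 2,
    fold_accents: bool = False,
) -> list[CandidatePair]:
    """Propose lexicon forms within *max_dist* edits of unattested strings.

    For each unattested string every lexicon form within the threshold is
    returned as a proposed pair carrying the CUIs of the entries containing
    that form, sorted by (distance, known term).  Distance-0 pairs are exact
    matches (the base-list CUI-assignment criterion).  No pair is ever
    auto-accepted.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if len(lexicon) == 0:
        raise EmptyLexiconError("cannot search variants in an empty lexicon")
    surfaces = sorted(lexicon.all_surfaces())
    pairs: list[CandidatePair] = []
    for candidate in unattested:
        candidate = nfc(candidate).strip()
        found: list[CandidatePair] = []
        for surface in surfaces:
            # cheap length bound before the DP
            if abs(len(surface) - len(candidate)) > max_dist:
                continue
            d = edit_distance(surface, candidate, fold_accents=fold_accents)
            if d <= max_dist:
                cuis = frozenset(
                    c for e in lexicon.by_form(surface) for c in e.cuis
                )
                found.append(CandidatePair(
                    known_term=surface, candidate=candidate, distance=d, cuis=cuis,
                ))
        found.sort(key=lambda p: (p.distance, p.known_term))
        pairs.extend(found)
    return pairs


# ---------------------------------------------------------------------------
# Acronym / abbreviation linking
# ---------------------------------------------------------------------------

def _classify_short_form(short: str) -> VariantType:
    """All-caps short forms are acronyms; the rest are abbreviations."""
    letters = [c for c in short if c.isalpha()]
    if letters and all(c.isupper() for c in letters):
        return VariantType.ACRONYM
    return VariantType.ABBREVIATION


@dataclass
class AcronymLinkReport:
    """Outcome of one linking pass over the abbreviation table."""

    linked: list[tuple[str, str]]
    ambiguous: dict[str, frozenset[str]]   # short form -> all candidate CUIs
    unresolved: list[tuple[str, str]]      # pairs whose full form is unknown


def link_acronyms(
    records: LexicalRecords, lexicon: Lexicon,
    report: AcronymLinkReport | None = None,
) -> Lexicon:
    """Propagate CUIs between short forms and full forms, in place.

    For each (short form, full form) pair whose full form is a lexicon form,
    the CUI sets of the corresponding entries are united on both sides and
    the short form is added to the full-form entry as an acronym/abbreviation
    variant.  Short forms that resolve to more than one distinct concept
    (e.g. *IM*: mitral insufficiency / myocardial infarction / intramuscular)
    keep all candidate CUIs and are flagged ambiguous; language-invariant
    items (e.g. *kg*) with a single concept link without any review flag.
    Pairs whose full form is absent are logged and reported unresolved.
    Idempotent: a second pass changes nothing.
    """
    out = report if report is not None else AcronymLinkReport([], {}, [])
    # first pass: gather concepts per short form to detect ambiguity
    short_cuis: dict[str, set[str]] = {}
    for short, full in records.abbreviations:
        entries = lexicon.by_form(full, folded=True)
        cuis = {c for e in entries for c in e.cuis}
        cuis |= {c for e in lexicon.by_form(short) for c in e.cuis}
        short_cuis.setdefault(short, set()).update(cuis)

    for short, full in records.abbreviations:
        full_entries = lexicon.by_form(full, folded=True)
        if not full_entries:
            logger.warning("acronym %r: full form %r not in lexicon", short, full)
            out.unresolved.append((short, full))
            continue
        all_cuis = frozenset(short_cuis[short])
        variant_type = _classify_short_form(short)
        short_wf = WordForm(short, MorphFeatures(variant_type=variant_type))
        for entry in list(full_entries):
            merged_cuis = entry.cuis | all_cuis
            if merged_cuis != entry.cuis or short_wf not in entry.forms:
                lexicon.replace_entry(entry, replace(
                    entry, cuis=merged_cuis, forms=entry.forms | {short_wf},
                ))
        # propagate onto any standalone short-form entries as well
        for entry in list(lexicon.by_form(short)):
            if all_cuis - entry.cuis:
                lexicon.replace_entry(entry, replace(entry, cuis=entry.cuis | all_cuis))
        concepts_per_sense = {
            frozenset(e.cuis) for e in lexicon.by_form(full, folded=True)
        }
        out.linked.append((short, full))
        # ambiguity: the short form maps to >1 distinct full-form concept
        full_forms = {f for s, f in records.abbreviations if s == short}
        if len(full_forms) > 1 or len(concepts_per_sense) > 1:
            out.ambiguous[short] = frozenset(short_cuis[short])
    if out.ambiguous:
        logger.info("ambiguous short forms flagged: %s", sorted(out.ambiguous))
    return lexicon


# ---------------------------------------------------------------------------
# Affix lookup
# ---------------------------------------------------------------------------

def affix_lookup(
    token: str, records: LexicalRecords
) -> list[tuple[str, str, str | None]]:
    """Affix-table matches for a token, longest affix first.

    A trailing-hyphen affix (*reno-*) must match the token's start, a
    leading-hyphen affix (*-cilina*) its end.  The match must be proper
    (shorter than the token).  No match yields an empty list.
    """
    token = fold(token)
    hits: list[tuple[str, str, str | None]] = []
    for affix, gloss, cui in records.affixes:
        body = fold(affix).strip("-")
        if not body or len(body) >= len(token):
            continue
        if affix.endswith("-") and token.startswith(body):
            hits.append((affix, gloss, cui))
        elif affix.startswith("-") and token.endswith(body):
            hits.append((affix, gloss, cui))
    hits.sort(key=lambda h: (-len(h[0].strip("-")), h[0]))
    return hits
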