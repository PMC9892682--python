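"""Lexicon-backed PoS tagging, lemmatization and their evaluation.

A domain lexicon layered over a general-purpose tagger fixes systematic
errors on medical vocabulary: acronyms like *UCI* get NOUN instead of
PROPN, adjectives like *úrico* stop being mislabelled as nouns, and
out-of-vocabulary compounds keep their own surface as lemma instead of a
fabricated string (the failure mode of seq2seq lemmatizers, which can turn
*vesico-prostática* into a non-word).

The base tagger is an injected dependency — any callable producing a
per-token tag; a trivial all-``OTHER`` base ships for dependency-free use.
Evaluation follows the protocol used for medical PoS/lemma benchmarking:
only the open lexical categories (ADJ, ADV, NOUN, PROPN, VERB) are
compared, lemma comparison is lenient (accent- and case-folded), and
precision/recall/F1 are reported per category and micro-aggregated (macro
also emitted).  Metrics are computed with scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

from sklearn.metrics import precision_recall_fscore_support

from .lexicon_core import (
    LexicalEntry,
    Lexicon,
    MedLexError,
    PoS,
    fold,
    nfc,
    strip_accents,
)

logger = logging.getLogger("medlex")

#: Evaluation tagset (Universal Dependencies open classes + OTHER).
LEXICAL_TAGS = ("ADJ", "ADV", "NOUN", "PROPN", "VERB")
OTHER = "OTHER"

#: Lexicon PoS → ordered evaluation-tag alternatives (first = preferred).
POS_TO_TAGS: dict[PoS, tuple[str, ...]] = {
    PoS.N: ("NOUN",),
    PoS.NPR: ("PROPN",),
    PoS.V: ("VERB",),
    PoS.ADJ: ("ADJ",),
    PoS.ADV: ("ADV",),
    PoS.ADJ_N: ("ADJ", "NOUN"),
    PoS.N_NPR: ("NOUN", "PROPN"),
    PoS.ADJ_ADV: ("ADJ", "ADV"),
    # AFF entries are bound morphemes, not word tokens: no tag contribution
}


class MisalignedSequencesError(MedLexError):
    """Prediction and gold token sequences do not line up."""


class TagSource(str, Enum):
    LEXICON = "lexicon"
    FALLBACK = "fallback"


@dataclass(frozen=True)
class TaggedToken:
    surface: str
    pos: str
    lemma: str
    source: TagSource


def all_other_tagger(tokens: Sequence[str]) -> list[str]:
    """Trivial base tagger: every token is OTHER (lexicon does the work)."""
    return [OTHER] * len(tokens)


# ---------------------------------------------------------------------------
# Lemmatization
# ---------------------------------------------------------------------------

def lemmatize_token(
    surface: str, pos_hint: str | None, lexicon: Lexicon
) -> tuple[str, TagSource]:
    """Lexicon lookup of the folded surface; identity fallback for OOVs.

    When several entries share the surface, the one whose PoS is compatible
    with *pos_hint* wins, then the lexicographically smallest lemma.  An
    out-of-vocabulary surface returns itself as lemma — never an invented
    string.
    """
    surface = nfc(surface)
    entries = lexicon.by_form(surface, folded=True)
    if not entries:
        return surface, TagSource.FALLBACK
    def rank(entry: LexicalEntry) -> tuple[int, str]:
        tags = POS_TO_TAGS.get(entry.pos, ())
        compatible = pos_hint is not None and pos_hint in tags
        return (0 if compatible else 1, entry.lemma)
    best = sorted(entries, key=rank)[0]
    return best.lemma, TagSource.LEXICON


# ---------------------------------------------------------------------------
# Tagging (lexicon as an override layer over a base tagger)
# ---------------------------------------------------------------------------

def _lexicon_alternatives(entries: list[LexicalEntry]) -> list[str]:
    """Ordered evaluation-tag alternatives contributed by lexicon entries."""
    alternatives: list[str] = []
    for entry in sorted(entries, key=LexicalEntry.sort_key):
        for tag in POS_TO_TAGS.get(entry.pos, ()):
            if tag not in alternatives:
                alternatives.append(tag)
    return alternatives


def tag_tokens(
    tokens: Sequence[tuple[str, str]], lexicon: Lexicon
) -> list[TaggedToken]:
    """Override base tags with lexicon categories where the lexicon is sure.

    Each input token carries a base tag from an upstream tagger.  If the
    surface is a lexicon form with a single lexical category, that category
    (mapped N→NOUN, NPR→PROPN, V→VERB, ADJ→ADJ, ADV→ADV) replaces the base
    tag.  Ambiguous lexicon categories (ADJ/N, N/NPR, ADJ/ADV) defer to the
    base tag when it is one of the alternatives — context decides cases like
    participle/adjective *ulcerada* — and otherwise take the first
    alternative.  Tokens outside the lexicon keep their base tag untouched.
    """
    out: list[TaggedToken] = []
    for item in tokens:
        if not isinstance(item, tuple) or len(item) != 2:
            raise MisalignedSequencesError(
                "tag_tokens expects (surface, base_tag) pairs"
            )
        surface, base_tag = item
        entries = lexicon.by_form(surface, folded=True)
        alternatives = _lexicon_alternatives(entries)
        if not alternatives:
            tag, source = base_tag, TagSource.FALLBACK
        elif len(alternatives) == 1:
            tag, source = alternatives[0], TagSource.LEXICON
        elif base_tag in alternatives:
            tag, source = base_tag, TagSource.LEXICON
        else:
            tag, source = alternatives[0], TagSource.LEXICON
        lemma, _ = lemmatize_token(surface, tag, lexicon)
        out.append(TaggedToken(surface=nfc(surface), pos=tag, lemma=lemma,
                               source=source))
    return out


def tag_text(
    tokens: Sequence[str],
    lexicon: Lexicon,
    base_tagger: Callable[[Sequence[str]], Sequence[str]] = all_other_tagger,
) -> list[TaggedToken]:
    """Run the injected base tagger, then the lexicon override layer."""
    base_tags = list(base_tagger(tokens))
    if len(base_tags) != len(tokens):
        raise MisalignedSequencesError(
            f"base tagger returned {len(base_tags)} tags for {len(tokens)} tokens"
        )
    return tag_tokens(list(zip(tokens, base_tags)), lexicon)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-category and aggregate precision/recall/F1.

    ``aggregate`` is the micro average over the five lexical categories;
    ``macro`` the unweighted mean over categories present in the gold.
    """

    per_category: dict[str, tuple[float, float, float]]
    aggregate: tuple[float, float, float]
    macro: tuple[float, float, float]
    n_tokens: int


def lenient_lemma(lemma: str) -> str:
    """Accent-stripped, case-folded lemma for lenient comparison.

    *cardíaco* and *cardiaco* compare equal; nothing broader is folded.
    """
    return strip_accents(fold(lemma))


def evaluate(
    pred: Sequence[TaggedToken],
    gold: Sequence[tuple[str, str, str]],
    mode: str = "pos",
) -> EvalReport:
    """Score predictions against gold (surface, tag, lemma) triples.

    Only tokens whose gold tag is an open lexical category are compared.
    ``pos`` mode scores tags one-vs-rest per category; ``lemma`` mode scores
    leniently folded lemma strings (per-category scores are computed over
    the tokens of that gold category).  Sequences must align token by token.
    """
    if mode not in ("pos", "lemma"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if len(pred) != len(gold):
        raise MisalignedSequencesError(
            f"length mismatch: {len(pred)} predictions vs {len(gold)} gold tokens"
        )
    for i, (p, g) in enumerate(zip(pred, gold)):
        if fold(p.surface) != fold(g[0]):
            raise MisalignedSequencesError(
                f"surface mismatch at position {i}: {p.surface!r} vs {g[0]!r}"
            )
    keep = [i for i, g in enumerate(gold) if g[1] in LEXICAL_TAGS]
    if not keep:
        raise MedLexError("no gold tokens in the open lexical categories")

    if mode == "pos":
        y_true = [gold[i][1] for i in keep]
        y_pred = [pred[i].pos for i in keep]
        labels = list(LEXICAL_TAGS)
    else:
        y_true = [lenient_lemma(gold[i][2]) for i in keep]
        y_pred = [lenient_lemma(pred[i].lemma) for i in keep]
        labels = sorted(set(y_true))

    micro = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="micro", zero_division=0.0
    )[:3]
    macro = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0.0
    )[:3]

    per_category: dict[str, tuple[float, float, float]] = {}
    if mode == "pos":
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average=None, zero_division=0.0
        )
        for tag, pi, ri, fi in zip(labels, p, r, f):
            per_category[tag] = (float(pi), float(ri), float(fi))
    else:
        for tag in LEXICAL_TAGS:
            idx = [i for i in keep if gold[i][1] == tag]
            if not idx:
                continue
            acc = sum(
                lenient_lemma(pred[i].lemma) == lenient_lemma(gold[i][2])
                for i in idx
            ) / len(idx)
            per_category[tag] = (acc, acc, acc)

    return EvalReport(
        per_category=per_category,
        aggregate=tuple(float(x) for x in micro),
        macro=tuple(float(x) for x in macro),
        n_tokens=len(keep),
    )


# ---------------------------------------------------------------------------
# CoNLL-U I/O (FORM, UPOS and LEMMA columns)
# ---------------------------------------------------------------------------

def read_conllu(path: str | Path) -> list[tuple[str, str, str]]:
    """(surface, UPOS, lemma) triples from a CoNLL-U file."""
    triples: list[tuple[str, str, str]] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise MedLexError(f"malformed CoNLL-U line: {line!r}")
        if "-" in cols[0] or "." in cols[0]:  # multiword/empty nodes
            continue
        triples.append((nfc(cols[1]), cols[3], nfc(cols[2])))
    return triples


def write_conllu(tokens: Iterable[TaggedToken], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for i, tok in enumerate(tokens, 1):
        lines.append("\t".join([
            str(i), tok.surface, tok.lemma, tok.pos, "_", "_", "_", "_", "_", "_",
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
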