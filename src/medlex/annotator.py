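"""Dictionary-based entity pre-annotation with standoff output.

Pre-annotating a corpus with a concept-anchored lexicon gives human
annotators a first pass of entity candidates: every maximal dictionary
match over the lexicon forms (typically restricted to the ANAT, CHEM, DISO
and PROC semantic groups) becomes a character-span annotation carrying all
candidate CUIs — ambiguity such as *radio* (radius bone / radium / shortened
'radiotherapy') is preserved for manual resolution.  Two pruning rules then
clean the raw matches:

1. nested general/specific pairs of the same group: the less specific
   (properly contained) entity is removed — *dolor* inside *dolor de cabeza*;
2. crossing entities (spans that partially overlap) are corrected to
   independent entities by splitting at the overlap boundary — the
   *administración de vacunas* / *vacunas vivas* case.

Output is BRAT standoff (``T`` entity lines with group and offsets, ``N``
normalization lines with CUIs) next to the source text.  Offsets are
0-based, end-exclusive, and every annotation's surface equals the document
slice.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .lexicon_core import (
    EmptyLexiconError,
    LexicalEntry,
    Lexicon,
    MedLexError,
    PoS,
    VariantType,
    fold,
    nfc,
)

logger = logging.getLogger("medlex")

# same token shape as the embedding-corpus normalizer: word runs with
# intra-token hyphens kept whole, punctuation split off
_TOKEN_RE = re.compile(r"[\w]+(?:[-·'][\w]+)*|[^\w\s]", re.UNICODE)


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """(token, start, end) triples over *text*; offsets 0-based end-exclusive."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# Annotation type
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Annotation:
    """A character span with its candidate concepts.

    ``surface`` always equals the document slice ``text[start:end]``.
    """

    start: int
    end: int
    surface: str
    cuis: frozenset[str]
    group: str
    lemma: str
    pos: PoS

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MedLexError(f"invalid span [{self.start}, {self.end})")

    def contains(self, other: "Annotation") -> bool:
        """Proper containment of *other*'s span in this span."""
        return (
            self.start <= other.start
            and other.end <= self.end
            and (self.end - self.start) > (other.end - other.start)
        )

    def crosses(self, other: "Annotation") -> bool:
        """Partial overlap with neither span containing the other."""
        return (
            self.start < other.end
            and other.start < self.end
            and not self.contains(other)
            and not other.contains(self)
            and (self.start, self.end) != (other.start, other.end)
        )


# ---------------------------------------------------------------------------
# Matcher index (token-sequence trie)
# ---------------------------------------------------------------------------

class _TrieNode:
    __slots__ = ("children", "payload")

    def __init__(self) -> None:
        self.children: dict[str, "_TrieNode"] = {}
        self.payload: list[tuple[LexicalEntry, str]] = []


@dataclass
class MatcherIndex:
    """Token-sequence trie over lexicon forms.

    Non-acronym forms are indexed case-folded (NFC); acronym-typed forms are
    indexed case-sensitively so *EV* does not fire on *ev*.
    """

    root: _TrieNode
    n_forms: int

    def lookup(self, tokens: Sequence[str]) -> list[tuple[LexicalEntry, str]]:
        """Payload for an exact token sequence (used by tests/oracles)."""
        nodes = [self.root]
        for token in tokens:
            nodes = _advance(nodes, token)
            if not nodes:
                return []
        return [p for n in nodes for p in n.payload]


def _advance(nodes: list[_TrieNode], token: str) -> list[_TrieNode]:
    token_exact = nfc(token)
    token_folded = fold(token)
    out = []
    for node in nodes:
        hit = node.children.get("=" + token_exact)
        if hit is not None:
            out.append(hit)
        hit = node.children.get("~" + token_folded)
        if hit is not None:
            out.append(hit)
    return out


def build_matcher_index(
    lexicon: Lexicon, groups: set[str] | None = None
) -> MatcherIndex:
    """Index the forms of entries whose semantic group is in *groups*.

    With ``groups=None`` all entries are indexed.  An empty result after
    filtering is an error (nothing could ever match).
    """
    if len(lexicon) == 0:
        raise EmptyLexiconError("cannot build a matcher over an empty lexicon")
    root = _TrieNode()
    n_forms = 0
    for entry in lexicon:
        if groups is not None and entry.semantic_group not in groups:
            continue
        for wf in entry.forms:
            tokens = [t for t, _, _ in tokenize_with_offsets(wf.surface)]
            if not tokens:
                continue
            case_sensitive = wf.morph.variant_type is VariantType.ACRONYM
            node = root
            for token in tokens:
                key = ("=" + nfc(token)) if case_sensitive else ("~" + fold(token))
                node = node.children.setdefault(key, _TrieNode())
            node.payload.append((entry, wf.surface))
            n_forms += 1
    if n_forms == 0:
        raise EmptyLexiconError(
            f"group filter {sorted(groups or ())} leaves no indexable form"
        )
    return MatcherIndex(root=root, n_forms=n_forms)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_all(text: str, index: MatcherIndex) -> list[Annotation]:
    """Every dictionary match in *text*, overlaps and ambiguity included.

    At each token position the trie is walked as far as it can go and every
    terminal hit along the way is reported, so both *dolor* and *dolor de
    cabeza* come back when both are lexicon forms.  Matches of the same span
    and semantic group are merged with CUI-set union (the *radio* case keeps
    all its candidate concepts).
    """
    tokens = tokenize_with_offsets(text)
    by_span_group: dict[tuple[int, int, str], list[LexicalEntry]] = defaultdict(list)
    for i in range(len(tokens)):
        nodes = [index.root]
        for j in range(i, len(tokens)):
            nodes = _advance(nodes, tokens[j][0])
            if not nodes:
                break
            for node in nodes:
                for entry, _surface in node.payload:
                    span = (tokens[i][1], tokens[j][2], entry.semantic_group)
                    by_span_group[span].append(entry)
    annotations = []
    for (start, end, group), entries in by_span_group.items():
        entries = sorted(set(entries), key=LexicalEntry.sort_key)
        cuis = frozenset(c for e in entries for c in e.cuis)
        annotations.append(Annotation(
            start=start, end=end, surface=text[start:end], cuis=cuis,
            group=group, lemma=entries[0].lemma, pos=entries[0].pos,
        ))
    annotations.sort(key=lambda a: (a.start, a.end, a.group))
    return annotations


# ---------------------------------------------------------------------------
# Pruning (nested and crossing entities)
# ---------------------------------------------------------------------------

def _truncate(ann: Annotation, new_start: int, text_like: str) -> Annotation | None:
    """Cut *ann* to start at *new_start*, trimming leading whitespace."""
    offset = new_start - ann.start
    surface = ann.surface[offset:]
    trimmed = len(surface) - len(surface.lstrip())
    new_start += trimmed
    surface = surface.lstrip()
    if not surface:
        return None
    return replace(ann, start=new_start, end=ann.end, surface=surface)


def prune_annotations(annotations: list[Annotation]) -> list[Annotation]:
    """Apply the two pre-annotation correction rules.

    (1) an annotation properly contained in a longer annotation of the same
    group is removed (keep the more specific *dolor de cabeza*, drop
    *dolor*); (2) crossing pairs are corrected to independent entities by
    truncating the later-starting span to begin where the earlier one ends.
    The output is sorted by (start, end) and contains no properly nested
    same-group pairs and no crossing pairs.
    """
    current = sorted(annotations, key=lambda a: (a.start, -(a.end), a.group))
    for _ in range(len(current) + 1):  # fixpoint: each pass strictly shrinks spans
        # rule 1: drop same-group properly nested annotations
        kept = [
            a for a in current
            if not any(b.group == a.group and b.contains(a) for b in current)
        ]
        # rule 2: split crossing pairs at the overlap boundary
        kept.sort(key=lambda a: (a.start, -(a.end), a.group))
        result: list[Annotation] = []
        changed = False
        for ann in kept:
            clipped: Annotation | None = ann
            for prev in result:
                if clipped is not None and prev.crosses(clipped) and prev.end > clipped.start:
                    clipped = _truncate(clipped, prev.end, clipped.surface)
                    changed = True
            if clipped is not None:
                result.append(clipped)
        current = result
        if not changed:
            break
    current.sort(key=lambda a: (a.start, a.end, a.group))
    return current


# ---------------------------------------------------------------------------
# Document-level pipeline and frequencies
# ---------------------------------------------------------------------------

def annotate_document(
    text: str,
    lexicon: Lexicon,
    groups: set[str] | None = None,
    index: MatcherIndex | None = None,
) -> list[Annotation]:
    """build → match → prune for one document; deterministic.

    A prebuilt :class:`MatcherIndex` can be passed to amortize index
    construction over a corpus.  A group filter that matches nothing in the
    document simply yields an empty list.
    """
    if index is None:
        index = build_matcher_index(lexicon, groups)
    return prune_annotations(match_all(text, index))


def term_frequencies(
    documents: Iterable[str],
    lexicon: Lexicon,
    groups: set[str] | None = None,
) -> tuple[Counter, list[Counter]]:
    """Corpus-wide and per-document lemma frequencies of annotated terms.

    Supports prioritizing which subset of a large thesaurus to review by
    how often its terms actually occur in a domain corpus.
    """
    index = build_matcher_index(lexicon, groups)
    total: Counter = Counter()
    per_doc: list[Counter] = []
    for text in documents:
        counts = Counter(a.lemma for a in annotate_document(
            text, lexicon, groups, index=index))
        per_doc.append(counts)
        total.update(counts)
    return total, per_doc


# ---------------------------------------------------------------------------
# BRAT standoff I/O
# ---------------------------------------------------------------------------

def write_brat(annotations: list[Annotation], path: str | Path) -> Path:
    """Write annotations as BRAT standoff (.ann) with CUI normalization lines."""
    path = Path(path)
    lines = []
    for i, ann in enumerate(sorted(annotations, key=lambda a: (a.start, a.end)), 1):
        lines.append(f"T{i}\t{ann.group} {ann.start} {ann.end}\t{ann.surface}")
        for j, cui in enumerate(sorted(ann.cuis), 1):
            lines.append(f"N{i}_{j}\tReference T{i} UMLS:{cui}\t{ann.surface}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


def read_brat(path: str | Path, lexicon: Lexicon | None = None) -> list[Annotation]:
    """Read entity (T) and normalization (N) lines back into annotations."""
    spans: dict[str, tuple[str, int, int, str]] = {}
    cuis: dict[str, set[str]] = defaultdict(set)
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        tid, body, surface = line.split("\t")
        if tid.startswith("T"):
            group, start, end = body.split(" ")
            spans[tid] = (group, int(start), int(end), surface)
        elif tid.startswith("N"):
            _ref, target, norm = body.split(" ")
            cuis[target].add(norm.removeprefix("UMLS:"))
    out = []
    for tid, (group, start, end, surface) in spans.items():
        lemma, pos = surface, PoS.N
        if lexicon is not None:
            entries = lexicon.by_form(surface, folded=True)
            if entries:
                entry = sorted(entries, key=LexicalEntry.sort_key)[0]
                lemma, pos = entry.lemma, entry.pos
        out.append(Annotation(
            start=start, end=end, surface=surface,
            cuis=frozenset(cuis.get(tid, ())), group=group, lemma=lemma, pos=pos,
        ))
    out.sort(key=lambda a: (a.start, a.end, a.group))
    return out
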