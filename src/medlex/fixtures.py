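"""Deterministic synthetic fixtures: lexicons, corpora and vector models.

The real lexicon content is license-gated (UMLS-derived terminology cannot
be redistributed), so every other module is exercised against generated
stand-ins: pseudo-Spanish lemmas built from CV/CVC syllable templates (so
the inflection and conjugation rules apply naturally), unique synthetic
CUIs, corpora with planted entities at recorded offsets, and word-vector
models with planted synonym neighbourhoods.  Everything is a pure function
of a :class:`FixtureSpec` — the same seed regenerates byte-identical
outputs.

The generated lexicon deliberately contains the structures downstream
tests need: duplicate records (merge handling), multiword terms whose head
is a known noun, acronym/full-form pairs mirrored in an abbreviation
Lexical Record, affix entries, distance-1 spelling variants, and
nested/crossing term pairs for the pruning rules.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotator import Annotation, write_brat
from .embedding_expansion import VectorModel
from .lexicon_core import (
    Gender,
    LexicalEntry,
    LexicalRecords,
    Lexicon,
    MorphFeatures,
    Number,
    PoS,
    VariantType,
    WordForm,
    write_lexicon,
)
from .morph_engine import FUNCTION_WORDS, conjugate_verb, inflect_nominal
from .tagger_lemmatizer import OTHER, POS_TO_TAGS, TaggedToken, TagSource, write_conllu

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v", "br", "tr", "pl"]
_VOWELS = ["a", "e", "i", "o", "u"]
_CODAS = ["", "", "", "n", "r", "s", "l"]

_GROUP_TYPES = {
    "ANAT": "Body Part, Organ, or Organ Component",
    "CHEM": "Pharmacologic Substance",
    "DISO": "Disease or Syndrome",
    "PROC": "Therapeutic or Preventive Procedure",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic fixture set."""

    n_concepts: int = 50
    forms_per_concept: tuple[int, int] = (2, 5)
    groups: tuple[str, ...] = ("ANAT", "CHEM", "DISO", "PROC")
    n_docs: int = 8
    tokens_per_doc: tuple[int, int] = (30, 60)
    n_seed_terms: int = 20
    planted_synonyms_per_seed: int = 5
    vocab_size: int = 2000
    dim: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_concepts", "n_docs", "n_seed_terms",
                     "planted_synonyms_per_seed", "vocab_size", "dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _syllable(rng: random.Random) -> str:
    return rng.choice(_ONSETS) + rng.choice(_VOWELS) + rng.choice(_CODAS)


def _pseudo_word(rng: random.Random, n_syllables: tuple[int, int] = (2, 4)) -> str:
    n = rng.randint(*n_syllables)
    word = "".join(_syllable(rng) for _ in range(n))
    # final consonant clusters like -nr are unpronounceable; keep vowel or n/s/r
    while word[-1] == "l":
        word = word[:-1]
    return word


def _fresh_word(rng: random.Random, taken: set[str],
                suffix: str = "") -> str:
    for _ in range(1000):
        word = _pseudo_word(rng) + suffix
        if word not in taken and word not in FUNCTION_WORDS:
            taken.add(word)
            return word
    raise RuntimeError("could not generate a fresh pseudo-word")


def _fresh_cui(rng: random.Random, taken: set[str]) -> str:
    while True:
        cui = f"C{rng.randint(0, 9_999_999):07d}"
        if cui not in taken:
            taken.add(cui)
            return cui


# ---------------------------------------------------------------------------
# Toy lexicon
# ---------------------------------------------------------------------------

def make_toy_lexicon(spec: FixtureSpec) -> Lexicon:
    """Generate a schema-conformant synthetic lexicon.

    Roughly: mostly nouns, some adjectives and verbs, a proper noun, an
    affix; every entry gets its rule-generated inflections; plus the
    structured extras (multiwords, acronyms, variants, nested/crossing
    pairs) that downstream tests rely on.
    """
    rng = random.Random(spec.seed)
    taken_words: set[str] = set()
    taken_cuis: set[str] = set()
    lexicon = Lexicon()
    noun_lemmas: list[str] = []

    def group_of(i: int) -> str:
        return spec.groups[i % len(spec.groups)]

    pos_cycle = [PoS.N, PoS.N, PoS.N, PoS.ADJ, PoS.N, PoS.V, PoS.N, PoS.ADJ_N]
    for i in range(spec.n_concepts):
        pos = pos_cycle[i % len(pos_cycle)]
        group = group_of(i)
        cui = _fresh_cui(rng, taken_cuis)
        if pos is PoS.V:
            lemma = _fresh_word(rng, taken_words, suffix=rng.choice(["ar", "er", "ir"]))
            forms = conjugate_verb(lemma).word_forms()
        else:
            ending = rng.choice(["o", "a", "e", "on", "is"])
            lemma = _fresh_word(rng, taken_words, suffix=ending)
            gender = Gender.MASCULINE if ending == "o" else (
                Gender.FEMININE if ending == "a" else Gender.UNSPECIFIED)
            number = (Number.SINGULAR_AND_PLURAL if lemma.endswith("is")
                      else Number.SINGULAR)
            forms = inflect_nominal(
                lemma, pos, MorphFeatures(gender=gender, number=number))
        # skip entries whose generated surfaces collide with existing ones
        surfaces = {wf.surface for wf in forms}
        if any(lexicon.has_form(s, folded=True) for s in surfaces):
            continue
        taken_words.update(surfaces)
        entry = LexicalEntry(
            lemma=lemma, pos=pos, cuis=frozenset({cui}),
            semantic_types=frozenset({_GROUP_TYPES.get(group, group)}),
            semantic_group=group, forms=frozenset(forms),
        )
        lexicon.add(entry)
        lexicon.add(entry)  # controlled duplicate: exercises merge reporting
        if pos is PoS.N:
            noun_lemmas.append(lemma)

    # one proper noun and one suffix affix entry
    npr = _fresh_word(rng, taken_words).capitalize()
    lexicon.add(LexicalEntry(
        lemma=npr, pos=PoS.NPR, cuis=frozenset({_fresh_cui(rng, taken_cuis)}),
        semantic_types=frozenset({_GROUP_TYPES["CHEM"]}), semantic_group="CHEM",
    ))
    affix = "-" + _pseudo_word(rng, (1, 2)) + "o"
    lexicon.add(LexicalEntry(
        lemma=affix, pos=PoS.AFF, cuis=frozenset({_fresh_cui(rng, taken_cuis)}),
        semantic_types=frozenset({_GROUP_TYPES["CHEM"]}), semantic_group="CHEM",
        forms=frozenset(inflect_nominal(affix, PoS.AFF)),
    ))

    # multiword terms headed by known nouns (head-word morphology, matching)
    heads = noun_lemmas[: max(3, len(noun_lemmas) // 4)]
    for head in heads:
        modifier = _fresh_word(rng, taken_words)
        term = f"{head} de {modifier}"
        lexicon.add(LexicalEntry(
            lemma=term, pos=PoS.N, cuis=frozenset({_fresh_cui(rng, taken_cuis)}),
            semantic_types=frozenset({_GROUP_TYPES["DISO"]}),
            semantic_group="DISO",
        ))

    # acronym pairs: uppercase initial segment of a noun lemma
    for lemma in noun_lemmas[:3]:
        short = lemma[:2].upper() + lemma[2:3].upper()
        if lexicon.has_form(short, folded=True):
            continue
        entries = lexicon.by_lemma(lemma)
        entry = entries[0]
        lexicon.replace_entry(entry, replace(
            entry,
            forms=entry.forms | {WordForm(short, MorphFeatures(
                variant_type=VariantType.ACRONYM))},
        ))

    # distance-1 spelling-variant form on a couple of entries (viriasis-style)
    for lemma in noun_lemmas[3:5]:
        variant = lemma[:-1] + ("u" if lemma[-1] != "u" else "e")
        if lexicon.has_form(variant, folded=True):
            continue
        entry = lexicon.by_lemma(lemma)[0]
        lexicon.replace_entry(entry, replace(
            entry, forms=entry.forms | {WordForm(variant)}))

    # nested pair: a DISO noun and a longer same-group multiword headed by it
    if noun_lemmas:
        head = noun_lemmas[-1]
        nested = f"{head} de {_fresh_word(rng, taken_words)}"
        lexicon.add(LexicalEntry(
            lemma=nested, pos=PoS.N, cuis=frozenset({_fresh_cui(rng, taken_cuis)}),
            semantic_types=frozenset({_GROUP_TYPES["DISO"]}),
            semantic_group="DISO",
        ))
    # crossing pair: "A de B" (PROC) and "B C" (DISO) share the middle token
    a, b, c = (_fresh_word(rng, taken_words) for _ in range(3))
    for term, group in ((f"{a} de {b}", "PROC"), (f"{b} {c}", "DISO")):
        lexicon.add(LexicalEntry(
            lemma=term, pos=PoS.N, cuis=frozenset({_fresh_cui(rng, taken_cuis)}),
            semantic_types=frozenset({_GROUP_TYPES[group]}), semantic_group=group,
        ))
    return lexicon


def make_toy_records(lexicon: Lexicon, spec: FixtureSpec) -> LexicalRecords:
    """Lexical Record tables consistent with the toy lexicon.

    Abbreviation rows pair each acronym-typed form with its full lemma;
    affix rows expose the lexicon's affix entries with glosses; derivation
    tables pair noun and verb entries (used by concept propagation tests).
    """
    records = LexicalRecords()
    verbs = [e for e in lexicon if e.pos is PoS.V]
    nouns = [e for e in lexicon if e.pos is PoS.N and " " not in e.lemma]
    for entry in lexicon:
        for wf in sorted(entry.forms, key=lambda w: w.surface):
            if wf.morph.variant_type is VariantType.ACRONYM:
                records.abbreviations.append((wf.surface, entry.lemma))
        if entry.pos is PoS.AFF:
            cui = min(entry.cuis, default=None)
            records.affixes.append((entry.lemma, f"meaning of {entry.lemma}", cui))
    for noun, verb in zip(nouns, verbs):
        records.deverbal.append((noun.lemma, verb.lemma))
    adjectives = [e for e in lexicon if e.pos is PoS.ADJ]
    for adj, noun in zip(adjectives, nouns[len(verbs):]):
        records.denominal_adj.append((adj.lemma, noun.lemma))
    return records


# ---------------------------------------------------------------------------
# Toy corpus with gold annotations and tags/lemmas
# ---------------------------------------------------------------------------

@dataclass
class ToyCorpus:
    """Documents with their gold standoff annotations and gold tag/lemma rows."""

    documents: list[str]
    gold_annotations: list[list[Annotation]]
    gold_tags: list[list[tuple[str, str, str]]]  # (surface, tag, lemma) per token

    def write(self, outdir: str | Path, lexicon: Lexicon | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, (text, anns, tags) in enumerate(
            zip(self.documents, self.gold_annotations, self.gold_tags), 1
        ):
            (outdir / f"doc{i:03d}.txt").write_text(text, encoding="utf-8")
            write_brat(anns, outdir / f"doc{i:03d}.ann")
            rows = [
                TaggedToken(surface=s, pos=t, lemma=l, source=TagSource.LEXICON)
                for s, t, l in tags
            ]
            write_conllu(rows, outdir / f"doc{i:03d}.conllu")


def _gold_tag_lemma(token: str, lexicon: Lexicon) -> tuple[str, str]:
    entries = lexicon.by_form(token, folded=True)
    if len(entries) == 1 and entries[0].pos in POS_TO_TAGS:
        return POS_TO_TAGS[entries[0].pos][0], entries[0].lemma
    return OTHER, token


def make_toy_corpus(lexicon: Lexicon, spec: FixtureSpec) -> ToyCorpus:
    """Documents embedding known lexicon forms at recorded offsets.

    Each document alternates filler pseudo-words (guaranteed absent from
    the lexicon) with planted lexicon forms; planted spans become gold
    annotations whose surface equals the document slice by construction.
    The last document additionally contains the nested and crossing term
    constructions (without gold spans for the crossing region — those
    exercise the pruning rules, not recovery).
    """
    rng = random.Random(spec.seed + 1)
    taken = set()
    for s in lexicon.all_surfaces():
        for t in s.split():
            taken.add(t)

    plantable = [
        e for e in lexicon
        if e.pos in (PoS.N, PoS.ADJ, PoS.V, PoS.ADJ_N) and e.cuis
    ]
    # keep surfaces that belong to exactly one entry so gold tags are unambiguous
    def plant_forms(entry: LexicalEntry) -> list[str]:
        return sorted(
            wf.surface for wf in entry.forms
            if wf.morph.variant_type is VariantType.NONE
            and len(lexicon.by_form(wf.surface, folded=True)) == 1
        )

    documents, gold_annotations, gold_tags = [], [], []
    for d in range(spec.n_docs):
        n_tokens = rng.randint(*spec.tokens_per_doc)
        pieces: list[str] = []
        anns: list[Annotation] = []
        tags: list[tuple[str, str, str]] = []
        cursor = 0
        budget = n_tokens
        while budget > 0:
            if rng.random() < 0.3 and plantable:
                entry = rng.choice(plantable)
                forms = plant_forms(entry)
                if not forms:
                    budget -= 1
                    continue
                surface = rng.choice(forms)
                start = cursor
                end = start + len(surface)
                anns.append(Annotation(
                    start=start, end=end, surface=surface, cuis=entry.cuis,
                    group=entry.semantic_group, lemma=entry.lemma, pos=entry.pos,
                ))
                pieces.append(surface)
                cursor = end + 1
                for token in surface.split():
                    tag, lemma = _gold_tag_lemma(token, lexicon)
                    tags.append((token, tag, lemma))
                budget -= len(surface.split())
            else:
                filler = _fresh_word(rng, taken)
                pieces.append(filler)
                tags.append((filler, OTHER, filler))
                cursor += len(filler) + 1
                budget -= 1
        text = " ".join(pieces)
        documents.append(text)
        gold_annotations.append(anns)
        gold_tags.append(tags)

    # dedicated overlap-rich document: nested + crossing constructions
    crossing_terms = [
        e.lemma for e in lexicon
        if " " in e.lemma and e.semantic_group in ("PROC", "DISO")
    ]
    overlap_doc = " . ".join(crossing_terms[-4:]) if crossing_terms else ""
    ab = [e.lemma for e in lexicon if e.semantic_group == "PROC" and " de " in e.lemma]
    bc = [e.lemma for e in lexicon if e.semantic_group == "DISO"
          and " " in e.lemma and " de " not in e.lemma]
    if ab and bc and bc[0].split()[0] == ab[0].split()[-1]:
        # "A de B C": the crossing construction proper
        overlap_doc = overlap_doc + " . " + ab[0] + " " + bc[0].split()[1]
    if overlap_doc:
        documents.append(overlap_doc)
        gold_annotations.append([])
        gold_tags.append([
            (t, *_gold_tag_lemma(t, lexicon)) for t in overlap_doc.split()
        ])
    return ToyCorpus(documents, gold_annotations, gold_tags)


# ---------------------------------------------------------------------------
# Toy vector model with planted synonym neighbourhoods
# ---------------------------------------------------------------------------

def make_toy_vectors(
    lexicon: Lexicon, spec: FixtureSpec
) -> tuple[VectorModel, dict[str, list[str]]]:
    """A vector model where each seed has planted near-synonym neighbours.

    Seed tokens are single-word lexicon lemmas; each gets
    ``planted_synonyms_per_seed`` out-of-lexicon tokens at cosine > 0.95,
    while distractor tokens stay below cosine 0.5 to every seed.  Returns
    the model and the seed → planted-token map.
    """
    if spec.dim < 2:
        raise ValueError("vector dimension must be >= 2")
    rng = np.random.default_rng(spec.seed + 2)
    word_rng = random.Random(spec.seed + 3)
    taken = set(lexicon.all_surfaces())

    single = [e.lemma for e in lexicon if " " not in e.lemma and not
              e.lemma.startswith("-")]
    seeds = sorted(single)[: spec.n_seed_terms]
    tokens: list[str] = []
    rows: list[np.ndarray] = []
    planted: dict[str, list[str]] = {}
    seed_vecs: list[np.ndarray] = []

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    for seed_token in seeds:
        v = unit(rng.standard_normal(spec.dim))
        # seeds must be mutually non-confusable: redraw until far from others
        while seed_vecs and max(abs(v @ s) for s in seed_vecs) > 0.4:
            v = unit(rng.standard_normal(spec.dim))
        seed_vecs.append(v)
        tokens.append(seed_token)
        rows.append(v)
        planted[seed_token] = []
        for _ in range(spec.planted_synonyms_per_seed):
            syn = _fresh_word(word_rng, taken)
            w = unit(v + 0.04 * rng.standard_normal(spec.dim))
            while float(v @ w) <= 0.95:
                w = unit(v + 0.03 * rng.standard_normal(spec.dim))
            planted[seed_token].append(syn)
            tokens.append(syn)
            rows.append(w)

    while len(tokens) < spec.vocab_size:
        tok = _fresh_word(word_rng, taken)
        w = unit(rng.standard_normal(spec.dim))
        while seed_vecs and max(float(s @ w) for s in seed_vecs) >= 0.5:
            w = unit(rng.standard_normal(spec.dim))
        tokens.append(tok)
        rows.append(w)

    model = VectorModel(dim=spec.dim, tokens=tokens,
                        matrix=np.vstack(rows))
    return model, planted


# ---------------------------------------------------------------------------
# Fixture-set emission (CLI support)
# ---------------------------------------------------------------------------

def write_fixture_set(outdir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    """Emit lexicon.dsv / lexicon.lmf.xml / LR files / corpus / vectors.vec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexicon = make_toy_lexicon(spec)
    records = make_toy_records(lexicon, spec)
    corpus = make_toy_corpus(lexicon, spec)
    model, _planted = make_toy_vectors(lexicon, spec)

    paths = {
        "dsv": outdir / "lexicon.dsv",
        "lmf": outdir / "lexicon.lmf.xml",
        "vectors": outdir / "vectors.vec",
    }
    write_lexicon(lexicon, paths["dsv"], format="dsv")
    write_lexicon(lexicon, paths["lmf"], format="lmf")
    model.write(paths["vectors"])
    for kind in ("abbreviations", "affixes", "deverbal", "denominal_adj"):
        path = outdir / f"LR_{kind}.dsv"
        rows = getattr(records, kind)
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write("|".join(c for c in row if c is not None) + "\n")
        paths[kind] = path
    corpus.write(outdir / "corpus", lexicon)
    paths["corpus"] = outdir / "corpus"
    return paths
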