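"""Seed-term expansion by cosine nearest neighbours over word vectors.

Neologisms (COVID-19 vocabulary being the motivating case) can be harvested
by taking a small set of seed terms, querying a word-embedding model trained
on topical text for the k = 50 candidates with the highest cosine
similarity

    similarity = cos(s, w) = (s · w) / (‖s‖ · ‖w‖)

to each seed vector s, and keeping the retrieved tokens that are
out-of-vocabulary with respect to the lexicon — candidates for new concept-
mapped terms after a (reproducible, file-driven) UMLS lookup.  A cosine of 1
means token and term are identical in the vector space; 0 means the vectors
are unrelated.

Vectors are consumed, never trained here, in the standard plain-text vector
format (header line ``vocab_size dim``, then one token and ``dim`` floats
per line).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .lexicon_core import Lexicon, MedLexError, fold, nfc

logger = logging.getLogger("medlex")


class OOVQueryError(MedLexError):
    """A query term is absent from the vector-model vocabulary."""


class UndefinedSimilarityError(MedLexError):
    """Cosine similarity is undefined (zero vector or length mismatch)."""


# ---------------------------------------------------------------------------
# Text normalization (mirrors the corpus preparation for vector training)
# ---------------------------------------------------------------------------

_URL_RE = re.compile(r"https?://\S+|www\.\S+")
# a token is a run of word characters, optionally joined by - · ' (so
# COVID-19 stays whole); anything else non-space is punctuation
_TOKEN_RE = re.compile(r"[\w]+(?:[-·'][\w]+)*|[^\w\s]", re.UNICODE)


def normalize_text(raw: str, uncased: bool = False) -> list[str]:
    """Tokenize raw text the way the embedding corpus was normalized.

    URLs and undecodable characters are removed, punctuation is split from
    adjacent tokens, and intra-token hyphens are preserved (``COVID-19`` is
    one token).  ``uncased`` lowercases the stream.
    """
    text = nfc(raw)
    text = _URL_RE.sub(" ", text)
    text = text.encode("utf-8", errors="ignore").decode("utf-8", errors="ignore")
    tokens = _TOKEN_RE.findall(text)
    if uncased:
        tokens = [t.lower() for t in tokens]
    return tokens


# ---------------------------------------------------------------------------
# Vector model
# ---------------------------------------------------------------------------

@dataclass
class VectorModel:
    """A token → dense-vector map supporting cosine nearest-neighbour queries."""

    dim: int
    tokens: list[str]
    matrix: np.ndarray                      # shape (vocab, dim)
    _index: dict[str, int] = field(init=False, repr=False)
    _norms: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.tokens), self.dim):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"({len(self.tokens)}, {self.dim})"
            )
        self._index = {t: i for i, t in enumerate(self.tokens)}
        if len(self._index) != len(self.tokens):
            raise ValueError("duplicate tokens in vector model")
        self._norms = np.linalg.norm(self.matrix, axis=1)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.matrix[self._index[token]]
        except KeyError:
            raise OOVQueryError(f"token {token!r} not in model vocabulary") from None

    @classmethod
    def from_mapping(cls, vectors: Mapping[str, Iterable[float]]) -> "VectorModel":
        tokens = list(vectors)
        matrix = np.array([list(vectors[t]) for t in tokens], dtype=np.float64)
        return cls(dim=matrix.shape[1], tokens=tokens, matrix=matrix)

    @classmethod
    def read(cls, path: str | Path) -> "VectorModel":
        """Read the plain-text vector format (``vocab dim`` header)."""
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise MedLexError(f"{path}: malformed vector-file header")
            vocab, dim = int(header[0]), int(header[1])
            tokens: list[str] = []
            rows = np.empty((vocab, dim), dtype=np.float64)
            for i in range(vocab):
                parts = fh.readline().rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise MedLexError(f"{path}: bad vector line {i + 2}")
                tokens.append(parts[0])
                rows[i] = [float(x) for x in parts[1:]]
        return cls(dim=dim, tokens=tokens, matrix=rows)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.tokens)} {self.dim}\n")
            for token, row in zip(self.tokens, self.matrix):
                floats = " ".join(format(x, ".6g") for x in row)
                fh.write(f"{token} {floats}\n")
        return path


def cosine_similarity(s: np.ndarray, w: np.ndarray) -> float:
    """cos(s, w) = s·w / (‖s‖‖w‖); raises on zero vectors or length mismatch."""
    s = np.asarray(s, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if s.shape != w.shape:
        raise UndefinedSimilarityError(
            f"vector lengths differ: {s.shape} vs {w.shape}"
        )
    ns, nw = np.linalg.norm(s), np.linalg.norm(w)
    if ns == 0.0 or nw == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero vector")
    return float(np.dot(s, w) / (ns * nw))


@dataclass(frozen=True)
class NeighborHit:
    """One retrieved neighbour with its cosine-similarity (CS) value."""

    token: str
    similarity: float


def nearest_neighbors(model: VectorModel, term: str, k: int = 50) -> list[NeighborHit]:
    """Top-k vocabulary tokens by cosine similarity to *term*, descending.

    The query token itself is excluded; ties are broken by codepoint order
    of the token; at most ``vocab − 1`` hits are returned.  The default
    depth of 50 retrieves enough genuinely new terms per seed (shallower
    neighbourhoods are dominated by misspellings of the seed itself).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if term not in model:
        raise OOVQueryError(f"query term {term!r} not in model vocabulary")
    qi = model._index[term]
    q = model.matrix[qi]
    nq = model._norms[qi]
    if nq == 0.0 or np.any(model._norms == 0.0):
        raise UndefinedSimilarityError("zero vector in model")
    sims = model.matrix @ q / (model._norms * nq)
    order = sorted(
        (i for i in range(len(model.tokens)) if i != qi),
        key=lambda i: (-sims[i], model.tokens[i]),
    )
    return [NeighborHit(model.tokens[i], float(sims[i])) for i in order[:k]]


# ---------------------------------------------------------------------------
# OOV filtering and the expansion report
# ---------------------------------------------------------------------------

def filter_oov(hits: Iterable[str], lexicon: Lexicon) -> list[str]:
    """Tokens whose surface matches no lexicon form (NFC, case-folded).

    Order is preserved; duplicates are kept here and deduplicated only in
    the report aggregate.
    """
    return [t for t in hits if not lexicon.has_form(fold(t), folded=True)]


@dataclass
class ExpansionReport:
    """Aggregate outcome of a seed-expansion run.

    ``n_candidates`` is Σ over seeds of min(k, vocab − 1) retrieved tokens;
    ``oov_fraction`` is the percentage of those (raw, with repeats) that are
    out-of-vocabulary for the lexicon; ``oov`` lists the deduplicated OOV
    tokens; ``mappable`` lists OOV tokens resolvable to a CUI through the
    reference mapping with ``mappable_fraction_of_oov`` the corresponding
    percentage of the raw OOV count.
    """

    per_seed: dict[str, list[NeighborHit]]
    skipped_seeds: list[str]
    oov: list[str]
    n_candidates: int
    n_oov_raw: int
    oov_fraction: float
    mappable: list[tuple[str, str]]
    mappable_fraction_of_oov: float

    def to_rows(self) -> list[tuple[str, str, float, str]]:
        """Deterministic delimited-table serialization (seed, token, CS, flag)."""
        oov_set = set(self.oov)
        mapped = dict(self.mappable)
        rows = []
        for seed in sorted(self.per_seed):
            for hit in self.per_seed[seed]:
                flag = "oov" if hit.token in oov_set else "known"
                if hit.token in mapped:
                    flag = f"mapped:{mapped[hit.token]}"
                rows.append((seed, hit.token, round(hit.similarity, 4), flag))
        return rows


def expand_seed_terms(
    model: VectorModel,
    seeds: list[str],
    k: int = 50,
    lexicon: Lexicon | None = None,
    reference_cuis: Mapping[str, str] | None = None,
) -> ExpansionReport:
    """Retrieve k nearest neighbours per seed and report lexicon OOVs.

    Seeds missing from the model vocabulary are reported and skipped; if no
    seed is usable an error is raised.  Tokens found in ``reference_cuis``
    (the reproducible stand-in for a manual UMLS lookup) are counted as
    mappable with their CUI.
    """
    per_seed: dict[str, list[NeighborHit]] = {}
    skipped: list[str] = []
    for seed in seeds:
        if seed in model:
            per_seed[seed] = nearest_neighbors(model, seed, k=k)
        else:
            logger.warning("seed %r not in model vocabulary; skipped", seed)
            skipped.append(seed)
    if not per_seed:
        raise MedLexError("no usable seed terms (all out of vocabulary)")

    raw_tokens = [h.token for seed in per_seed for h in per_seed[seed]]
    n_candidates = len(raw_tokens)
    if lexicon is not None and len(lexicon) > 0:
        raw_oov = filter_oov(raw_tokens, lexicon)
    else:
        raw_oov = list(raw_tokens)
    oov_dedup: list[str] = []
    seen: set[str] = set()
    for t in raw_oov:
        if t not in seen:
            seen.add(t)
            oov_dedup.append(t)
    mappable: list[tuple[str, str]] = []
    if reference_cuis:
        folded_ref = {fold(t): c for t, c in reference_cuis.items()}
        mappable = [
            (t, folded_ref[fold(t)]) for t in oov_dedup if fold(t) in folded_ref
        ]
    n_oov_raw = len(raw_oov)
    n_mappable_raw = sum(
        1 for t in raw_oov if fold(t) in {fold(m) for m, _ in mappable}
    )
    return ExpansionReport(
        per_seed=per_seed,
        skipped_seeds=skipped,
        oov=oov_dedup,
        n_candidates=n_candidates,
        n_oov_raw=n_oov_raw,
        oov_fraction=round(100.0 * n_oov_raw / n_candidates, 2) if n_candidates else 0.0,
        mappable=mappable,
        mappable_fraction_of_oov=(
            round(100.0 * n_mappable_raw / n_oov_raw, 2) if n_oov_raw else 0.0
        ),
    )
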