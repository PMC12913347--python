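"""Cosine semantic similarity over a pluggable word-embedding lexicon.

Semantic relatedness of a target–response pair is the cosine similarity of
their embedding vectors. The lexicon backend is an interface: tests and
simulations use a deterministic in-memory lexicon (loadable from TSV), and
pretrained vectors in the word2vec text format can be loaded for real data.

Two surface-form wrinkles are handled before scoring:

* compounds — a response written solid ("cheesecake") may only exist in the
  vocabulary as an underscore-joined key ("cheese_cake"); both forms are
  scored and the higher value kept;
* capitonyms — lowercasing can hide a sense split ("father" vs "Father");
  the first-letter-capitalized response is also scored when present and the
  higher value kept.

A response with no scoreable surface form is a nonword and is routed to the
phonological comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, runtime_checkable

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ABSENT",
    "EmbeddingLexicon",
    "InMemoryLexicon",
    "SemanticResult",
    "cosine_similarity",
    "load_word2vec_text",
    "semantic_similarity",
    "split_compound",
]


class _Absent:
    """Sentinel for an absent semantic score (nonword response)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "ABSENT"


ABSENT = _Absent()


@runtime_checkable
class EmbeddingLexicon(Protocol):
    """Vector lookup over a fixed vocabulary.

    Keys may include underscore-joined multiword entries and capitalized
    forms. ``vector`` must raise ``KeyError`` for absent keys rather than
    back off to any default.
    """

    dimension: int

    def __contains__(self, word: str) -> bool: ...

    def vector(self, word: str) -> np.ndarray: ...


class InMemoryLexicon:
    """Embedding lexicon backed by a plain dict; the fixture backend.

    Serialized as TSV: one row per word, ``word<TAB>c1,c2,...,cD``.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ConfigurationError("embedding lexicon is empty")
        dims = {len(np.asarray(v).ravel()) for v in vectors.values()}
        if len(dims) != 1:
            raise ConfigurationError(f"inconsistent vector dimensions in lexicon: {sorted(dims)}")
        self.dimension = dims.pop()
        self._vectors = {w: np.asarray(v, dtype=float).ravel() for w, v in vectors.items()}
        for w, v in self._vectors.items():
            if not np.linalg.norm(v) > 0:
                raise ConfigurationError(f"zero vector for word {w!r}")

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def __iter__(self):
        return iter(self._vectors)

    def vector(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for word in self._vectors:
                comps = ",".join(repr(float(c)) for c in self._vectors[word])
                fh.write(f"{word}\t{comps}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "InMemoryLexicon":
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                word, _, comps = line.partition("\t")
                vectors[word] = np.array(comps.split(","), dtype=float)
        return cls(vectors)


def load_word2vec_text(path: str | Path, limit: int | None = None) -> InMemoryLexicon:
    """Load pretrained vectors in the word2vec *text* format.

    The first line is ``<vocab_size> <dimension>``; each following line is a
    word and its components, space-separated. ``limit`` truncates the
    vocabulary (the pretrained general-corpus models are large; naming-task
    vocabulary sits well inside the most frequent entries).
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8", errors="replace") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ConfigurationError(f"not a word2vec text file: {path}")
        _, dim = (int(x) for x in header)
        for i, line in enumerate(fh):
            if limit is not None and i >= limit:
                break
            parts = line.rstrip("\n").split(" ")
            word, comps = parts[0], parts[1:]
            if len(comps) != dim:
                continue  # malformed row; skip rather than abort a huge file
            vectors[word] = np.array(comps, dtype=float)
    return InMemoryLexicon(vectors)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Raises ``ValueError`` on dimension mismatch or a zero vector.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def split_compound(response: str, lex: EmbeddingLexicon, max_parts: int = 3) -> Optional[str]:
    """Underscore-joined decomposition of a solid compound, if the joined
    form is a vocabulary key; ``None`` otherwise.

    All contiguous splits into 2..``max_parts`` parts (each part at least
    two characters) are tried; the first vocabulary hit, preferring fewer
    parts and earlier split points, is returned.
    """
    n = len(response)

    def _splits(start: int, parts_left: int) -> Iterable[tuple[str, ...]]:
        if parts_left == 1:
            if n - start >= 2:
                yield (response[start:],)
            return
        for cut in range(start + 2, n - 1):
            for rest in _splits(cut, parts_left - 1):
                yield (response[start:cut],) + rest

    for n_parts in range(2, max_parts + 1):
        for parts in _splits(0, n_parts):
            joined = "_".join(parts)
            if joined in lex:
                return joined
    return None


@dataclass(frozen=True)
class SemanticResult:
    """Outcome of semantic scoring for one pair.

    ``score`` is the maximum cosine over the scored surface variants, or
    :data:`ABSENT` when no variant is in the vocabulary (``is_nonword``).
    """

    score: float | _Absent
    is_nonword: bool
    variant_used: Optional[str] = None


def semantic_similarity(
    target: str,
    response: str,
    lex: EmbeddingLexicon,
    *,
    capitonym_target: bool = False,
) -> SemanticResult:
    """Score a lemmatized, lowercased target–response pair.

    Candidate response forms are the response itself, its underscore-joined
    compound decomposition (when that key exists), and its first-letter
    capitalization (when that key exists); the score is the maximum cosine
    over the candidates. With ``capitonym_target`` the capitalized target is
    additionally paired against every candidate.

    Raises :class:`ConfigurationError` when the target is absent from the
    vocabulary: targets are test items and must resolve.
    """
    if target not in lex:
        raise ConfigurationError(f"target word {target!r} not in embedding vocabulary")

    candidates = [response] if response in lex else []
    joined = split_compound(response, lex)
    if joined is not None:
        candidates.append(joined)
    capitalized = response[:1].upper() + response[1:]
    if capitalized != response and capitalized in lex:
        candidates.append(capitalized)

    if not candidates:
        return SemanticResult(score=ABSENT, is_nonword=True)

    target_forms = [target]
    if capitonym_target:
        cap_t = target[:1].upper() + target[1:]
        if cap_t != target and cap_t in lex:
            target_forms.append(cap_t)

    best, best_variant = -np.inf, None
    for t_form in target_forms:
        tv = lex.vector(t_form)
        for cand in candidates:
            s = cosine_similarity(tv, lex.vector(cand))
            if s > best:
                best, best_variant = s, cand
    return SemanticResult(score=best, is_nonword=False, variant_used=best_variant)
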