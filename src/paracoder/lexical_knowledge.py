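"""Special-case lexical resolvers: onomatopoeia, synonyms, and
hypernym/hyponym detection via the lowest common hypernym.

These checks run before any similarity scoring. An onomatopoeic response
("purr" for *cat*) carries no lexical retrieval and is a non-response; a
synonym ("tv" for *television*) is a correct naming; a response one level
up or down the category hierarchy ("animal" or "Doberman" for *dog*) is
tagged explicitly rather than lumped in with semantic errors.

The knowledge base is a pluggable interface. The packaged fixture KB is a
small hand-built JSON taxonomy (a DAG of synsets with lemma lists and
parent links, plus per-word sense inventories in frequency order and
synonym sets) mirroring the structure of the large lexical databases the
method is designed to run against; an adapter over such a database can be
dropped in by constructing :class:`LexicalKB` from its export.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigurationError

__all__ = [
    "HierarchyTag",
    "LexicalKB",
    "is_onomatopoeia",
    "is_synonym",
    "load_onomatopoeia",
    "packaged_kb",
    "packaged_onomatopoeia",
    "resolve_hierarchy",
]


class HierarchyTag(enum.Enum):
    HYPONYM = "HYPONYM"
    HYPERNYM = "HYPERNYM"
    NONE = "NONE"


@dataclass
class LexicalKB:
    """Synonym sets, sense inventories, and a hypernym DAG.

    ``synonyms``: word -> set of synonym words (noun senses, lemmatized
    lowercase; the word itself need not be listed).
    ``senses``: word -> ordered list of (synset id, part of speech), most
    frequent sense first.
    ``synsets``: synset id -> {"lemmas": [...], "parents": [...]}.
    """

    synonyms: Mapping[str, set[str]]
    senses: Mapping[str, Sequence[tuple[str, str]]]
    synsets: Mapping[str, Mapping[str, Sequence[str]]]
    _depth_cache: dict[str, int] = field(default_factory=dict, repr=False)

    @classmethod
    def from_json(cls, path: str | Path) -> "LexicalKB":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "LexicalKB":
        return cls(
            synonyms={w: set(s) for w, s in payload.get("synonyms", {}).items()},
            senses={w: [tuple(p) for p in lst] for w, lst in payload.get("senses", {}).items()},
            synsets=payload.get("synsets", {}),
        )

    def to_dict(self) -> dict:
        return {
            "synonyms": {w: sorted(s) for w, s in self.synonyms.items()},
            "senses": {w: [list(p) for p in lst] for w, lst in self.senses.items()},
            "synsets": {k: dict(v) for k, v in self.synsets.items()},
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, ensure_ascii=False, indent=1, sort_keys=True)

    # -- hierarchy plumbing ------------------------------------------------

    def noun_synsets(self, word: str) -> list[str]:
        return [sid for sid, pos in self.senses.get(word, []) if pos == "n"]

    def is_noun_predominant(self, word: str) -> bool:
        """True when the word's first-listed (most frequent) sense is a noun."""
        senses = self.senses.get(word, ())
        return bool(senses) and senses[0][1] == "n"

    def lemmas(self, synset_id: str) -> Sequence[str]:
        return self.synsets.get(synset_id, {}).get("lemmas", ())

    def parents(self, synset_id: str) -> Sequence[str]:
        return self.synsets.get(synset_id, {}).get("parents", ())

    def _ancestors(self, synset_id: str) -> set[str]:
        """All hypernym ancestors of a synset, inclusive of itself."""
        seen: set[str] = set()
        stack = [synset_id]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(self.parents(node))
        return seen

    def _depth(self, synset_id: str) -> int:
        """Longest hypernym path from the synset up to a root."""
        cached = self._depth_cache.get(synset_id)
        if cached is not None:
            return cached
        parents = self.parents(synset_id)
        depth = 0 if not parents else 1 + max(self._depth(p) for p in parents)
        self._depth_cache[synset_id] = depth
        return depth

    def lowest_common_hypernyms(self, a: str, b: str) -> list[str]:
        """Deepest common ancestors of two synsets (inclusive); may be
        several when the DAG branches symmetrically."""
        common = self._ancestors(a) & self._ancestors(b)
        if not common:
            return []
        best = max(self._depth(n) for n in common)
        return sorted(n for n in common if self._depth(n) == best)


def load_onomatopoeia(path: str | Path) -> frozenset[str]:
    """Load the onomatopoeia word list: plain text, one lowercase word per
    line, '#' comments allowed."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"onomatopoeia list not found: {path}")
    words = []
    for line in p.read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.append(word)
    return frozenset(words)


@lru_cache(maxsize=1)
def packaged_onomatopoeia() -> frozenset[str]:
    """The packaged list of common English onomatopoeia."""
    with resources.as_file(resources.files("paracoder").joinpath("data/onomatopoeia.txt")) as p:
        return load_onomatopoeia(p)


def packaged_kb() -> LexicalKB:
    """The packaged hand-built fixture knowledge base (~60 words)."""
    with resources.as_file(resources.files("paracoder").joinpath("data/kb_fixture.json")) as p:
        return LexicalKB.from_json(p)


def is_onomatopoeia(response: str, word_list: Iterable[str]) -> bool:
    """True iff the (lemmatized, lowercase) response imitates a sound."""
    return bool(response) and response in word_list


def is_synonym(target: str, response: str, kb: LexicalKB) -> bool:
    """True iff the response names the target correctly: identical to it or
    listed among its synonyms."""
    return response == target or response in kb.synonyms.get(target, ())


def resolve_hierarchy(target: str, response: str, kb: LexicalKB) -> HierarchyTag:
    """Classify the pair by the lowest common hypernym of their noun senses.

    If any LCH carries the target as a lemma the response sits below it
    (HYPONYM); if any LCH carries the response the response sits above
    (HYPERNYM); HYPONYM is checked first across all noun-sense pairs, making
    ties deterministic. NONE means no direct hierarchical link and the pair
    proceeds to semantic scoring. Identity and absent words yield NONE
    (identity is a correct response, caught by the synonym check upstream).
    """
    if target == response:
        return HierarchyTag.NONE
    t_syns = kb.noun_synsets(target)
    r_syns = kb.noun_synsets(response)
    if set(t_syns) & set(r_syns):
        # co-lemmas of a shared synset are synonyms, not hierarchy
        return HierarchyTag.NONE
    lch_lemma_sets = [
        frozenset(kb.lemmas(n))
        for st in t_syns
        for sr in r_syns
        for n in kb.lowest_common_hypernyms(st, sr)
    ]
    if any(target in lemmas for lemmas in lch_lemma_sets):
        return HierarchyTag.HYPONYM
    if any(response in lemmas for lemmas in lch_lemma_sets):
        return HierarchyTag.HYPERNYM
    return HierarchyTag.NONE
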