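"""Deterministic synthetic lexicons and simulated naming datasets.

Everything the coding pipeline consumes can be generated offline and
seeded: an embedding lexicon with planted semantic clusters, a toy
taxonomy/synonym knowledge base, an IPA lexicon, and trial tables whose
human tags are known by construction.

The generator emulates the structure of a multi-session picture-naming
study: ``n_subjects`` participants each attempt ``n_items`` target
pictures ``trials_per_item`` times, and each trial's response is drawn
from a mixture over the seven response categories. Responses are built to
respect planted generative thresholds ``s_star`` and ``p_star``:

* same-cluster words score above ``s_star`` semantically (within-cluster
  cosine ~ ``within_cos``), different-cluster words score 0;
* phonological neighbours are single-phoneme edits of the target (similarity
  >= 0.75 for the word lengths used), while phonologically unrelated
  responses are built from a disjoint phoneme inventory (similarity exactly
  0) — so every binary decision is separable at the planted thresholds.

Words are pronounceable CV pseudo-words with a one-to-one letter-to-IPA
map, split into two disjoint phoneme inventories (one for targets and
their neighbours, one for phonologically unrelated material).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .lexical_knowledge import LexicalKB
from .phonology import phon_similarity
from .semantics import InMemoryLexicon
from .tagger import ErrorTag
from .datasets_io import TrialRecord, lemmatize

__all__ = ["FixtureResources", "SimSpec", "build_fixture_lexicon", "simulate_trials"]

# Two disjoint inventories; orthography letter -> IPA symbol.
_INV_A_CONS = {"p": "p", "t": "t", "k": "k", "m": "m", "s": "s", "l": "l"}
_INV_A_VOW = {"a": "ɑ", "e": "ɛ", "i": "i"}
_INV_B_CONS = {"b": "b", "d": "d", "g": "ɡ", "n": "n", "f": "f", "r": "r"}
_INV_B_VOW = {"o": "ɔ", "u": "u", "y": "ʊ"}

_DEFAULT_MIXTURE = {
    "R": 0.55, "S": 0.13, "F": 0.08, "M": 0.06, "U": 0.08, "N": 0.06, "NU": 0.04,
}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the simulated study.

    Defaults mirror a single-session pass of a 38-participant, 175-item
    naming battery. ``mixture`` gives the response-category proportions;
    ``s_star``/``p_star`` are the planted generative thresholds the
    response construction respects; ``within_cos`` the planted
    within-cluster cosine (between-cluster cosine is 0);
    ``cluster_margin`` the required separation between the smallest
    within-cluster and largest between-cluster cosine; ``edit_rates``
    the (substitute, insert, delete) probabilities used when deriving
    phonological neighbours and nonwords; ``label_noise`` the probability
    that a trial's human tag is replaced by a different random category.
    """

    n_subjects: int = 38
    n_items: int = 175
    trials_per_item: int = 1
    mixture: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIXTURE))
    within_cos: float = 0.75
    cos_jitter: float = 0.04
    cluster_margin: float = 0.3
    s_star: float = 0.40
    p_star: float = 0.25
    edit_rates: tuple[float, float, float] = (0.6, 0.2, 0.2)
    synonym_rate: float = 0.2
    label_noise: float = 0.0
    seed: int = 20260217

    def __post_init__(self):
        if not math.isclose(sum(self.mixture.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture proportions sum to {sum(self.mixture.values())}, not 1")
        unknown = set(self.mixture) - set(_DEFAULT_MIXTURE)
        if unknown:
            raise ValueError(f"unknown mixture categories: {sorted(unknown)}")
        for name in ("s_star", "p_star"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if any(not 0.0 <= r <= 1.0 for r in self.edit_rates) or \
                not math.isclose(sum(self.edit_rates), 1.0, abs_tol=1e-9):
            raise ValueError(f"edit rates must lie in [0,1] and sum to 1: {self.edit_rates}")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError(f"label_noise={self.label_noise} outside [0, 1)")


@dataclass
class FixtureResources:
    """Everything simulate_trials and the pipeline need, generated as one
    consistent unit."""

    lexicon: InMemoryLexicon
    kb: LexicalKB
    ipa: dict[str, str]                      # word -> IPA transcription
    clusters: dict[str, int]                 # word -> planted cluster index
    roles: list[dict[str, str]]              # per item: target / m / s / f / u words
    synonyms: dict[str, str]                 # target -> synonym word
    taxonomy_triple: tuple[str, str, str]    # (basic target, hyponym, hypernym)


class _WordFactory:
    """Generates unique CV pseudo-words from one phoneme inventory."""

    def __init__(self, cons: Mapping[str, str], vow: Mapping[str, str], rng: np.random.Generator):
        self.cons = list(cons.items())
        self.vow = list(vow.items())
        self.rng = rng
        self.taken: set[str] = set()

    def new_word(self, n_syllables: Optional[int] = None) -> tuple[str, str]:
        """A fresh (orthography, IPA) pair, vowel-final so lemmatization is
        a no-op."""
        for _ in range(10_000):
            n = int(n_syllables or self.rng.integers(2, 4))
            ortho, ipa = [], []
            for _ in range(n):
                c = self.cons[self.rng.integers(len(self.cons))]
                v = self.vow[self.rng.integers(len(self.vow))]
                ortho += [c[0], v[0]]
                ipa += [c[1], v[1]]
            word = "".join(ortho)
            if word not in self.taken:
                self.taken.add(word)
                return word, "".join(ipa)
        raise RuntimeError("exhausted pseudo-word space")  # pragma: no cover

    def edit(self, ipa: str, rates: tuple[float, float, float]) -> tuple[str, str]:
        """Apply one random single-phoneme edit, staying inside this
        inventory and keeping consonants/vowels in place for
        substitutions. Returns (orthography, IPA) of the edited form."""
        ipa_to_ortho = {p: o for o, p in self.cons + self.vow}
        cons_ipa = [p for _, p in self.cons]
        vow_ipa = [p for _, p in self.vow]
        for _ in range(10_000):
            symbols = list(ipa)
            op = self.rng.choice(3, p=rates)
            pos = int(self.rng.integers(len(symbols)))
            if op == 0:  # substitute, same class
                pool = cons_ipa if symbols[pos] in cons_ipa else vow_ipa
                repl = pool[self.rng.integers(len(pool))]
                if repl == symbols[pos]:
                    continue
                symbols[pos] = repl
            elif op == 1:  # insert
                pool = cons_ipa + vow_ipa
                symbols.insert(pos, pool[self.rng.integers(len(pool))])
            else:  # delete
                if len(symbols) <= 2:
                    continue
                del symbols[pos]
            new_ipa = "".join(symbols)
            if new_ipa == ipa:
                continue
            ortho = "".join(ipa_to_ortho[s] for s in symbols)
            # orthography must survive ingest lemmatization unchanged
            if ortho in self.taken or lemmatize(ortho) != ortho:
                continue
            self.taken.add(ortho)
            return ortho, new_ipa
        raise RuntimeError("could not derive a fresh edited form")  # pragma: no cover


def build_fixture_lexicon(spec: SimSpec,
                          rng: Optional[np.random.Generator] = None) -> FixtureResources:
    """Build the planted-cluster embedding lexicon, toy knowledge base and
    IPA lexicon for a simulation spec.

    Each item owns a cluster {target, mixed neighbour, semantic
    neighbour}; all formal and unrelated distractors live in one extra
    cluster. Cluster directions are orthogonal and every word keeps a
    private residual dimension, so between-cluster cosines are exactly 0
    and within-cluster cosines concentrate around ``within_cos``. Raises
    ``ValueError`` when the requested margin cannot be realized.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    min_within = spec.within_cos - spec.cos_jitter
    if spec.within_cos + spec.cos_jitter > 1.0 or min_within <= 0.0:
        raise ValueError(f"within_cos={spec.within_cos} with jitter {spec.cos_jitter} "
                         "leaves [0, 1]")
    if min_within - 0.0 < spec.cluster_margin:
        raise ValueError(
            f"cluster margin {spec.cluster_margin} infeasible: smallest within-cluster "
            f"cosine {min_within:.3f} vs between-cluster cosine 0.0")
    if not 0.0 < spec.s_star <= min_within:
        raise ValueError(f"s_star={spec.s_star} outside the separability gap (0, {min_within:.3f}]")

    fac_a = _WordFactory(_INV_A_CONS, _INV_A_VOW, rng)
    fac_b = _WordFactory(_INV_B_CONS, _INV_B_VOW, rng)
    # Shared uniqueness pool across inventories (letters are disjoint anyway).
    fac_b.taken = fac_a.taken

    ipa: dict[str, str] = {}
    clusters: dict[str, int] = {}
    roles: list[dict[str, str]] = []
    synonyms: dict[str, str] = {}
    distractor_cluster = spec.n_items

    for i in range(spec.n_items):
        target, t_ipa = fac_a.new_word()
        m_word, m_ipa = fac_a.edit(t_ipa, spec.edit_rates)     # same cluster, 1 edit away
        s_word, s_ipa = fac_b.new_word()                       # same cluster, disjoint phonemes
        f_word, f_ipa = fac_a.edit(t_ipa, spec.edit_rates)     # other cluster, 1 edit away
        u_word, u_ipa = fac_b.new_word()                       # other cluster, disjoint phonemes
        syn_word, syn_ipa = fac_b.new_word()
        for w, p in ((target, t_ipa), (m_word, m_ipa), (s_word, s_ipa),
                     (f_word, f_ipa), (u_word, u_ipa), (syn_word, syn_ipa)):
            ipa[w] = p
        clusters[target] = clusters[m_word] = clusters[s_word] = i
        clusters[f_word] = clusters[u_word] = distractor_cluster
        roles.append({"target": target, "m": m_word, "s": s_word, "f": f_word, "u": u_word})
        synonyms[target] = syn_word

    # Embedding vectors: sqrt(w)*cluster_axis + sqrt(1-w)*private_axis.
    vocab = list(clusters)
    n_clusters = spec.n_items + 1
    dim = n_clusters + len(vocab)
    vectors: dict[str, np.ndarray] = {}
    for j, word in enumerate(vocab):
        w = spec.within_cos + rng.uniform(-spec.cos_jitter, spec.cos_jitter)
        v = np.zeros(dim)
        v[clusters[word]] = math.sqrt(w)
        v[n_clusters + j] = math.sqrt(1.0 - w)
        vectors[word] = v
    lexicon = InMemoryLexicon(vectors)

    # Toy taxonomy: the first target gets one hyponym and one hypernym,
    # linked through a synset chain; every word has a noun-first sense.
    basic = roles[0]["target"]
    child, child_ipa = fac_a.new_word()
    parent, parent_ipa = fac_b.new_word()
    ipa[child], ipa[parent] = child_ipa, parent_ipa
    all_words = set(ipa)
    senses = {w: [(f"{w}.n.01", "n")] for w in all_words}
    synsets: dict[str, dict] = {f"{w}.n.01": {"lemmas": [w], "parents": []} for w in all_words}
    synsets[f"{child}.n.01"]["parents"] = [f"{basic}.n.01"]
    synsets[f"{basic}.n.01"]["parents"] = [f"{parent}.n.01"]
    kb = LexicalKB(
        synonyms={t: {s} for t, s in synonyms.items()} | {s: {t} for t, s in synonyms.items()},
        senses=senses,
        synsets=synsets,
    )
    return FixtureResources(lexicon=lexicon, kb=kb, ipa=ipa, clusters=clusters,
                            roles=roles, synonyms=synonyms,
                            taxonomy_triple=(basic, child, parent))


_TAGS = tuple(_DEFAULT_MIXTURE)  # canonical category order for drawing


def simulate_trials(
    spec: SimSpec,
    resources: Optional[FixtureResources] = None,
) -> tuple[list[TrialRecord], FixtureResources]:
    """Simulate a human-coded trial table.

    For each subject x item x repetition a category is drawn from the
    mixture and a response consistent with it is constructed (see module
    docstring). The human tag records the drawn category, optionally
    corrupted at ``label_noise``. The run is fully determined by
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if resources is None:
        resources = build_fixture_lexicon(spec, rng)
    res = resources
    vocab_and_kb = set(res.ipa)

    fac_a = _WordFactory(_INV_A_CONS, _INV_A_VOW, rng)
    fac_b = _WordFactory(_INV_B_CONS, _INV_B_VOW, rng)
    fac_a.taken = fac_b.taken = set(vocab_and_kb)

    cats = [c for c in _TAGS if spec.mixture.get(c, 0.0) > 0]
    probs = np.array([spec.mixture[c] for c in cats], dtype=float)
    probs /= probs.sum()

    trials: list[TrialRecord] = []
    for s in range(spec.n_subjects):
        subject_id = f"S{s:03d}"
        for i in range(spec.n_items):
            item = res.roles[i]
            target = item["target"]
            t_ipa = res.ipa[target]
            for _ in range(spec.trials_per_item):
                cat = cats[rng.choice(len(cats), p=probs)]
                if cat == "R":
                    if rng.random() < spec.synonym_rate:
                        response = res.synonyms[target]
                    else:
                        response = target
                    r_ipa = res.ipa[response]
                elif cat in ("S", "M", "F", "U"):
                    response = item[cat.lower()]
                    r_ipa = res.ipa[response]
                elif cat == "N":
                    response, r_ipa = fac_a.edit(t_ipa, spec.edit_rates)
                else:  # NU
                    response, r_ipa = fac_b.new_word()
                _check_planted(cat, t_ipa, r_ipa, spec)

                trials.append(TrialRecord(
                    subject_id=subject_id,
                    item_id=f"I{i:03d}",
                    target=target,
                    response=response,
                    target_ipa=t_ipa,
                    response_ipa=r_ipa,
                    human_tag=ErrorTag(cat),
                    response_surface=response,
                ))

    if spec.label_noise > 0:
        # dedicated stream so the same seed yields the same underlying
        # trials with and without label corruption
        noise_rng = np.random.default_rng([spec.seed, 1])
        noised = []
        for t in trials:
            if noise_rng.random() < spec.label_noise:
                others = [c for c in _TAGS if c != t.human_tag.value]
                t = replace(t, human_tag=ErrorTag(others[noise_rng.choice(len(others))]))
            noised.append(t)
        trials = noised
    return trials, res


def _check_planted(cat: str, t_ipa: str, r_ipa: str, spec: SimSpec) -> None:
    """Defensive check that a constructed response respects the planted
    phonological threshold (the generator guarantees it; violations mean
    the lexicon is too small or the spec inconsistent)."""
    if cat == "R":
        return
    sim = phon_similarity(t_ipa, r_ipa).similarity
    related = cat in ("F", "M", "N")
    if related and sim < spec.p_star:
        raise ValueError(f"{cat} response violates planted p*: sim={sim:.3f}")
    if not related and sim >= spec.p_star:
        raise ValueError(f"{cat} response violates planted p*: sim={sim:.3f}")
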