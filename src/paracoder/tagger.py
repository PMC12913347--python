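"""The coding cascade: special cases, similarity scores, threshold
binarization, final tag.

Each trial receives exactly one tag. The cascade order is fixed — first
match wins:

1. onomatopoeic response            -> NR (non-response)
2. identity or synonym              -> R  (correct)
3. hierarchy link (noun responses)  -> HYPERNYM / HYPONYM
4. response absent from vocabulary  -> nonword route: N if phonologically
                                       related else NU
5. lexical route: the (semantic, phonological) binary decisions map
   (yes, no) -> S, (no, yes) -> F, (yes, yes) -> M, (no, no) -> U

Binarization is inclusive on both dimensions: a score counts as related
when it is greater than or equal to the threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional

from .datasets_io import TrialRecord
from .errors import MalformedTrialError
from .lexical_knowledge import HierarchyTag, LexicalKB, is_onomatopoeia, is_synonym, resolve_hierarchy
from .phonology import PhonComparison, phon_similarity
from .semantics import ABSENT, EmbeddingLexicon, SemanticResult, semantic_similarity

__all__ = [
    "CodedTrial", "ErrorTag", "PrecodedTrial", "Thresholds", "binarize",
    "code_trial", "code_trials", "finalize_trial", "precode_trial", "score_trial",
]


class ErrorTag(enum.Enum):
    """Closed tag vocabulary: the seven standard paraphasia codes, the
    non-response code, and the two explicit hierarchy codes."""

    R = "R"            # correct (target or synonym)
    S = "S"            # semantic error
    F = "F"            # phonological (formal) error
    M = "M"            # mixed error
    U = "U"            # unrelated word
    N = "N"            # phonologically related nonword
    NU = "NU"          # phonologically unrelated nonword
    NR = "NR"          # non-response / excluded
    HYPERNYM = "HYPERNYM"
    HYPONYM = "HYPONYM"


HUMAN_TAGS = frozenset({ErrorTag.R, ErrorTag.S, ErrorTag.F, ErrorTag.M,
                        ErrorTag.U, ErrorTag.N, ErrorTag.NU, ErrorTag.NR})


@dataclass(frozen=True)
class Thresholds:
    """Semantic (s) and phonological (p) cutoffs, both in [0, 1]."""

    s: float
    p: float

    def __post_init__(self):
        for name, v in (("s", self.s), ("p", self.p)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


def binarize(score: float, threshold: float) -> bool:
    """Related iff the score is greater than or equal to the cutoff."""
    return score >= threshold


@dataclass(frozen=True)
class CodedTrial:
    trial: TrialRecord
    semantic: Optional[SemanticResult]
    phonological: Optional[PhonComparison]
    sem_related: Optional[bool]
    phon_related: Optional[bool]
    tag: ErrorTag
    rule_fired: str


def score_trial(
    trial: TrialRecord,
    lex: EmbeddingLexicon,
    *,
    capitonym_target: bool = False,
) -> tuple[SemanticResult, PhonComparison]:
    """Raw semantic and phonological scores for one pair, independent of
    any threshold; used both by the cascade and by threshold training."""
    sem = semantic_similarity(trial.target, trial.response, lex,
                              capitonym_target=capitonym_target)
    phon = phon_similarity(trial.target_ipa, trial.response_ipa)
    return sem, phon


@dataclass(frozen=True)
class PrecodedTrial:
    """Threshold-independent cascade state for one trial.

    Either the cascade already decided a fixed tag (excluded passthrough,
    onomatopoeia, synonym, hierarchy), or the trial reached the scoring
    stage and carries its raw scores; :func:`finalize_trial` turns either
    into a :class:`CodedTrial` once thresholds are known.
    """

    trial: TrialRecord
    fixed_tag: Optional[ErrorTag]
    rule_fired: str
    semantic: Optional[SemanticResult] = None
    phonological: Optional[PhonComparison] = None


def precode_trial(
    trial: TrialRecord,
    lex: EmbeddingLexicon,
    kb: LexicalKB,
    onomatopoeia: Iterable[str],
    *,
    capitonym_target: bool = False,
) -> PrecodedTrial:
    """Run every cascade step that does not depend on the thresholds."""
    if trial.excluded:
        tag = trial.human_tag if trial.human_tag is not None else ErrorTag.NR
        return PrecodedTrial(trial, tag, "excluded_passthrough")
    if not trial.target or not trial.response:
        raise MalformedTrialError(
            f"trial {trial.subject_id}/{trial.item_id}: missing target or response")

    if is_onomatopoeia(trial.response, onomatopoeia):
        return PrecodedTrial(trial, ErrorTag.NR, "onomatopoeia")

    if is_synonym(trial.target, trial.response, kb):
        return PrecodedTrial(trial, ErrorTag.R, "synonym")

    if kb.is_noun_predominant(trial.response):
        link = resolve_hierarchy(trial.target, trial.response, kb)
        if link is HierarchyTag.HYPONYM:
            return PrecodedTrial(trial, ErrorTag.HYPONYM, "hierarchy")
        if link is HierarchyTag.HYPERNYM:
            return PrecodedTrial(trial, ErrorTag.HYPERNYM, "hierarchy")

    sem, phon = score_trial(trial, lex, capitonym_target=capitonym_target)
    rule = "nonword_route" if sem.is_nonword else "lexical_route"
    return PrecodedTrial(trial, None, rule, semantic=sem, phonological=phon)


def finalize_trial(pre: PrecodedTrial, thresholds: Thresholds) -> CodedTrial:
    """Apply threshold binarization to a precoded trial."""
    if pre.fixed_tag is not None:
        return CodedTrial(pre.trial, None, None, None, None, pre.fixed_tag, pre.rule_fired)

    sem, phon = pre.semantic, pre.phonological
    phon_rel = binarize(phon.similarity, thresholds.p)
    if sem.is_nonword:
        tag = ErrorTag.N if phon_rel else ErrorTag.NU
        return CodedTrial(pre.trial, sem, phon, None, phon_rel, tag, pre.rule_fired)

    sem_rel = binarize(sem.score, thresholds.s)
    tag = {
        (True, False): ErrorTag.S,
        (False, True): ErrorTag.F,
        (True, True): ErrorTag.M,
        (False, False): ErrorTag.U,
    }[(sem_rel, phon_rel)]
    return CodedTrial(pre.trial, sem, phon, sem_rel, phon_rel, tag, pre.rule_fired)


def code_trial(
    trial: TrialRecord,
    thresholds: Thresholds,
    lex: EmbeddingLexicon,
    kb: LexicalKB,
    onomatopoeia: Iterable[str],
    *,
    capitonym_target: bool = False,
) -> CodedTrial:
    """Assign one final tag to a trial via the decision cascade.

    Trials pre-marked excluded (visual errors, descriptions, no response)
    pass through untouched, keeping their given code or NR. Raises
    :class:`MalformedTrialError` for a missing target or response.
    """
    pre = precode_trial(trial, lex, kb, onomatopoeia, capitonym_target=capitonym_target)
    return finalize_trial(pre, thresholds)


def code_trials(trials, thresholds, lex, kb, onomatopoeia, **kwargs) -> list[CodedTrial]:
    """Code a whole trial list, preserving order."""
    return [code_trial(t, thresholds, lex, kb, onomatopoeia, **kwargs) for t in trials]
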