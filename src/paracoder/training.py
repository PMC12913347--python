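"""Threshold training: binary standards from human codes, grid search.

Human seven-category codes are collapsed into two binary ground truths.
For the semantic dimension, S and M count as semantically related, F and U
as unrelated; nonword trials (N, NU) carry no semantic judgment and are
dropped, as are non-responses (NR) and correct responses (R), which the
cascade short-circuits before scoring. For the phonological dimension, F,
M and N count as related and S, U and NU as unrelated; NR and R are
dropped.

The optimal cutoff on each dimension is then found by exhaustive grid
search: by default 1001 candidate thresholds from 0 to 1 in steps of
0.001, each scored by its agreement with the binary standard under the
inclusive rule (score >= threshold counts as related). Ties are broken
toward the smallest threshold so results are reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import MalformedTrialError
from .tagger import ErrorTag

__all__ = [
    "BinaryStandard",
    "Dimension",
    "GridSearchResult",
    "ScoredTrial",
    "binarize_standard",
    "default_grid",
    "grid_search_threshold",
]


class Dimension(enum.Enum):
    SEMANTIC = "semantic"
    PHONOLOGICAL = "phonological"


# Human tag -> binary label, per dimension; tags not listed are excluded.
_SEMANTIC_LABELS = {ErrorTag.S: True, ErrorTag.M: True, ErrorTag.F: False, ErrorTag.U: False}
_PHONOLOGICAL_LABELS = {ErrorTag.F: True, ErrorTag.M: True, ErrorTag.N: True,
                        ErrorTag.S: False, ErrorTag.U: False, ErrorTag.NU: False}


class ScoredTrial(NamedTuple):
    """A trial's human tag together with its raw similarity scores.

    ``semantic_score`` is ``None`` for nonword responses (out of
    vocabulary); ``phonological_score`` is always defined.
    """

    trial_id: str
    human_tag: ErrorTag
    semantic_score: Optional[float]
    phonological_score: float


@dataclass(frozen=True)
class BinaryStandard:
    """Ground-truth labels and scores on one dimension."""

    dimension: Dimension
    entries: tuple[tuple[str, float, bool], ...]  # (trial id, score, label)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=bool)


def binarize_standard(scored: Sequence[ScoredTrial], dimension: Dimension) -> BinaryStandard:
    """Collapse human tags into the binary standard for one dimension.

    Raises :class:`MalformedTrialError` on a tag outside the human coding
    vocabulary (the hierarchy codes are machine-only and never legitimate
    here).
    """
    label_map = _SEMANTIC_LABELS if dimension is Dimension.SEMANTIC else _PHONOLOGICAL_LABELS
    entries = []
    for st in scored:
        if not isinstance(st.human_tag, ErrorTag) or st.human_tag in (
                ErrorTag.HYPERNYM, ErrorTag.HYPONYM):
            raise MalformedTrialError(
                f"trial {st.trial_id}: tag {st.human_tag!r} is not a human code")
        label = label_map.get(st.human_tag)
        if label is None:
            continue  # R, NR, and (semantic dimension) N/NU carry no label
        score = st.semantic_score if dimension is Dimension.SEMANTIC else st.phonological_score
        if score is None:
            continue  # unscoreable on this dimension (OOV response)
        entries.append((st.trial_id, float(score), label))
    return BinaryStandard(dimension=dimension, entries=tuple(entries))


def default_grid(step: float = 0.001) -> np.ndarray:
    """Candidate thresholds 0, step, 2*step, ..., 1 (1001 points at the
    default step)."""
    n = round(1.0 / step)
    return np.linspace(0.0, 1.0, n + 1)


@dataclass(frozen=True)
class GridSearchResult:
    best_threshold: float
    best_accuracy: float
    accuracy_curve: tuple[tuple[float, float], ...]  # (threshold, accuracy)


def grid_search_threshold(standard: BinaryStandard,
                          grid: Optional[Sequence[float]] = None) -> GridSearchResult:
    """Exhaustive search for the cutoff maximizing agreement with the
    standard; the smallest of equally accurate thresholds wins.

    Raises ``ValueError`` on an empty standard.
    """
    if len(standard) == 0:
        raise ValueError(f"empty {standard.dimension.value} standard: nothing to train on")
    grid_arr = default_grid() if grid is None else np.asarray(grid, dtype=float)
    scores = standard.scores
    labels = standard.labels
    # predictions[i, j]: score j related at threshold i (inclusive rule)
    predictions = scores[None, :] >= grid_arr[:, None]
    accuracies = (predictions == labels[None, :]).mean(axis=1)
    best_i = int(np.argmax(accuracies))  # argmax returns the first (smallest) maximizer
    return GridSearchResult(
        best_threshold=float(grid_arr[best_i]),
        best_accuracy=float(accuracies[best_i]),
        accuracy_curve=tuple(zip(grid_arr.tolist(), accuracies.tolist())),
    )
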