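"""Cross-validation harness and tag-agreement accuracy.

Three partitioning schemes mirror the three generalization questions:

* TENFOLD — random folds of near-equal size (sizes differ by at most one):
  generalization to unseen trials from the same source;
* SUBJECT_LOO — one fold per participant, all of that participant's trials
  held out together: generalization to new speakers;
* ITEM_LOO — one fold per target word: generalization to new items.

In each iteration the held-in trials train the semantic and phonological
thresholds and the held-out trials are coded with them; accuracy is the
agreement between assigned and human tags. A cross-dataset mode applies
thresholds trained on folds of one dataset to the whole of another.

Human coders use only the seven standard codes, so by default the machine
hierarchy tags (HYPERNYM/HYPONYM) are mapped to S when computing agreement;
a strict mode leaves them unmapped.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .datasets_io import TrialRecord
from .lexical_knowledge import LexicalKB
from .semantics import EmbeddingLexicon
from .tagger import ErrorTag, PrecodedTrial, Thresholds, finalize_trial, precode_trial
from .training import Dimension, ScoredTrial, binarize_standard, grid_search_threshold

__all__ = [
    "CVReport",
    "DEFAULT_HIERARCHY_MAPPING",
    "FoldPlan",
    "FoldResult",
    "Scheme",
    "make_folds",
    "run_cross_dataset",
    "run_cv",
    "tag_accuracy",
]

DEFAULT_SEED = 20260217

DEFAULT_HIERARCHY_MAPPING: Mapping[ErrorTag, ErrorTag] = {
    ErrorTag.HYPERNYM: ErrorTag.S,
    ErrorTag.HYPONYM: ErrorTag.S,
}


class Scheme(enum.Enum):
    TENFOLD = "tenfold"
    SUBJECT_LOO = "subject"
    ITEM_LOO = "item"


@dataclass(frozen=True)
class FoldPlan:
    """A disjoint, covering partition of trial indices."""

    scheme: Scheme
    folds: tuple[tuple[int, ...], ...]
    seed: Optional[int] = None

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_folds(trials: Sequence[TrialRecord], scheme: Scheme,
               seed: Optional[int] = None) -> FoldPlan:
    """Partition trials according to the scheme.

    TENFOLD shuffles by ``seed`` only and yields exactly 10 folds whose
    sizes differ by at most one (raises ``ValueError`` below 10 trials).
    SUBJECT_LOO / ITEM_LOO yield one fold per distinct subject id / target
    word, grouping all of that unit's trials; fold order follows sorted
    unit labels and needs no seed.
    """
    n = len(trials)
    if n == 0:
        raise ValueError("cannot partition an empty trial list")
    if scheme is Scheme.TENFOLD:
        if n < 10:
            raise ValueError(f"tenfold partitioning needs at least 10 trials, got {n}")
        if seed is None:
            seed = DEFAULT_SEED
        kf = KFold(n_splits=10, shuffle=True, random_state=seed)
        folds = tuple(tuple(int(i) for i in test_idx)
                      for _, test_idx in kf.split(np.arange(n)))
        return FoldPlan(scheme=scheme, folds=folds, seed=seed)

    key = (lambda t: t.subject_id) if scheme is Scheme.SUBJECT_LOO else (lambda t: t.target)
    groups: dict[str, list[int]] = {}
    for i, t in enumerate(trials):
        groups.setdefault(key(t), []).append(i)
    if any(not g for g in (key(t) for t in trials)):
        raise ValueError(f"{scheme.value} partitioning requires a non-empty grouping id per trial")
    folds = tuple(tuple(groups[g]) for g in sorted(groups))
    return FoldPlan(scheme=scheme, folds=folds, seed=None)


def tag_accuracy(predicted: Sequence[ErrorTag], human: Sequence[ErrorTag],
                 mapping: Optional[Mapping[ErrorTag, ErrorTag]] = None) -> float:
    """Fraction of aligned positions where the (mapped) predicted tag
    equals the human tag. Raises ``ValueError`` on length mismatch."""
    if len(predicted) != len(human):
        raise ValueError(f"length mismatch: {len(predicted)} predicted vs {len(human)} human")
    if not predicted:
        raise ValueError("cannot compute accuracy of an empty tag list")
    if mapping is None:
        mapping = DEFAULT_HIERARCHY_MAPPING
    hits = sum(mapping.get(p, p) is h for p, h in zip(predicted, human))
    return hits / len(predicted)


@dataclass(frozen=True)
class FoldResult:
    fold: int
    n_train: int
    n_test: int
    thresholds: Thresholds
    train_accuracy: float
    test_accuracy: float


@dataclass
class CVReport:
    scheme: str
    seed: Optional[int]
    folds: list[FoldResult]
    summary: dict = field(init=False)

    def __post_init__(self):
        self.summary = self._summarize()

    def _summarize(self) -> dict:
        out = {}
        for which in ("train_accuracy", "test_accuracy"):
            vals = np.array([getattr(f, which) for f in self.folds], dtype=float)
            out[which] = {
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        for which, attr in (("semantic_threshold", "s"), ("phonological_threshold", "p")):
            vals = np.array([getattr(f.thresholds, attr) for f in self.folds], dtype=float)
            out[which] = {"mean": float(vals.mean()), "min": float(vals.min()),
                          "max": float(vals.max())}
        return out

    def to_frame(self) -> pd.DataFrame:
        """One tidy row per fold, suitable for box plots."""
        return pd.DataFrame([
            {
                "scheme": self.scheme, "fold": f.fold,
                "n_train": f.n_train, "n_test": f.n_test,
                "semantic_threshold": f.thresholds.s,
                "phonological_threshold": f.thresholds.p,
                "train_accuracy": f.train_accuracy,
                "test_accuracy": f.test_accuracy,
            }
            for f in self.folds
        ])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "seed": self.seed,
            "folds": self.to_frame().drop(columns="scheme").to_dict(orient="records"),
            "summary": self.summary,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def _precode_all(trials, lex, kb, onomatopoeia, capitonym_target) -> list[PrecodedTrial]:
    return [precode_trial(t, lex, kb, onomatopoeia, capitonym_target=capitonym_target)
            for t in trials]


def _scorable(pre: PrecodedTrial) -> bool:
    t = pre.trial
    return (t.human_tag is not None and not t.excluded and t.human_tag is not ErrorTag.NR)


def _scored_trial(pre: PrecodedTrial) -> Optional[ScoredTrial]:
    if pre.fixed_tag is not None or not _scorable(pre):
        return None
    sem = None if pre.semantic.is_nonword else float(pre.semantic.score)
    return ScoredTrial(pre.trial.trial_id, pre.trial.human_tag, sem,
                       float(pre.phonological.similarity))


def _train_thresholds(precoded: Iterable[PrecodedTrial], grid) -> Thresholds:
    scored = [s for s in (_scored_trial(p) for p in precoded) if s is not None]
    sem = grid_search_threshold(binarize_standard(scored, Dimension.SEMANTIC), grid)
    phon = grid_search_threshold(binarize_standard(scored, Dimension.PHONOLOGICAL), grid)
    return Thresholds(s=sem.best_threshold, p=phon.best_threshold)


def _agreement(precoded: Sequence[PrecodedTrial], thresholds: Thresholds, mapping) -> float:
    eligible = [p for p in precoded if _scorable(p)]
    predicted = [finalize_trial(p, thresholds).tag for p in eligible]
    human = [p.trial.human_tag for p in eligible]
    return tag_accuracy(predicted, human, mapping)


def run_cv(
    trials: Sequence[TrialRecord],
    plan: FoldPlan,
    *,
    lex: EmbeddingLexicon,
    kb: LexicalKB,
    onomatopoeia: Iterable[str],
    grid: Optional[Sequence[float]] = None,
    hierarchy_mapping: Optional[Mapping[ErrorTag, ErrorTag]] = None,
    capitonym_target: bool = False,
) -> CVReport:
    """Train thresholds on the held-in trials of each fold and code the
    held-out trials, reporting per-fold train/test agreement.

    Accuracy is computed over trials that carry a human tag and were not
    excluded before coding (non-responses are excluded first, as in
    training). A fold whose training partition yields an empty binary
    standard raises ``ValueError``.
    """
    precoded = _precode_all(trials, lex, kb, onomatopoeia, capitonym_target)
    results = []
    for k, fold in enumerate(plan.folds):
        held_out = set(fold)
        train = [p for i, p in enumerate(precoded) if i not in held_out]
        test = [precoded[i] for i in fold]
        thresholds = _train_thresholds(train, grid)
        results.append(FoldResult(
            fold=k, n_train=len(train), n_test=len(test), thresholds=thresholds,
            train_accuracy=_agreement(train, thresholds, hierarchy_mapping),
            test_accuracy=_agreement(test, thresholds, hierarchy_mapping),
        ))
    return CVReport(scheme=plan.scheme.value, seed=plan.seed, folds=results)


def run_cross_dataset(
    train_trials: Sequence[TrialRecord],
    test_trials: Sequence[TrialRecord],
    plan: FoldPlan,
    *,
    lex: EmbeddingLexicon,
    kb: LexicalKB,
    onomatopoeia: Iterable[str],
    grid: Optional[Sequence[float]] = None,
    hierarchy_mapping: Optional[Mapping[ErrorTag, ErrorTag]] = None,
    capitonym_target: bool = False,
) -> CVReport:
    """Cross-dataset generalization: thresholds trained on each held-in
    partition of the training dataset (per ``plan``, defined over
    ``train_trials``) are applied to the whole of ``test_trials``."""
    pre_train = _precode_all(train_trials, lex, kb, onomatopoeia, capitonym_target)
    pre_test = _precode_all(test_trials, lex, kb, onomatopoeia, capitonym_target)
    results = []
    for k, fold in enumerate(plan.folds):
        held_out = set(fold)
        train = [p for i, p in enumerate(pre_train) if i not in held_out]
        thresholds = _train_thresholds(train, grid)
        results.append(FoldResult(
            fold=k, n_train=len(train), n_test=len(pre_test), thresholds=thresholds,
            train_accuracy=_agreement(train, thresholds, hierarchy_mapping),
            test_accuracy=_agreement(pre_test, thresholds, hierarchy_mapping),
        ))
    return CVReport(scheme=f"cross:{plan.scheme.value}", seed=plan.seed, folds=results)
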