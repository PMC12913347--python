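"""Trial CSV input/output, lemmatization, and run configuration.

A trial table is a UTF-8 CSV with header columns ``subject_id, item_id,
target, response, target_ipa, response_ipa`` and optional ``human_tag`` and
``excluded``. Orthographic forms are lemmatized to lowercase at ingest (the
original response surface form is preserved for the capitonym path) and IPA
is Unicode-normalized to NFC, so every downstream module sees one
consistent representation.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .errors import ConfigurationError, MalformedTrialError

__all__ = [
    "RunConfig",
    "TrialRecord",
    "lemmatize",
    "load_thresholds",
    "read_trials",
    "save_thresholds",
    "write_coded_trials",
    "write_trials",
]

REQUIRED_COLUMNS = ("subject_id", "item_id", "target", "response", "target_ipa", "response_ipa")
OPTIONAL_COLUMNS = ("human_tag", "excluded")


@dataclass(frozen=True)
class TrialRecord:
    """One target–response pair.

    ``target`` and ``response`` are lemmatized lowercase forms;
    ``response_surface`` keeps the response as written (capitalization may
    carry meaning). ``human_tag`` is the manual code when present.
    ``excluded`` marks trials taken out before coding (visual errors,
    descriptions, no response).
    """

    subject_id: str
    item_id: str
    target: str
    response: str
    target_ipa: str
    response_ipa: str
    human_tag: Optional["ErrorTag"] = None  # noqa: F821 - imported lazily
    excluded: bool = False
    response_surface: str = ""
    row: Optional[int] = None

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}:{self.item_id}:{self.row if self.row is not None else ''}"


# -- lemmatization -----------------------------------------------------------

_IRREGULAR_PLURALS = {
    "children": "child", "feet": "foot", "geese": "goose", "men": "man",
    "mice": "mouse", "oxen": "ox", "people": "person", "teeth": "tooth",
    "women": "woman", "knives": "knife", "wives": "wife", "leaves": "leaf",
    "wolves": "wolf", "loaves": "loaf",
}

# Words a naive -s rule would truncate.
_PLURAL_EXCEPTIONS = {"bus", "gas", "lens", "species", "series", "glasses", "scissors"}


def lemmatize(word: str) -> str:
    """Lowercase a token and reduce regular English noun plurals to their
    base form (rule-based, with a small irregular table).

    >>> lemmatize("Cats")
    'cat'
    """
    w = word.strip().lower()
    if not w:
        return w
    if w in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[w]
    if w in _PLURAL_EXCEPTIONS:
        return w
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 3 and w.endswith(("ses", "xes", "zes", "ches", "shes")):
        return w[:-2]
    if len(w) > 2 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


# -- CSV I/O -----------------------------------------------------------------

def _parse_tag(value: str, row: int):
    from .tagger import ErrorTag  # local import to avoid a module cycle

    value = value.strip()
    if not value:
        return None
    try:
        return ErrorTag(value)
    except ValueError:
        raise MalformedTrialError(f"unknown tag {value!r}", row=row, column="human_tag") from None


def read_trials(
    path: str | Path,
    *,
    column_map: Optional[Mapping[str, str]] = None,
    lemmatize_inputs: bool = True,
) -> list[TrialRecord]:
    """Read a trial CSV into :class:`TrialRecord` objects.

    ``column_map`` maps file column names to the canonical names, so
    differently laid-out exports can be adapted without rewriting the file.
    Row numbers (1-based, header excluded) are retained for error messages.
    """
    with open(path, encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedTrialError(f"empty file: {path}") from None
        if column_map:
            header = [column_map.get(c, c) for c in header]
        seen: set[str] = set()
        for col in header:
            if col in seen:
                raise MalformedTrialError(f"duplicate header column {col!r}", column=col)
            seen.add(col)
        for col in REQUIRED_COLUMNS:
            if col not in seen:
                raise MalformedTrialError(f"missing required column {col!r}", column=col)
        idx = {c: i for i, c in enumerate(header)}

        records: list[TrialRecord] = []
        for rownum, fields in enumerate(reader, start=1):
            if not fields or all(not f.strip() for f in fields):
                continue
            if len(fields) < len(header):
                raise MalformedTrialError(
                    f"expected {len(header)} fields, got {len(fields)}", row=rownum)

            def get(col: str, default: str = "") -> str:
                i = idx.get(col)
                return fields[i] if i is not None else default

            excluded = get("excluded").strip().lower() in {"1", "true", "yes", "y"}
            surface = get("response").strip()
            target = get("target").strip()
            if lemmatize_inputs:
                target = lemmatize(target)
                response = lemmatize(surface)
            else:
                response = surface
            if not target and not excluded:
                raise MalformedTrialError("missing target", row=rownum, column="target")
            records.append(TrialRecord(
                subject_id=get("subject_id").strip(),
                item_id=get("item_id").strip(),
                target=target,
                response=response,
                target_ipa=unicodedata.normalize("NFC", get("target_ipa").strip()),
                response_ipa=unicodedata.normalize("NFC", get("response_ipa").strip()),
                human_tag=_parse_tag(get("human_tag"), rownum),
                excluded=excluded,
                response_surface=surface,
                row=rownum,
            ))
    return records


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write trials back to the canonical CSV layout, preserving order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
        for t in trials:
            writer.writerow([
                t.subject_id, t.item_id, t.target, t.response,
                unicodedata.normalize("NFC", t.target_ipa),
                unicodedata.normalize("NFC", t.response_ipa),
                t.human_tag.value if t.human_tag is not None else "",
                "1" if t.excluded else "",
            ])


def write_coded_trials(coded: Sequence["CodedTrial"], path: str | Path) -> None:  # noqa: F821
    """Write coded trials in the audit layout: scores to 4 decimal places,
    Y/N binary decisions, final tag, and the cascade rule that fired."""

    def fmt_score(x: Optional[float]) -> str:
        return "N/A" if x is None else f"{x:.4f}"

    def fmt_rel(x: Optional[bool]) -> str:
        return "" if x is None else ("Y" if x else "N")

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([
            "subject_id", "item_id", "target", "response",
            "semantic_score", "semantic_related",
            "phonological_score", "phonological_related",
            "tag", "rule_fired",
        ])
        for c in coded:
            sem_score = None
            if c.semantic is not None and not c.semantic.is_nonword:
                sem_score = c.semantic.score
            phon_score = c.phonological.similarity if c.phonological is not None else None
            writer.writerow([
                c.trial.subject_id, c.trial.item_id, c.trial.target, c.trial.response,
                fmt_score(sem_score), fmt_rel(c.sem_related),
                fmt_score(phon_score), fmt_rel(c.phon_related),
                c.tag.value, c.rule_fired,
            ])


# -- thresholds and configuration -------------------------------------------

def save_thresholds(thresholds: "Thresholds", path: str | Path, *,  # noqa: F821
                    grid_step: float = 0.001, dataset: str = "") -> None:
    payload = {"semantic": thresholds.s, "phonological": thresholds.p,
               "grid_step": grid_step, "dataset": dataset}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def load_thresholds(path: str | Path) -> "Thresholds":  # noqa: F821
    from .tagger import Thresholds

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return Thresholds(s=float(payload["semantic"]), p=float(payload["phonological"]))
    except KeyError as e:
        raise ConfigurationError(f"threshold file {path} missing key {e}") from None


@dataclass
class RunConfig:
    """Resource paths and switches for a coding / training / CV run."""

    embeddings: Optional[str] = None
    kb: Optional[str] = None
    onomatopoeia: Optional[str] = None
    thresholds: Optional[str] = None
    seed: int = 20260217
    grid_step: float = 0.001
    capitonym_target: bool = False
    hierarchy_mapping: str = "to_s"   # "to_s" | "strict"
    out: Optional[str] = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        payload = yaml.safe_load(text) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in payload.items() if k in known}
        extra = {k: v for k, v in payload.items() if k not in known}
        return cls(**kwargs, extra=extra)
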