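"""Interview data model, transcript I/O, and PHQ-8 score conversion rules.

The PHQ-8 instrument scores eight depression symptoms on a 0--3 scale; the
total (0--24) is conventionally dichotomised at 10 into non-depressed vs
depressed, or binned into five severity classes.  This module holds the
corpus containers (turns, interviews, symptom profiles), readers for the
DAIC-WOZ transcript dialect and a JSONL corpus format, and every score
conversion used downstream.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import json
import numbers
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed order of the eight PHQ-8 symptom keys used everywhere in the package.
SYMPTOM_KEYS: tuple[str, ...] = (
    "nointerest",
    "depressed",
    "sleep",
    "tired",
    "appetite",
    "failure",
    "concentrating",
    "moving",
)

#: Human-readable names, same order as :data:`SYMPTOM_KEYS`.
SYMPTOM_NAMES: tuple[str, ...] = (
    "No interest",
    "Depressed mood",
    "Insomnia or hypersomnia",
    "Feeling tired",
    "Eating too little or too much",
    "Feeling of being a failure",
    "Problems with concentrating",
    "Moving too slowly or too fast",
)

BINARY_CUTOFF = 10
SYMPTOM_PRESENT_CUTOFF = 1.5
SEVERITY_BIN_EDGES = (0, 5, 10, 15, 20)  # lower edges of the five classes


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class FormatError(ValidationError):
    """A transcript file does not parse under the requested dialect."""


class EmptyInterviewError(FormatError):
    """A transcript file parsed to zero turns."""


class Speaker(str, enum.Enum):
    INTERVIEWER = "interviewer"
    PARTICIPANT = "participant"


class BinaryDiagnosis(str, enum.Enum):
    NON_DEPRESSED = "non_depressed"
    DEPRESSED = "depressed"


class SeverityClass(str, enum.Enum):
    NO_SYMPTOMS = "no_symptoms"
    MILD = "mild"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately_severe"
    SEVERE = "severe"


#: Severity classes in increasing order; index matches the bin number.
SEVERITY_ORDER: tuple[SeverityClass, ...] = (
    SeverityClass.NO_SYMPTOMS,
    SeverityClass.MILD,
    SeverityClass.MODERATE,
    SeverityClass.MODERATELY_SEVERE,
    SeverityClass.SEVERE,
)


class SymptomPresence(str, enum.Enum):
    ABSENT = "absent"
    PRESENT = "present"


@dataclasses.dataclass
class Turn:
    """One uninterrupted utterance by one speaker."""

    speaker: Speaker
    text: str
    index: int
    start_time: float | None = None
    stop_time: float | None = None

    def __post_init__(self) -> None:
        self.speaker = Speaker(self.speaker)
        if not isinstance(self.text, str):
            raise ValidationError("turn text must be a string")
        if self.index < 0:
            raise ValidationError("turn index must be non-negative")
        if (
            self.start_time is not None
            and self.stop_time is not None
            and self.stop_time < self.start_time
        ):
            raise ValidationError(
                f"turn {self.index}: stop_time {self.stop_time} < start_time {self.start_time}"
            )


@dataclasses.dataclass
class Interview:
    """Ordered sequence of dialogue turns with a corpus split assignment."""

    id: str
    turns: list[Turn]
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.turns:
            raise EmptyInterviewError(f"interview {self.id!r} has no turns")
        indices = [t.index for t in self.turns]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValidationError(
                f"interview {self.id!r}: turn indices must be strictly increasing"
            )
        if self.split not in ("train", "dev", "test", "unassigned"):
            raise ValidationError(f"unknown split {self.split!r}")

    def __len__(self) -> int:
        return len(self.turns)

    def participant_turns(self) -> list[Turn]:
        return [t for t in self.turns if t.speaker is Speaker.PARTICIPANT]


@dataclasses.dataclass
class SymptomProfile:
    """Eight named PHQ-8 symptom scores, gold integers or predicted reals."""

    scores: dict[str, float]
    kind: str = "gold"

    def __post_init__(self) -> None:
        if self.kind not in ("gold", "predicted"):
            raise ValidationError(f"unknown profile kind {self.kind!r}")
        if set(self.scores) != set(SYMPTOM_KEYS):
            missing = set(SYMPTOM_KEYS) - set(self.scores)
            extra = set(self.scores) - set(SYMPTOM_KEYS)
            raise ValidationError(
                f"profile must have exactly the 8 symptom keys (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        # canonical fixed order
        self.scores = {k: self.scores[k] for k in SYMPTOM_KEYS}
        for key, value in self.scores.items():
            if self.kind == "gold":
                if not isinstance(value, numbers.Integral):
                    raise ValidationError(
                        f"gold score for {key!r} must be an integer, got {value!r}"
                    )
                if not 0 <= value <= 3:
                    raise ValidationError(f"gold score for {key!r} out of [0,3]: {value}")
                self.scores[key] = int(value)
            else:
                v = float(value)
                if not np.isfinite(v):
                    raise ValidationError(f"predicted score for {key!r} is not finite")
                if not 0.0 <= v <= 3.0:
                    raise ValidationError(
                        f"predicted score for {key!r} out of [0,3] after clamping: {v}"
                    )
                self.scores[key] = v

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[k] for k in SYMPTOM_KEYS], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], kind: str = "gold") -> "SymptomProfile":
        values = list(values)
        if len(values) != len(SYMPTOM_KEYS):
            raise ValidationError(f"expected 8 scores, got {len(values)}")
        if kind == "gold":
            # normalise numpy integer types; leave non-integral values for
            # the validator to reject
            values = [int(v) if float(v).is_integer() else v for v in values]
        return cls(dict(zip(SYMPTOM_KEYS, values)), kind=kind)


@dataclasses.dataclass
class DiagnosticLabels:
    """Derived labels: total score, binary diagnosis, and severity class."""

    total: int
    binary: BinaryDiagnosis
    severity: SeverityClass

    @classmethod
    def from_profile(cls, profile: SymptomProfile) -> "DiagnosticLabels":
        total = total_score(profile)
        return cls(total, binary_diagnosis(total), severity_class(total))


# ---------------------------------------------------------------------------
# Score conversion rules
# ---------------------------------------------------------------------------

def total_score(profile: SymptomProfile) -> int:
    """Sum of the eight gold symptom scores (0..24)."""
    if profile.kind != "gold":
        raise ValidationError("total_score requires a gold profile")
    return int(sum(profile.scores.values()))


def _check_total(total: float) -> None:
    if not np.isfinite(total) or not 0 <= total <= 24:
        raise ValidationError(f"total score out of [0,24]: {total}")


def binary_diagnosis(total: float) -> BinaryDiagnosis:
    """Dichotomise a PHQ-8 total at the standard cutoff of 10.

    Accepts real-valued totals (e.g. a sum of predicted symptom scores);
    the comparison is ``total >= 10`` with no rounding.
    """
    _check_total(total)
    return BinaryDiagnosis.DEPRESSED if total >= BINARY_CUTOFF else BinaryDiagnosis.NON_DEPRESSED


def severity_class(total: float) -> SeverityClass:
    """Five-class severity: [0,5) none, [5,10) mild, [10,15) moderate,
    [15,20) moderately severe, [20,24] severe."""
    _check_total(total)
    for i, edge in enumerate(SEVERITY_BIN_EDGES[1:]):
        if total < edge:
            return SEVERITY_ORDER[i]
    return SeverityClass.SEVERE


def binarize_symptom(score: float) -> SymptomPresence:
    """Symptom present iff its (possibly real-valued) score is >= 1.5."""
    return (
        SymptomPresence.PRESENT
        if score >= SYMPTOM_PRESENT_CUTOFF
        else SymptomPresence.ABSENT
    )


# ---------------------------------------------------------------------------
# Transcript file I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("start_time", "stop_time", "speaker", "value")


def read_transcript(path: str | Path, dialect: str = "daicwoz_tsv") -> Interview:
    """Read a single interview transcript.

    ``daicwoz_tsv``: tab-separated with header ``start_time, stop_time,
    speaker, value``; the speaker string ``Ellie`` maps to the interviewer
    role and everything else to the participant.  ``jsonl``: one interview
    object in the JSONL corpus format (first line of the file).
    """
    path = Path(path)
    if dialect == "daicwoz_tsv":
        return _read_daicwoz_tsv(path)
    if dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    return _interview_from_record(json.loads(line))
        raise EmptyInterviewError(f"{path}: no interview records")
    raise ValidationError(f"unknown transcript dialect {dialect!r}")


def _read_daicwoz_tsv(path: Path) -> Interview:
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _TSV_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        turns: list[Turn] = []
        for i, row in enumerate(reader):
            speaker = (
                Speaker.INTERVIEWER
                if (row["speaker"] or "").strip().lower() == "ellie"
                else Speaker.PARTICIPANT
            )
            turns.append(
                Turn(
                    speaker=speaker,
                    text=(row["value"] or "").strip(),
                    index=i,
                    start_time=_opt_float(row["start_time"]),
                    stop_time=_opt_float(row["stop_time"]),
                )
            )
    if not turns:
        raise EmptyInterviewError(f"{path}: transcript has no rows")
    return Interview(id=path.stem, turns=turns)


def _opt_float(value: str | None) -> float | None:
    if value is None or value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"bad time value {value!r}") from exc


# ---------------------------------------------------------------------------
# Corpus container and JSONL format
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Corpus:
    """A set of interviews with (optional) gold symptom profiles.

    JSONL serialisation: one object per interview with fields ``id``,
    ``split``, ``turns`` (list of ``{speaker, text}``) and ``labels``
    (the 8-key score mapping, or null for unlabeled interviews).
    """

    interviews: list[Interview]
    labels: dict[str, SymptomProfile] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [iv.id for iv in self.interviews]
        if len(set(ids)) != len(ids):
            raise ValidationError("interview ids must be unique within a corpus")
        for iid in self.labels:
            if iid not in set(ids):
                raise ValidationError(f"label for unknown interview id {iid!r}")

    def __len__(self) -> int:
        return len(self.interviews)

    def split(self, name: str) -> list[Interview]:
        return [iv for iv in self.interviews if iv.split == name]

    def subset(self, name: str) -> "Corpus":
        ivs = self.split(name)
        return Corpus(ivs, {iv.id: self.labels[iv.id] for iv in ivs if iv.id in self.labels})

    def score_table(self, split: str | None = None) -> pd.DataFrame:
        """Gold scores as a DataFrame (rows = interviews, columns = symptoms)."""
        ivs = self.interviews if split is None else self.split(split)
        rows = {iv.id: self.labels[iv.id].as_array() for iv in ivs if iv.id in self.labels}
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(SYMPTOM_KEYS))

    def write_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for iv in self.interviews:
                profile = self.labels.get(iv.id)
                record = {
                    "id": iv.id,
                    "split": iv.split,
                    "turns": [
                        {"speaker": t.speaker.value, "text": t.text} for t in iv.turns
                    ],
                    "labels": None if profile is None else profile.scores,
                }
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")

    @classmethod
    def read_jsonl(cls, path: str | Path) -> "Corpus":
        interviews: list[Interview] = []
        labels: dict[str, SymptomProfile] = {}
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                record = json.loads(line)
                interviews.append(_interview_from_record(record))
                if record.get("labels") is not None:
                    labels[record["id"]] = SymptomProfile(dict(record["labels"]), kind="gold")
        if not interviews:
            raise EmptyInterviewError(f"{path}: empty corpus file")
        return cls(interviews, labels)


def _interview_from_record(record: Mapping) -> Interview:
    for field in ("id", "turns"):
        if field not in record:
            raise FormatError(f"corpus record missing field {field!r}")
    turns = [
        Turn(speaker=Speaker(t["speaker"]), text=t["text"], index=i)
        for i, t in enumerate(record["turns"])
    ]
    if not turns:
        raise EmptyInterviewError(f"interview {record['id']!r} has no turns")
    return Interview(id=record["id"], turns=turns, split=record.get("split", "unassigned"))
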