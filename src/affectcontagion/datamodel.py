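"""Domain types and validation for three-dimensional affect rating data.

The data model mirrors a two-phase affect-induction experiment: each
participant watches one emotionally laden video, rates the affect it induced
on three monopolar 0-100 scales (negativity, positivity, arousal), and then
judges the affect of 20 unfamiliar faces (10 happy, 10 angry) on the same
three scales.  Positivity and negativity are stored as independent
dimensions -- they are never collapsed into a single bipolar valence axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

#: Within-subject face categories.
VALENCES = ("happy", "angry")

#: Canonical between-subject induction group labels.
GROUPS = ("negative_induction", "positive_induction")

#: Questionnaire instruments modelled as total scores only.
QUESTIONNAIRES = ("ECS", "IRI", "BES", "QPC")

#: Trials per face-valence category in a complete design.
TRIALS_PER_VALENCE = 10

RATING_MIN = 0.0
RATING_MAX = 100.0


class DataError(ValueError):
    """Base class for data-layer errors."""


class SchemaError(DataError):
    """A required column or field is missing or malformed."""


class RatingRangeError(DataError):
    """A rating is non-finite or outside the [0, 100] scale."""


class DuplicateParticipantError(DataError):
    """The same participant_id occurs more than once in a dataset."""


def _check_rating(value: float, name: str, context: str = "") -> float:
    value = float(value)
    if not math.isfinite(value) or not (RATING_MIN <= value <= RATING_MAX):
        where = f" ({context})" if context else ""
        raise RatingRangeError(
            f"rating '{name}'{where} must be a finite number in "
            f"[{RATING_MIN:g}, {RATING_MAX:g}], got {value!r}"
        )
    return value


@dataclass(frozen=True)
class AffectCoordinate:
    """One point in the three-dimensional affective space.

    Each dimension is a monopolar rating on a 0-100 scale.  The three
    dimensions are independent: a coordinate may be simultaneously high in
    negativity and positivity (co-activation), which a bipolar valence
    scale could not express.
    """

    negativity: float
    positivity: float
    arousal: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "negativity", _check_rating(self.negativity, "negativity"))
        object.__setattr__(self, "positivity", _check_rating(self.positivity, "positivity"))
        object.__setattr__(self, "arousal", _check_rating(self.arousal, "arousal"))

    def as_array(self) -> np.ndarray:
        """Return the coordinate as a float array ``[negativity, positivity, arousal]``."""
        return np.array([self.negativity, self.positivity, self.arousal], dtype=float)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.negativity, self.positivity, self.arousal)


@dataclass(frozen=True)
class FaceTrial:
    """One face judgment: which face, its category, and the judged coordinate."""

    face_id: str
    valence: str
    judgment: AffectCoordinate
    presentation_order: int | None = None

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise SchemaError(
                f"trial valence must be one of {VALENCES}, got {self.valence!r}"
            )
        if self.presentation_order is not None and int(self.presentation_order) < 1:
            raise SchemaError("presentation_order must be a positive integer")


@dataclass
class Participant:
    """One participant: induction group, baseline video rating, and face trials."""

    participant_id: str
    group: str
    video_rating: AffectCoordinate
    trials: list[FaceTrial] = field(default_factory=list)
    gender: str | None = None
    age: float | None = None
    questionnaires: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(
                f"group must be one of {GROUPS}, got {self.group!r} "
                f"(map arbitrary input labels before constructing Participant)"
            )

    def trials_by_valence(self, valence: str) -> list[FaceTrial]:
        if valence not in VALENCES:
            raise ValueError(f"unknown valence {valence!r}")
        return [t for t in self.trials if t.valence == valence]


@dataclass
class StudyDataset:
    """A collection of participants plus free-form provenance metadata."""

    participants: list[Participant] = field(default_factory=list)
    metadata: dict[str, object] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Participant]:
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)

    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def by_group(self) -> dict[str, list[Participant]]:
        out: dict[str, list[Participant]] = {g: [] for g in GROUPS}
        for p in self.participants:
            out.setdefault(p.group, []).append(p)
        return out

    def group_sizes(self) -> dict[str, int]:
        return {g: len(ps) for g, ps in self.by_group().items()}


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is ``"hard"`` or ``"warning"``."""

    severity: str
    participant_id: str | None
    message: str

    def is_hard(self) -> bool:
        return self.severity == "hard"


def validate_dataset(dataset: StudyDataset) -> list[Violation]:
    """Check dataset invariants and return violations (empty list = clean).

    Hard violations (analysis operations refuse to run):
      * duplicate participant ids,
      * a participant without exactly 10 happy and 10 angry trials.

    Warnings (analysis proceeds):
      * missing questionnaire totals,
      * missing gender or age.

    Violations are data, not exceptions; callers decide how to react.
    """
    violations: list[Violation] = []

    seen: set[str] = set()
    for p in dataset:
        if p.participant_id in seen:
            violations.append(
                Violation("hard", p.participant_id, "duplicate participant_id")
            )
        seen.add(p.participant_id)

    for p in dataset:
        counts = {v: len(p.trials_by_valence(v)) for v in VALENCES}
        for valence, n in counts.items():
            if n != TRIALS_PER_VALENCE:
                violations.append(
                    Violation(
                        "hard",
                        p.participant_id,
                        f"trial count: expected {TRIALS_PER_VALENCE} {valence} "
                        f"trials, found {n}",
                    )
                )
        missing_q = [q for q in QUESTIONNAIRES if q not in p.questionnaires]
        if missing_q:
            violations.append(
                Violation(
                    "warning",
                    p.participant_id,
                    f"missing questionnaire totals: {', '.join(missing_q)}",
                )
            )
        if p.gender is None:
            violations.append(Violation("warning", p.participant_id, "missing gender"))

    return violations


def hard_violations(violations: Iterable[Violation]) -> list[Violation]:
    """Filter to hard violations only."""
    return [v for v in violations if v.is_hard()]
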