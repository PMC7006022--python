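"""The emotional-contagion statistic and its participant-level aggregation.

Emotional contagion between an induced affective state and a face judgment
is quantified as one minus the normalized Euclidean distance between the
two points in the three-dimensional affective space:

    ec = 1 - sqrt(((n_v - n_f)^2 + (p_v - p_f)^2 + (a_v - a_f)^2) / (100^2 * 3))

where ``(n_v, p_v, a_v)`` is the participant's self-reported state after
the induction video and ``(n_f, p_f, a_f)`` is the judged state of a face.
The divisor ``100^2 * 3`` is the squared maximal distance between two
points of the ``[0, 100]^3`` cube (the diagonal, ``100 * sqrt(3)``), so the
score lies in ``[0, 1]``: 1 when the two coordinates coincide (total
contagion), 0 at opposite corners of the affective space.

The score is symmetric in its two arguments, weighs the three dimensions
equally, and is invariant under any permutation of the dimensions.  Note
the boundary condition: two coordinates may be close for reasons unrelated
to contagion (e.g. both neutral), in which case a high score does not imply
affect was actually transferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    VALENCES,
    AffectCoordinate,
    Participant,
    StudyDataset,
)

#: Maximal Euclidean distance between two points of the rating cube.
MAX_DISTANCE = 100.0 * math.sqrt(3.0)

_SQ_MAX = 100.0 ** 2 * 3.0


class SummaryError(ValueError):
    """A participant lacks usable trials in some face category."""


class OutlierScreenError(ValueError):
    """Too few participants in a group for Tukey fences to be defined."""


def _as_point(value: AffectCoordinate | Sequence[float], name: str) -> np.ndarray:
    if isinstance(value, AffectCoordinate):
        return value.as_array()
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have exactly 3 dimensions, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 100.0:
        raise ValueError(f"{name} must lie in [0, 100]^3, got {arr.tolist()}")
    return arr


def contagion_score(
    video: AffectCoordinate | Sequence[float],
    face: AffectCoordinate | Sequence[float],
) -> float:
    """Emotional contagion between a video-induced state and a face judgment.

    Parameters
    ----------
    video, face
        Points in the three-dimensional affective space, either
        :class:`~affectcontagion.datamodel.AffectCoordinate` instances or
        length-3 sequences ``(negativity, positivity, arousal)`` with every
        entry in [0, 100].  Out-of-range input raises; it is never clamped.

    Returns
    -------
    float
        Score in ``[0, 1]``; 1 iff the coordinates are identical.
    """
    v = _as_point(video, "video")
    f = _as_point(face, "face")
    return 1.0 - math.sqrt(float(np.sum((v - f) ** 2)) / _SQ_MAX)


def score_matrix(video: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Vectorized scores of one video coordinate against ``(n, 3)`` face rows."""
    diff = np.asarray(faces, dtype=float) - np.asarray(video, dtype=float)
    return 1.0 - np.sqrt(np.sum(diff ** 2, axis=-1) / _SQ_MAX)


@dataclass(frozen=True)
class ContagionSummary:
    """Per-participant cell means of the contagion statistic.

    ``mean_happy`` / ``mean_angry`` are arithmetic means of the per-trial
    scores within each face-valence category; they are the dependent
    variable of the downstream 2 (induction group) x 2 (face valence)
    mixed analysis.
    """

    participant_id: str
    group: str
    mean_happy: float
    mean_angry: float
    n_happy: int
    n_angry: int

    def mean_for(self, valence: str) -> float:
        if valence == "happy":
            return self.mean_happy
        if valence == "angry":
            return self.mean_angry
        raise ValueError(f"unknown valence {valence!r}")


def summarize_participant(participant: Participant) -> ContagionSummary:
    """Mean contagion score per face-valence category for one participant.

    Raises :class:`SummaryError` if a category has no usable trials.
    """
    video = participant.video_rating.as_array()
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for valence in VALENCES:
        trials = participant.trials_by_valence(valence)
        if not trials:
            raise SummaryError(
                f"participant {participant.participant_id!r} has no usable "
                f"{valence} trials"
            )
        faces = np.array([t.judgment.as_array() for t in trials])
        scores = score_matrix(video, faces)
        means[valence] = float(scores.mean())
        counts[valence] = len(trials)
    return ContagionSummary(
        participant_id=participant.participant_id,
        group=participant.group,
        mean_happy=means["happy"],
        mean_angry=means["angry"],
        n_happy=counts["happy"],
        n_angry=counts["angry"],
    )


def summarize_dataset(dataset: StudyDataset) -> list[ContagionSummary]:
    """Summaries for every participant, in dataset order."""
    return [summarize_participant(p) for p in dataset]


def summaries_frame(summaries: Iterable[ContagionSummary]) -> pd.DataFrame:
    """Summaries as a tidy DataFrame (one row per participant)."""
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "mean_happy": s.mean_happy,
                "mean_angry": s.mean_angry,
                "n_happy": s.n_happy,
                "n_angry": s.n_angry,
            }
            for s in summaries
        ]
    )


def trial_score_table(dataset: StudyDataset) -> pd.DataFrame:
    """Per-trial contagion scores for the whole dataset.

    One row per face trial with columns ``participant_id, group, gender,
    valence, face_id, order, score``.  This is the trial-level export used
    by the mixed-effects (gender) analysis.
    """
    rows = []
    for p in dataset:
        video = p.video_rating.as_array()
        for t in p.trials:
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "group": p.group,
                    "gender": p.gender,
                    "valence": t.valence,
                    "face_id": t.face_id,
                    "order": t.presentation_order,
                    "score": float(score_matrix(video, t.judgment.as_array())),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OutlierFlag:
    """One boxplot-style outlier finding."""

    participant_id: str
    group: str
    cell: str  # "mean_happy" or "mean_angry"
    value: float
    lower_fence: float
    upper_fence: float

    @property
    def reason(self) -> str:
        return (
            f"{self.cell}={self.value:.3f} outside Tukey fences "
            f"[{self.lower_fence:.3f}, {self.upper_fence:.3f}] of group {self.group}"
        )


def detect_outliers(
    summaries: Iterable[ContagionSummary],
    fence_multiplier: float = 1.5,
) -> list[OutlierFlag]:
    """Boxplot (Tukey-fence) outlier screen on the contagion summaries.

    Within each induction group and each face-valence cell separately, a
    participant is flagged when its cell mean lies outside
    ``[Q1 - k*IQR, Q3 + k*IQR]`` with ``k = fence_multiplier`` (1.5 by
    default, the conventional boxplot whisker rule).  Requires at least 4
    summaries per group; fences on fewer points are not meaningful.
    """
    if fence_multiplier < 0:
        raise ValueError("fence_multiplier must be non-negative")
    summaries = list(summaries)
    by_group: dict[str, list[ContagionSummary]] = {}
    for s in summaries:
        by_group.setdefault(s.group, []).append(s)

    flags: list[OutlierFlag] = []
    for group, members in sorted(by_group.items()):
        if len(members) < 4:
            raise OutlierScreenError(
                f"group {group!r} has {len(members)} summaries; "
                f"need >= 4 for Tukey fences"
            )
        for cell in ("mean_happy", "mean_angry"):
            values = np.array([getattr(s, cell) for s in members])
            q1, q3 = np.percentile(values, [25.0, 75.0])
            iqr = q3 - q1
            low = q1 - fence_multiplier * iqr
            high = q3 + fence_multiplier * iqr
            for s, v in zip(members, values):
                if v < low or v > high:
                    flags.append(
                        OutlierFlag(
                            participant_id=s.participant_id,
                            group=group,
                            cell=cell,
                            value=float(v),
                            lower_fence=float(low),
                            upper_fence=float(high),
                        )
                    )
    return flags
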