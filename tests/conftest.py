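"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import dataclasses

import pytest

from affectcontagion import (
    AffectCoordinate,
    FaceTrial,
    Participant,
    StudyDataset,
    default_calibrated_config,
    generate_dataset,
)


def build_participant(
    pid: str = "p01",
    group: str = "negative_induction",
    video: tuple[float, float, float] = (50.0, 50.0, 50.0),
    happy: list[tuple[float, float, float]] | None = None,
    angry: list[tuple[float, float, float]] | None = None,
    **kwargs,
) -> Participant:
    """A complete participant: 10 happy + 10 angry trials unless overridden."""
    happy = [(20.0, 70.0, 40.0)] * 10 if happy is None else happy
    angry = [(70.0, 20.0, 60.0)] * 10 if angry is None else angry
    trials = []
    order = 1
    for valence, judgments in (("happy", happy), ("angry", angry)):
        for i, coords in enumerate(judgments, start=1):
            trials.append(
                FaceTrial(
                    face_id=f"{valence}{i:02d}",
                    valence=valence,
                    judgment=AffectCoordinate(*coords),
                    presentation_order=order,
                )
            )
            order += 1
    return Participant(
        participant_id=pid,
        group=group,
        video_rating=AffectCoordinate(*video),
        trials=trials,
        **kwargs,
    )


def build_dataset(participants: list[Participant]) -> StudyDataset:
    return StudyDataset(participants=participants, metadata={"provenance": "test"})


@pytest.fixture(scope="session")
def small_cohort() -> StudyDataset:
    """A small synthetic cohort (8 + 9 participants), generated once."""
    config = dataclasses.replace(
        default_calibrated_config(seed=11), n_negative=8, n_positive=9
    )
    dataset, _ = generate_dataset(config)
    return dataset


@pytest.fixture(scope="session")
def study_cohort() -> StudyDataset:
    """A study-sized synthetic cohort (32 + 35 participants)."""
    dataset, _ = generate_dataset(default_calibrated_config(seed=5))
    return dataset
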