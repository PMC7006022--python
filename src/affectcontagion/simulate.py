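"""Seeded synthetic cohorts with the design of the induction study.

The generator emulates a two-phase affect-induction experiment: two
between-subject induction conditions (negative / positive video), one
baseline video rating per participant, and 20 face judgments (10 happy, 10
angry faces, presented in randomized order) on three monopolar 0-100
scales.

Generative model (per participant j in group i, trial t on a face of
category k):

    b_j        ~ Normal(0, participant_sd^2 I_3)     participant-level shift
    video_j    ~ TruncNormal_[0,100](mu_i + b_j, rating_sd^2)     per dimension
    judgment_jt ~ TruncNormal_[0,100](A_k + delta * (video_j - A_k),
                                      rating_sd^2)                per dimension

``mu_i`` is the group's video anchor, ``A_k`` the face-category anchor and
``delta`` in [0, 1] the assimilation strength: the fraction of the
anchor-to-induced-state displacement that leaks into face judgments.  It
formalizes the affect-as-information heuristic (judging others' affect
partly from one's own state); ``delta = 0`` gives anchor-only judgments,
``delta = 1`` makes every judgment coincide (in expectation) with the
participant's own induced state.  The shift ``b_j`` models how differently
the same video moves different people; because a participant's single
video rating enters every one of their face judgments through ``delta``
and every contagion score through the distance, it induces the
participant-level dependence across trials that the split-plot error
structure assumes.

Truncation to [0, 100] is sampled exactly by inverse-CDF transform.  All
randomness flows from one integer seed through per-participant substreams
(`numpy.random.SeedSequence.spawn`), so identical configs give
byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.special import ndtr, ndtri

from .datamodel import (
    GROUPS,
    QUESTIONNAIRES,
    AffectCoordinate,
    FaceTrial,
    Participant,
    StudyDataset,
)
from .metric import score_matrix

Point = tuple[float, float, float]


class ConfigError(ValueError):
    """A generator configuration value is invalid."""


#: Plausible total-score scales for the questionnaire instruments
#: (minimum, maximum, population mean, population SD).
_INSTRUMENT_SCALES: dict[str, tuple[float, float, float, float]] = {
    "ECS": (15.0, 75.0, 45.0, 8.0),
    "IRI": (0.0, 112.0, 60.0, 12.0),
    "BES": (20.0, 100.0, 75.0, 10.0),
    "QPC": (16.0, 80.0, 55.0, 9.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Anchors are points of the ``[0, 100]^3`` affective space ordered
    ``(negativity, positivity, arousal)``.  ``rating_sd`` is the
    pre-truncation SD of the per-rating noise, ``participant_sd`` the SD of
    the per-participant response-style offset shared across a participant's
    ratings.  ``questionnaire_corr`` is the target correlation between each
    questionnaire total and the participant's mean contagion score
    (default 0: the questionnaires measure a trait largely unrelated to
    momentary contagion).
    """

    n_negative: int = 32
    n_positive: int = 35
    video_anchor_negative: Point = (75.0, 12.0, 68.0)
    video_anchor_positive: Point = (10.0, 78.0, 55.0)
    face_anchor_happy: Point = (12.0, 80.0, 35.0)
    face_anchor_angry: Point = (68.0, 15.0, 55.0)
    assimilation: float = 0.25
    rating_sd: float = 10.0
    participant_sd: float = 6.0
    questionnaire_corr: float = 0.0
    proportion_women: float = 0.507
    age_mean: float = 21.6
    age_sd: float = 3.7
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_negative", "n_positive"):
            n = getattr(self, name)
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {n!r}")
        for name in (
            "video_anchor_negative", "video_anchor_positive",
            "face_anchor_happy", "face_anchor_angry",
        ):
            anchor = np.asarray(getattr(self, name), dtype=float)
            if anchor.shape != (3,) or not np.all(np.isfinite(anchor)):
                raise ConfigError(f"{name} must be 3 finite numbers, got {anchor!r}")
            if anchor.min() < 0.0 or anchor.max() > 100.0:
                raise ConfigError(f"{name} must lie in [0, 100]^3, got {anchor!r}")
        for name in ("rating_sd", "participant_sd", "age_sd"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {value!r}")
        if not (0.0 <= self.assimilation <= 1.0) or not math.isfinite(self.assimilation):
            raise ConfigError(f"assimilation must lie in [0, 1], got {self.assimilation!r}")
        if not (-1.0 <= self.questionnaire_corr <= 1.0):
            raise ConfigError(
                f"questionnaire_corr must lie in [-1, 1], got {self.questionnaire_corr!r}"
            )
        if not (0.0 <= self.proportion_women <= 1.0):
            raise ConfigError(
                f"proportion_women must lie in [0, 1], got {self.proportion_women!r}"
            )
        if not math.isfinite(self.age_mean):
            raise ConfigError(f"age_mean must be finite, got {self.age_mean!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in (
            "video_anchor_negative", "video_anchor_positive",
            "face_anchor_happy", "face_anchor_angry",
        ):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = dict(data)
        for key in (
            "video_anchor_negative", "video_anchor_positive",
            "face_anchor_happy", "face_anchor_angry",
        ):
            if key in kwargs:
                kwargs[key] = tuple(float(x) for x in kwargs[key])
        for key in ("n_negative", "n_positive", "seed"):
            if key in kwargs:
                kwargs[key] = int(kwargs[key])
        config = cls(**kwargs)
        config.validate()
        return config


@dataclass(frozen=True)
class GenerationReport:
    """Echo of the configuration plus realized summary quantities."""

    config: GeneratorConfig
    seed: int
    group_sizes: dict[str, int]
    cell_means: dict[str, float]  # "<group>/<valence>" -> mean contagion

    def __post_init__(self) -> None:
        expected = {
            "negative_induction": self.config.n_negative,
            "positive_induction": self.config.n_positive,
        }
        if self.group_sizes != expected:
            raise ValueError(
                f"realized group sizes {self.group_sizes} != configured {expected}"
            )


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float,
    low: float = 0.0,
    high: float = 100.0,
) -> np.ndarray:
    """Exact truncated-normal draws via the inverse-CDF transform."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0.0:
        return np.clip(mean, low, high)
    a = ndtr((low - mean) / sd)
    b = ndtr((high - mean) / sd)
    u = rng.random(mean.shape)
    # Clip guards ndtr underflow for means far outside [low, high];
    # the final clip keeps such extreme draws inside the scale.
    p = np.clip(a + u * (b - a), 1e-12, 1.0 - 1e-12)
    return np.clip(mean + sd * ndtri(p), low, high)


def _default_calibrated_kwargs() -> dict:
    # Numbers produced by the calibration search in
    # affectcontagion.calibrate (see scripts/calibrate_defaults.py);
    # provenance: "calibrated", not measured values.
    return dict(
        n_negative=32,
        n_positive=35,
        video_anchor_negative=(75.1, 13.75, 76.16),
        video_anchor_positive=(14.62, 75.85, 43.0),
        face_anchor_happy=(2.0, 93.22, 28.16),
        face_anchor_angry=(70.14, 15.48, 69.82),
        assimilation=0.1,
        rating_sd=4.0,
        participant_sd=38.82,
        questionnaire_corr=0.0,
        proportion_women=0.507,
        seed=0,
    )


def default_calibrated_config(seed: int = 0) -> GeneratorConfig:
    """The default study-like configuration.

    Group sizes follow the emulated design (32 negative-induction, 35
    positive-induction participants).  Anchors and assimilation strength
    were fixed once by a calibration search (least-squares over
    ``assimilation``, the four anchors and the two noise scales, minimizing
    the squared deviation of large-n simulated contagion cell means and
    SDs from the study-like target pattern: means angry|negative=0.76,
    happy|negative=0.41, angry|positive=0.54, happy|positive=0.71); see
    ``scripts/calibrate_defaults.py`` for the procedure.  The numbers are
    calibrated quantities, not measurements.
    """
    return GeneratorConfig(**{**_default_calibrated_kwargs(), "seed": seed})


_FACE_IDS = [f"happy{i:02d}" for i in range(1, 11)] + [
    f"angry{i:02d}" for i in range(1, 11)
]


def generate_dataset(config: GeneratorConfig) -> tuple[StudyDataset, GenerationReport]:
    """Generate one synthetic cohort; deterministic in ``config`` (incl. seed)."""
    config.validate()
    delta = config.assimilation
    anchors = {
        "happy": np.asarray(config.face_anchor_happy, dtype=float),
        "angry": np.asarray(config.face_anchor_angry, dtype=float),
    }
    plan = [
        ("negative_induction", "neg", np.asarray(config.video_anchor_negative, float),
         config.n_negative),
        ("positive_induction", "pos", np.asarray(config.video_anchor_positive, float),
         config.n_positive),
    ]
    n_total = config.n_negative + config.n_positive
    streams = np.random.SeedSequence(config.seed).spawn(n_total)

    participants: list[Participant] = []
    mean_scores: list[float] = []  # per-participant mean over all 20 trials
    q_noise: list[np.ndarray] = []
    stream_iter = iter(streams)
    for group, prefix, mu, n in plan:
        for i in range(1, n + 1):
            rng = np.random.default_rng(next(stream_iter))
            b = rng.normal(0.0, config.participant_sd, size=3)
            video = _truncated_normal(rng, mu + b, config.rating_sd)
            order = rng.permutation(len(_FACE_IDS))
            trials: list[FaceTrial] = []
            judged = np.empty((len(_FACE_IDS), 3))
            for pos, idx in enumerate(order, start=1):
                face_id = _FACE_IDS[idx]
                valence = "happy" if face_id.startswith("happy") else "angry"
                anchor = anchors[valence]
                mean = anchor + delta * (video - anchor)
                judgment = _truncated_normal(rng, mean, config.rating_sd)
                judged[pos - 1] = judgment
                trials.append(
                    FaceTrial(
                        face_id=face_id,
                        valence=valence,
                        judgment=AffectCoordinate(*judgment),
                        presentation_order=pos,
                    )
                )
            gender = "woman" if rng.random() < config.proportion_women else "man"
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 60.0))
            q_noise.append(rng.standard_normal(len(QUESTIONNAIRES)))
            participants.append(
                Participant(
                    participant_id=f"{prefix}{i:03d}",
                    group=group,
                    video_rating=AffectCoordinate(*video),
                    trials=trials,
                    gender=gender,
                    age=round(age, 1),
                )
            )
            mean_scores.append(float(score_matrix(video, judged).mean()))

    _attach_questionnaires(
        participants, np.array(mean_scores), np.array(q_noise), config.questionnaire_corr
    )

    dataset = StudyDataset(
        participants=participants,
        metadata={
            "provenance": "synthetic",
            "generator_config": config.to_dict(),
            "seed": config.seed,
        },
    )
    report = GenerationReport(
        config=config,
        seed=config.seed,
        group_sizes=dataset.group_sizes(),
        cell_means=_cell_means(participants),
    )
    return dataset, report


def _attach_questionnaires(
    participants: list[Participant],
    mean_scores: np.ndarray,
    noise: np.ndarray,
    rho: float,
) -> None:
    """Gaussian-copula-style totals with target correlation to mean contagion."""
    if not participants:
        return
    sd = mean_scores.std()
    z_ec = (mean_scores - mean_scores.mean()) / sd if sd > 0 else np.zeros_like(mean_scores)
    for j, p in enumerate(participants):
        for q_idx, name in enumerate(QUESTIONNAIRES):
            lo, hi, mu_q, sd_q = _INSTRUMENT_SCALES[name]
            z = rho * z_ec[j] + math.sqrt(max(0.0, 1.0 - rho ** 2)) * noise[j, q_idx]
            total = float(np.clip(round(mu_q + sd_q * z), lo, hi))
            p.questionnaires[name] = total


def _cell_means(participants: Iterable[Participant]) -> dict[str, float]:
    sums: dict[str, list[float]] = {}
    for p in participants:
        video = p.video_rating.as_array()
        for valence in ("happy", "angry"):
            trials = p.trials_by_valence(valence)
            if not trials:
                continue
            faces = np.array([t.judgment.as_array() for t in trials])
            sums.setdefault(f"{p.group}/{valence}", []).append(
                float(score_matrix(video, faces).mean())
            )
    return {key: float(np.mean(vals)) for key, vals in sorted(sums.items())}


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """Config with all four design cells made distributionally identical.

    Both groups share the midpoint of the two video anchors and both face
    categories the midpoint of the two face anchors, so assimilation acts
    identically everywhere and no group, valence or interaction effect
    exists in expectation.
    """
    video_mid = tuple(
        (a + b) / 2.0
        for a, b in zip(config.video_anchor_negative, config.video_anchor_positive)
    )
    face_mid = tuple(
        (a + b) / 2.0
        for a, b in zip(config.face_anchor_happy, config.face_anchor_angry)
    )
    return replace(
        config,
        video_anchor_negative=video_mid,
        video_anchor_positive=video_mid,
        face_anchor_happy=face_mid,
        face_anchor_angry=face_mid,
    )


def generate_null_dataset(config: GeneratorConfig) -> StudyDataset:
    """Cohort with no true effects: all 2x2 cell means equal by construction."""
    dataset, _ = generate_dataset(null_config(config))
    dataset.metadata["null"] = True
    return dataset
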