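"""Tests for the synthetic cohort generator."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from affectcontagion import (
    ConfigError,
    GenerationReport,
    GeneratorConfig,
    default_calibrated_config,
    generate_dataset,
    generate_null_dataset,
    summarize_dataset,
    write_ratings_csv,
)

INTERIOR = dict(
    video_anchor_negative=(60.0, 30.0, 55.0),
    video_anchor_positive=(35.0, 65.0, 50.0),
    face_anchor_happy=(35.0, 65.0, 45.0),
    face_anchor_angry=(65.0, 35.0, 55.0),
)


class TestGenerateDataset:
    def test_study_sized_cohort_has_67_participants_with_20_trials(self):
        dataset, report = generate_dataset(default_calibrated_config(seed=3))
        assert len(dataset) == 67
        assert report.group_sizes == {
            "negative_induction": 32,
            "positive_induction": 35,
        }
        assert all(len(p.trials) == 20 for p in dataset)

    def test_all_ratings_bounded(self, study_cohort):
        for p in study_cohort:
            for value in p.video_rating.as_tuple():
                assert 0.0 <= value <= 100.0
            for t in p.trials:
                for value in t.judgment.as_tuple():
                    assert 0.0 <= value <= 100.0

    def test_same_seed_gives_byte_identical_csv(self, tmp_path):
        config = dataclasses.replace(
            default_calibrated_config(seed=9), n_negative=5, n_positive=5
        )
        d1, _ = generate_dataset(config)
        d2, _ = generate_dataset(config)
        p1 = write_ratings_csv(d1, tmp_path / "one.csv")
        p2 = write_ratings_csv(d2, tmp_path / "two.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        base = dataclasses.replace(default_calibrated_config(), n_negative=3, n_positive=3)
        d1, _ = generate_dataset(dataclasses.replace(base, seed=1))
        d2, _ = generate_dataset(dataclasses.replace(base, seed=2))
        assert d1.participants != d2.participants

    def test_noiseless_zero_assimilation_reproduces_anchors(self):
        config = GeneratorConfig(
            n_negative=2,
            n_positive=2,
            rating_sd=0.0,
            participant_sd=0.0,
            assimilation=0.0,
            seed=1,
        )
        dataset, _ = generate_dataset(config)
        for p in dataset:
            for t in p.trials_by_valence("happy"):
                assert t.judgment.as_tuple() == config.face_anchor_happy

    def test_noiseless_full_assimilation_gives_scores_of_one(self):
        config = GeneratorConfig(
            n_negative=2,
            n_positive=2,
            rating_sd=0.0,
            participant_sd=0.0,
            assimilation=1.0,
            seed=1,
        )
        dataset, _ = generate_dataset(config)
        for s in summarize_dataset(dataset):
            assert s.mean_happy == pytest.approx(1.0, abs=1e-12)
            assert s.mean_angry == pytest.approx(1.0, abs=1e-12)

    def test_congruent_contagion_nondecreasing_in_assimilation(self):
        means = []
        for delta in (0.1, 0.3, 0.5):
            config = GeneratorConfig(
                n_negative=200,
                n_positive=2,
                assimilation=delta,
                rating_sd=8.0,
                participant_sd=8.0,
                seed=21,
                **INTERIOR,
            )
            _, report = generate_dataset(config)
            means.append(report.cell_means["negative_induction/angry"])
        assert means[0] <= means[1] <= means[2]

    def test_assimilation_recovery_from_mean_displacement(self):
        # E[judgment - anchor] = delta * E[video - anchor]; estimate delta by
        # projecting the mean face displacement onto the mean video displacement.
        delta = 0.3
        config = GeneratorConfig(
            n_negative=400,
            n_positive=400,
            assimilation=delta,
            rating_sd=8.0,
            participant_sd=8.0,
            seed=17,
            **INTERIOR,
        )
        dataset, _ = generate_dataset(config)
        anchors = {
            "happy": np.array(config.face_anchor_happy),
            "angry": np.array(config.face_anchor_angry),
        }
        estimates = []
        for group in ("negative_induction", "positive_induction"):
            members = [p for p in dataset if p.group == group]
            videos = np.array([p.video_rating.as_array() for p in members])
            for valence, anchor in anchors.items():
                faces = np.array(
                    [
                        np.mean([t.judgment.as_array() for t in p.trials_by_valence(valence)], axis=0)
                        for p in members
                    ]
                )
                v_disp = videos.mean(axis=0) - anchor
                f_disp = faces.mean(axis=0) - anchor
                estimates.append(float(f_disp @ v_disp / (v_disp @ v_disp)))
        assert np.mean(estimates) == pytest.approx(delta, abs=0.05)

    def test_questionnaire_totals_track_target_correlation(self):
        config = GeneratorConfig(
            n_negative=500,
            n_positive=500,
            questionnaire_corr=0.5,
            rating_sd=8.0,
            participant_sd=10.0,
            seed=23,
            **INTERIOR,
        )
        dataset, _ = generate_dataset(config)
        summaries = summarize_dataset(dataset)
        mean_ec = np.array([(s.mean_happy + s.mean_angry) / 2.0 for s in summaries])
        ecs = np.array([p.questionnaires["ECS"] for p in dataset])
        r = np.corrcoef(mean_ec, ecs)[0, 1]
        assert r == pytest.approx(0.5, abs=0.1)


class TestNullGenerator:
    def test_same_seed_identical_output(self):
        config = dataclasses.replace(default_calibrated_config(seed=4), n_negative=4, n_positive=4)
        d1 = generate_null_dataset(config)
        d2 = generate_null_dataset(config)
        assert d1.participants == d2.participants

    def test_cell_means_approximately_equal_at_large_n(self):
        config = dataclasses.replace(
            default_calibrated_config(seed=31), n_negative=800, n_positive=800
        )
        dataset = generate_null_dataset(config)
        summaries = summarize_dataset(dataset)
        cells = []
        for group in ("negative_induction", "positive_induction"):
            for valence in ("happy", "angry"):
                cells.append(
                    np.mean([s.mean_for(valence) for s in summaries if s.group == group])
                )
        assert max(cells) - min(cells) < 0.02


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"assimilation": 1.5},
            {"assimilation": float("nan")},
            {"rating_sd": -1.0},
            {"questionnaire_corr": 2.0},
            {"video_anchor_negative": (120.0, 0.0, 0.0)},
            {"proportion_women": 1.5},
            {"n_negative": -1},
        ],
    )
    def test_invalid_values_raise_config_error(self, kwargs):
        with pytest.raises(ConfigError):
            GeneratorConfig(**kwargs).validate()

    def test_dict_round_trip(self):
        config = default_calibrated_config(seed=7)
        assert GeneratorConfig.from_dict(config.to_dict()) == config

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            GeneratorConfig.from_dict({"nu_negative": 3})

    def test_default_calibrated_config_is_constant_and_valid(self):
        c1, c2 = default_calibrated_config(), default_calibrated_config()
        assert c1 == c2
        c1.validate()

    def test_report_rejects_mismatched_sizes(self):
        config = GeneratorConfig(n_negative=2, n_positive=2)
        with pytest.raises(ValueError, match="group sizes"):
            GenerationReport(
                config=config,
                seed=0,
                group_sizes={"negative_induction": 1, "positive_induction": 2},
                cell_means={},
            )
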