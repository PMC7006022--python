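"""Tests for the split-plot ANOVA and the surrounding inference chain."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from affectcontagion import (
    ContagionSummary,
    StatsError,
    brown_forsythe,
    default_calibrated_config,
    gender_effect_lrt,
    generate_dataset,
    mixed_anova_2x2,
    paired_t_bonferroni,
    pearson_corr,
    shapiro_wilk,
    trial_score_table,
)


def _summary(pid, group, happy, angry):
    return ContagionSummary(pid, group, happy, angry, 10, 10)


def _random_summaries(rng, n_neg, n_pos):
    out = []
    for i in range(n_neg):
        out.append(_summary(f"n{i}", "negative_induction", rng.random(), rng.random()))
    for i in range(n_pos):
        out.append(_summary(f"p{i}", "positive_induction", rng.random(), rng.random()))
    return out


def anova_oracle(summaries):
    """Brute-force sums-of-squares oracle via OLS model comparisons.

    Each stratum's SS is a residual-sum-of-squares difference between
    nested dummy-coded least-squares fits -- an independent route to the
    same decomposition.
    """
    summaries = list(summaries)
    groups = sorted({s.group for s in summaries})
    n = len(summaries)
    subj_mean = np.array([(s.mean_happy + s.mean_angry) / 2.0 for s in summaries])
    g_dummy = np.array([1.0 if s.group == groups[1] else 0.0 for s in summaries])

    def rss(X, y):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    ones = np.ones((n, 1))
    ss_group = 2.0 * (rss(ones, subj_mean) - rss(np.column_stack([ones, g_dummy]), subj_mean))
    ss_subj = 2.0 * rss(np.column_stack([ones, g_dummy]), subj_mean)

    # observation-level model with subject dummies
    y = np.concatenate(
        [[s.mean_happy for s in summaries], [s.mean_angry for s in summaries]]
    )
    subj = np.tile(np.eye(n), (2, 1))
    val = np.concatenate([np.zeros(n), np.ones(n)])[:, None]
    inter = val.ravel() * np.concatenate([g_dummy, g_dummy])
    m_s = rss(subj, y)
    m_sv = rss(np.column_stack([subj, val]), y)
    m_svi = rss(np.column_stack([subj, val, inter]), y)
    return {
        "group": ss_group,
        "subjects_error": ss_subj,
        "valence": m_s - m_sv,
        "interaction": m_sv - m_svi,
        "within_error": m_svi,
    }


class TestMixedAnova:
    def test_toy_design_matches_bruteforce_oracle(self):
        summaries = [
            _summary("a", "negative_induction", 0.2, 0.4),
            _summary("b", "negative_induction", 0.3, 0.5),
            _summary("c", "positive_induction", 0.6, 0.4),
            _summary("d", "positive_induction", 0.7, 0.5),
        ]
        table = mixed_anova_2x2(summaries)
        oracle = anova_oracle(summaries)
        assert table.group.ss == pytest.approx(oracle["group"], abs=1e-10)
        assert table.valence.ss == pytest.approx(oracle["valence"], abs=1e-10)
        assert table.interaction.ss == pytest.approx(oracle["interaction"], abs=1e-10)
        assert table.subjects_error[0] == pytest.approx(oracle["subjects_error"], abs=1e-10)
        assert table.within_error[0] == pytest.approx(oracle["within_error"], abs=1e-10)

    @pytest.mark.parametrize("n_neg,n_pos,seed", [(2, 2, 0), (3, 2, 1), (4, 5, 2), (3, 6, 3)])
    def test_random_unbalanced_designs_match_oracle(self, n_neg, n_pos, seed):
        rng = np.random.default_rng(seed)
        summaries = _random_summaries(rng, n_neg, n_pos)
        table = mixed_anova_2x2(summaries)
        oracle = anova_oracle(summaries)
        df2_between = n_neg + n_pos - 2
        for effect, err_key in (
            (table.group, "subjects_error"),
            (table.valence, "within_error"),
            (table.interaction, "within_error"),
        ):
            f_oracle = (oracle[effect.effect if effect.effect != "group:valence" else "interaction"]
                        ) / (oracle[err_key] / df2_between)
            assert effect.f == pytest.approx(f_oracle, abs=1e-10)

    def test_partial_eta_squared_identity(self):
        rng = np.random.default_rng(42)
        table = mixed_anova_2x2(_random_summaries(rng, 6, 8))
        for effect in table.effects():
            identity = (
                effect.f * effect.df / (effect.f * effect.df + effect.error_df)
            )
            assert effect.partial_eta_sq == pytest.approx(identity, abs=1e-12)

    def test_agreement_with_pingouin_on_balanced_design(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        summaries = _random_summaries(rng, 8, 8)
        table = mixed_anova_2x2(summaries)
        long = pd.DataFrame(
            [
                {"pid": s.participant_id, "group": s.group, "valence": v,
                 "score": s.mean_for(v)}
                for s in summaries
                for v in ("happy", "angry")
            ]
        )
        aov = pingouin.mixed_anova(
            long, dv="score", within="valence", subject="pid", between="group"
        ).set_index("Source")
        assert table.group.f == pytest.approx(aov.loc["group", "F"], abs=1e-8)
        assert table.valence.f == pytest.approx(aov.loc["valence", "F"], abs=1e-8)
        assert table.interaction.f == pytest.approx(aov.loc["Interaction", "F"], abs=1e-8)
        assert table.interaction.partial_eta_sq == pytest.approx(
            aov.loc["Interaction", "np2"], abs=1e-8
        )

    def test_constant_data_gives_zero_f(self):
        summaries = [
            _summary(f"x{i}", g, 0.5, 0.5)
            for i in range(4)
            for g in ("negative_induction", "positive_induction")
        ]
        table = mixed_anova_2x2(summaries)
        for effect in table.effects():
            assert effect.f == 0.0
            assert effect.partial_eta_sq == 0.0
            assert effect.p == 1.0

    def test_single_participant_group_raises(self):
        summaries = [
            _summary("a", "negative_induction", 0.1, 0.2),
            _summary("b", "positive_induction", 0.3, 0.4),
            _summary("c", "positive_induction", 0.5, 0.6),
        ]
        with pytest.raises(StatsError, match="negative_induction"):
            mixed_anova_2x2(summaries)


class TestPairedT:
    def test_hand_computed_t(self):
        # differences {0.1, 0.2, 0.3}: t = 0.2 / (0.1 / sqrt(3))
        summaries = [
            _summary("a", "negative_induction", 0.4, 0.5),
            _summary("b", "negative_induction", 0.4, 0.6),
            _summary("c", "negative_induction", 0.4, 0.7),
        ]
        result = paired_t_bonferroni(summaries, m=2)["negative_induction"]
        assert result.statistic == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-10)
        assert result.df == 2
        assert result.p_adjusted == pytest.approx(min(1.0, 2 * result.p_raw), abs=1e-15)

    def test_identical_pairs_give_zero_t(self):
        summaries = [_summary(f"i{k}", "negative_induction", 0.5, 0.5) for k in range(4)]
        result = paired_t_bonferroni(summaries)["negative_induction"]
        assert result.statistic == 0.0
        assert result.p_raw == 1.0
        assert result.p_adjusted == 1.0
        assert result.note is not None

    def test_bonferroni_never_exceeds_one(self):
        rng = np.random.default_rng(3)
        summaries = _random_summaries(rng, 5, 5)
        for result in paired_t_bonferroni(summaries).values():
            assert result.p_adjusted == min(1.0, 2 * result.p_raw)
            assert result.p_adjusted <= 1.0


class TestBrownForsythe:
    def test_identical_groups_give_zero_f(self):
        result = brown_forsythe({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_location_shift_invariance(self):
        result = brown_forsythe({"a": [1.0, 2.0, 3.0], "b": [11.0, 12.0, 13.0]})
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        # |dev from median|: {0,0,4} and {1,1} -> one-way ANOVA F = 0.0375
        result = brown_forsythe({"g1": [0.0, 0.0, 4.0], "g2": [1.0, 3.0]})
        assert result.statistic == pytest.approx(0.0375, abs=1e-12)
        scipy_stat, scipy_p = sps.levene([0.0, 0.0, 4.0], [1.0, 3.0], center="median")
        assert result.statistic == pytest.approx(scipy_stat, abs=1e-12)
        assert result.p_raw == pytest.approx(scipy_p, abs=1e-12)

    def test_degenerate_groups_raise(self):
        with pytest.raises(StatsError):
            brown_forsythe({"a": [1.0], "b": [1.0, 2.0]})


class TestShapiroWilk:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(0)
        result = shapiro_wilk(rng.normal(size=200))
        assert result.p_raw > 0.05

    def test_bimodal_sample_strongly_rejected(self):
        values = [0.0] * 50 + [1.0] * 50
        assert shapiro_wilk(values).p_raw < 0.001

    def test_constant_sample_flagged_not_raised(self):
        result = shapiro_wilk([2.0] * 10)
        assert result.note is not None
        assert np.isnan(result.statistic)

    def test_out_of_range_n_raises(self):
        with pytest.raises(StatsError):
            shapiro_wilk([1.0, 2.0])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        result = pearson_corr(x, 2 * x + 1)
        assert result.statistic == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_four_points(self):
        result = pearson_corr([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 0.0, 1.0])
        assert result.statistic == pytest.approx(1.0 / np.sqrt(5.0), abs=1e-12)

    def test_constant_variable_raises_naming_it(self):
        with pytest.raises(StatsError, match="ecs"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], labels=("ecs", "y"))

    def test_pairwise_deletion_of_missing_values(self):
        x = [1.0, 2.0, 3.0, 4.0, np.nan]
        y = [1.1, 2.2, 2.9, np.nan, 5.0]
        result = pearson_corr(x, y)
        assert result.n == 3

    def test_optional_bonferroni(self):
        result = pearson_corr([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 0.0, 1.0], bonferroni_m=4)
        assert result.p_adjusted == min(1.0, 4 * result.p_raw)


class TestGenderLrt:
    def _trial_table(self, rng, n_per_group=20, gender_shift=0.0):
        rows = []
        pid = 0
        for group in ("negative_induction", "positive_induction"):
            for _ in range(n_per_group):
                pid += 1
                gender = "woman" if rng.random() < 0.5 else "man"
                intercept = 0.6 + 0.05 * rng.standard_normal()
                if gender == "woman":
                    intercept += gender_shift
                for valence in ("happy", "angry"):
                    for trial in range(10):
                        rows.append(
                            {
                                "participant_id": f"s{pid}",
                                "group": group,
                                "valence": valence,
                                "gender": gender,
                                "score": intercept
                                + (0.05 if valence == "angry" else 0.0)
                                + 0.03 * rng.standard_normal(),
                            }
                        )
        return pd.DataFrame(rows)

    def test_constant_gender_gives_zero_statistic(self):
        rng = np.random.default_rng(0)
        table = self._trial_table(rng)
        table["gender"] = "woman"
        result = gender_effect_lrt(table)
        assert result.statistic == 0.0
        assert result.p_raw == 1.0
        assert result.note is not None

    def test_large_injected_gender_shift_detected(self):
        rng = np.random.default_rng(1)
        result = gender_effect_lrt(self._trial_table(rng, gender_shift=0.2))
        assert result.p_raw < 0.001

    def test_null_rejection_rate_near_alpha(self):
        # gender independent of scores by construction in the generator
        base = dataclasses.replace(
            default_calibrated_config(), n_negative=15, n_positive=15
        )
        n_reps, rejections, lr_values = 100, 0, []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for child in np.random.SeedSequence(7).spawn(n_reps):
                config = dataclasses.replace(
                    base, seed=int(child.generate_state(1)[0] % (2 ** 31))
                )
                dataset, _ = generate_dataset(config)
                result = gender_effect_lrt(trial_score_table(dataset))
                lr_values.append(result.statistic)
                rejections += result.p_raw < 0.05
        rate = rejections / n_reps
        assert 0.0 <= rate <= 0.13  # 95% MC band around alpha, small-n ML slack
        assert 0.4 <= float(np.mean(lr_values)) <= 2.0  # chi2(1) has mean 1

    def test_missing_columns_raise(self):
        with pytest.raises(StatsError, match="gender"):
            gender_effect_lrt(pd.DataFrame({"participant_id": [], "score": []}))
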