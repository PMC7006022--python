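"""Inference chain for the 2 (induction group) x 2 (face valence) design.

The dependent variable is each participant's mean contagion score per face
category (:class:`~affectcontagion.metric.ContagionSummary`).  The design
is split-plot: induction group varies between subjects, face valence
within subjects, so the ANOVA uses two error strata (subjects within
groups for the between effect; the subject-by-valence residual for the
within and interaction effects).

Unbalanced groups are handled by computing the between-subjects sums of
squares on participant means weighted by group size, the classical
decomposition for a 2x2 one-between / one-within design in which every
subject contributes both within levels.  Writing ``d_j`` for a subject's
angry-minus-happy difference, the interaction F is algebraically the
squared pooled two-sample t comparing ``d`` between groups.

Effect sizes are partial eta squared, ``SS_effect / (SS_effect +
SS_error)`` with the error stratum matching the effect, which satisfies
``eta_p^2 = F df1 / (F df1 + df2)``.

Assumption checks and follow-ups mirror the conventional chain for this
design: Shapiro-Wilk normality per design cell, Brown-Forsythe
(median-centered Levene) homogeneity across groups, Bonferroni-corrected
paired t-tests within each group, Pearson correlations with questionnaire
totals, and a likelihood-ratio test for a gender effect based on nested
linear mixed models on the trial-level scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metric import ContagionSummary

_ZERO_SS_TOL = 1e-12


class StatsError(ValueError):
    """Precondition failure in a statistical operation."""


@dataclass(frozen=True)
class TestResult:
    """One test: statistic, degrees of freedom, p-values, sample size.

    ``p_adjusted`` is present only when a multiplicity correction applies;
    it is never smaller than ``p_raw``.  ``note`` flags degenerate or
    unreliable results (zero variance, non-convergence) instead of raising.
    """

    method: str
    statistic: float
    df: float | tuple[float, float]
    p_raw: float
    n: int
    p_adjusted: float | None = None
    estimate: float | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_raw": self.p_raw,
            "n": self.n,
        }
        if self.p_adjusted is not None:
            d["p_adjusted"] = self.p_adjusted
        if self.estimate is not None:
            d["estimate"] = self.estimate
        if self.note is not None:
            d["note"] = self.note
        return d


@dataclass(frozen=True)
class EffectRow:
    """One ANOVA effect with its error stratum."""

    effect: str
    ss: float
    df: int
    ms: float
    f: float
    p: float
    partial_eta_sq: float
    error_ss: float
    error_df: int


@dataclass(frozen=True)
class AnovaTable:
    """Split-plot ANOVA decomposition for the 2x2 design."""

    group: EffectRow
    valence: EffectRow
    interaction: EffectRow
    subjects_error: tuple[float, int]  # SS, df (between stratum)
    within_error: tuple[float, int]  # SS, df (within stratum)
    n_per_group: dict[str, int] = field(default_factory=dict)

    def effects(self) -> list[EffectRow]:
        return [self.group, self.valence, self.interaction]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": e.effect,
                "SS": e.ss,
                "df": e.df,
                "MS": e.ms,
                "F": e.f,
                "p": e.p,
                "partial_eta_sq": e.partial_eta_sq,
                "error_SS": e.error_ss,
                "error_df": e.error_df,
            }
            for e in self.effects()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "effects": self.as_frame().to_dict(orient="records"),
            "subjects_error": {"SS": self.subjects_error[0], "df": self.subjects_error[1]},
            "within_error": {"SS": self.within_error[0], "df": self.within_error[1]},
            "n_per_group": self.n_per_group,
        }


def _f_and_p(ss_effect: float, df1: int, ss_error: float, df2: int) -> tuple[float, float]:
    ms_effect = ss_effect / df1
    ms_error = ss_error / df2 if df2 > 0 else 0.0
    if ms_error <= _ZERO_SS_TOL:
        if ss_effect <= _ZERO_SS_TOL:
            return 0.0, 1.0
        return math.inf, 0.0
    f = ms_effect / ms_error
    return f, float(sps.f.sf(f, df1, df2))


def _partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    denom = ss_effect + ss_error
    return 0.0 if denom <= _ZERO_SS_TOL else ss_effect / denom


def mixed_anova_2x2(summaries: Iterable[ContagionSummary]) -> AnovaTable:
    """Split-plot ANOVA of contagion on group (between) and valence (within).

    Requires exactly two groups with at least two participants each.
    Sums of squares use group-size-weighted means (see module docstring);
    F ratios use the between-subjects error for the group effect and the
    within-subjects residual for the valence and interaction effects.
    """
    summaries = list(summaries)
    groups = sorted({s.group for s in summaries})
    if len(groups) != 2:
        raise StatsError(f"need exactly 2 groups, got {groups}")
    y = {}  # group -> (n_i, 2) array, columns (happy, angry)
    for g in groups:
        rows = [(s.mean_happy, s.mean_angry) for s in summaries if s.group == g]
        if len(rows) < 2:
            raise StatsError(f"group {g!r} has {len(rows)} participants; need >= 2")
        y[g] = np.array(rows)

    ns = {g: len(y[g]) for g in groups}
    n_total = sum(ns.values())
    all_obs = np.vstack([y[g] for g in groups])
    grand = all_obs.mean()

    # Between stratum: subject means.
    subj_means = {g: y[g].mean(axis=1) for g in groups}
    group_means = {g: subj_means[g].mean() for g in groups}
    ss_group = 2.0 * sum(ns[g] * (group_means[g] - grand) ** 2 for g in groups)
    ss_subj = 2.0 * sum(((subj_means[g] - group_means[g]) ** 2).sum() for g in groups)
    df_subj = n_total - 2

    # Within stratum: cell means (weighted by group size for the margins).
    cell_means = {g: y[g].mean(axis=0) for g in groups}  # (happy, angry)
    valence_means = sum(ns[g] * cell_means[g] for g in groups) / n_total
    ss_valence = n_total * float(((valence_means - grand) ** 2).sum())
    ss_inter = sum(
        ns[g]
        * float(
            ((cell_means[g] - group_means[g] - valence_means + grand) ** 2).sum()
        )
        for g in groups
    )
    ss_werr = sum(
        float(
            (
                (y[g] - subj_means[g][:, None] - cell_means[g][None, :] + group_means[g])
                ** 2
            ).sum()
        )
        for g in groups
    )
    df_werr = n_total - 2

    f_g, p_g = _f_and_p(ss_group, 1, ss_subj, df_subj)
    f_v, p_v = _f_and_p(ss_valence, 1, ss_werr, df_werr)
    f_i, p_i = _f_and_p(ss_inter, 1, ss_werr, df_werr)

    def row(name: str, ss: float, f: float, p: float, err_ss: float, err_df: int) -> EffectRow:
        return EffectRow(
            effect=name,
            ss=ss,
            df=1,
            ms=ss,
            f=f,
            p=p,
            partial_eta_sq=_partial_eta_sq(ss, err_ss),
            error_ss=err_ss,
            error_df=err_df,
        )

    return AnovaTable(
        group=row("group", ss_group, f_g, p_g, ss_subj, df_subj),
        valence=row("valence", ss_valence, f_v, p_v, ss_werr, df_werr),
        interaction=row("group:valence", ss_inter, f_i, p_i, ss_werr, df_werr),
        subjects_error=(ss_subj, df_subj),
        within_error=(ss_werr, df_werr),
        n_per_group=ns,
    )


def paired_t_bonferroni(
    summaries: Iterable[ContagionSummary],
    m: int | None = None,
) -> dict[str, TestResult]:
    """Paired t (angry minus happy) within each group, Bonferroni-corrected.

    ``m`` is the number of tests in the family (defaults to the number of
    groups); ``p_adjusted = min(1, m * p_raw)``.
    """
    summaries = list(summaries)
    by_group: dict[str, list[ContagionSummary]] = {}
    for s in summaries:
        by_group.setdefault(s.group, []).append(s)
    m = len(by_group) if m is None else m

    results: dict[str, TestResult] = {}
    for group, members in sorted(by_group.items()):
        if len(members) < 2:
            raise StatsError(f"group {group!r} needs >= 2 paired observations")
        diffs = np.array([s.mean_angry - s.mean_happy for s in members])
        n = len(diffs)
        sd = diffs.std(ddof=1)
        if sd == 0.0:
            mean = float(diffs.mean())
            if mean == 0.0:
                t, p, note = 0.0, 1.0, "zero-variance, zero-mean differences"
            else:
                t = math.copysign(math.inf, mean)
                p, note = 0.0, "zero-variance, non-zero differences"
        else:
            t, p = sps.ttest_rel(
                [s.mean_angry for s in members], [s.mean_happy for s in members]
            )
            t, p, note = float(t), float(p), None
        results[group] = TestResult(
            method="paired t (angry - happy), Bonferroni",
            statistic=t,
            df=float(n - 1),
            p_raw=p,
            p_adjusted=min(1.0, m * p),
            n=n,
            estimate=float(diffs.mean()),
            note=note,
        )
    return results


def brown_forsythe(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Brown-Forsythe homogeneity-of-variance test across groups.

    One-way ANOVA F on absolute deviations from each group's median
    (`scipy.stats.levene` with ``center="median"``).
    """
    labels = sorted(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise StatsError("Brown-Forsythe needs >= 2 groups with >= 2 values each")
    stat, p = sps.levene(*samples, center="median")
    n_total = sum(len(s) for s in samples)
    k = len(samples)
    return TestResult(
        method="Brown-Forsythe",
        statistic=float(stat),
        df=(float(k - 1), float(n_total - k)),
        p_raw=float(p),
        n=n_total,
    )


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    arr = np.asarray(values, dtype=float)
    if not (3 <= arr.size <= 5000):
        raise StatsError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0.0:
        return TestResult(
            method="Shapiro-Wilk",
            statistic=math.nan,
            df=float(arr.size),
            p_raw=math.nan,
            n=int(arr.size),
            note="constant sample; W undefined",
        )
    w, p = sps.shapiro(arr)
    return TestResult(
        method="Shapiro-Wilk",
        statistic=float(w),
        df=float(arr.size),
        p_raw=float(p),
        n=int(arr.size),
    )


def pearson_corr(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
    bonferroni_m: int | None = None,
) -> TestResult:
    """Pearson correlation with two-sided p via the t transform.

    Pairs with a missing value in either variable are dropped (pairwise
    deletion).  No multiplicity adjustment is applied unless
    ``bonferroni_m`` is given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise StatsError(f"Pearson correlation needs >= 3 complete pairs, got {n}")
    for values, label in ((x, labels[0]), (y, labels[1])):
        if np.ptp(values) == 0.0:
            raise StatsError(f"variable {label!r} is constant; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        method="Pearson r",
        statistic=float(r),
        df=float(n - 2),
        p_raw=float(p),
        p_adjusted=(
            min(1.0, bonferroni_m * float(p)) if bonferroni_m is not None else None
        ),
        n=int(n),
    )


def gender_effect_lrt(trials: pd.DataFrame) -> TestResult:
    """Likelihood-ratio test for a gender effect on trial-level contagion.

    Fits two nested linear mixed models by maximum likelihood on the
    per-trial scores (columns ``participant_id, group, valence, gender,
    score``): a reference model with fixed effects for induction group and
    face valence and a random intercept per participant, and an augmented
    model adding a fixed gender effect.  Returns the likelihood-ratio
    statistic on 1 df.  Non-convergence is flagged in ``note``, never
    raised.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    required = {"participant_id", "group", "valence", "gender", "score"}
    missing = required - set(trials.columns)
    if missing:
        raise StatsError(f"trial table missing column(s): {sorted(missing)}")
    data = trials.dropna(subset=["gender", "score"]).copy()
    n = len(data)
    if data["gender"].nunique() < 2:
        return TestResult(
            method="LRT gender (nested linear mixed models)",
            statistic=0.0,
            df=1.0,
            p_raw=1.0,
            n=n,
            note="gender constant; augmented model identical to reference",
        )

    note = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ref = smf.mixedlm(
            "score ~ C(group) + C(valence)", data, groups=data["participant_id"]
        ).fit(reml=False)
        aug = smf.mixedlm(
            "score ~ C(group) + C(valence) + C(gender)",
            data,
            groups=data["participant_id"],
        ).fit(reml=False)
        conv = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
    if not (ref.converged and aug.converged):
        note = "mixed-model fit did not converge; statistic unreliable"
    elif conv:
        note = f"convergence warnings during fit: {conv[0].message}"

    lr = max(0.0, 2.0 * (aug.llf - ref.llf))
    return TestResult(
        method="LRT gender (nested linear mixed models)",
        statistic=float(lr),
        df=1.0,
        p_raw=float(sps.chi2.sf(lr, 1)),
        n=n,
        note=note,
    )
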