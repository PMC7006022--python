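"""End-to-end analysis pipeline: load -> validate -> score -> screen -> infer.

One call (:func:`run_pipeline`) executes the whole chain in a fixed order
and returns a :class:`PipelineReport` whose every number is recomputable
from the archived configuration and input:

1. load the dataset (ratings CSV or the synthetic generator),
2. validate; hard violations abort,
3. per-participant contagion summaries,
4. Tukey-fence outlier screen on the summaries; flagged participants are
   excluded once, before all inference, and logged with reasons,
5. 2x2 cell means/SDs, split-plot ANOVA, Shapiro-Wilk per cell,
   Brown-Forsythe per valence, Bonferroni-corrected paired t per group,
6. Pearson correlations of each design cell with each questionnaire total
   (when totals are present),
7. gender likelihood-ratio test on trial-level scores (when gender is
   present).

The run is fully deterministic given (input, config, seed): repeating an
invocation yields byte-identical JSON reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datamodel import (
    QUESTIONNAIRES,
    VALENCES,
    StudyDataset,
    hard_violations,
    validate_dataset,
)
from .io import read_ratings_csv, write_ratings_csv
from .metric import (
    ContagionSummary,
    detect_outliers,
    summarize_dataset,
    trial_score_table,
)
from .simulate import GeneratorConfig, generate_dataset
from .stats import (
    AnovaTable,
    TestResult,
    brown_forsythe,
    gender_effect_lrt,
    mixed_anova_2x2,
    paired_t_bonferroni,
    pearson_corr,
    shapiro_wilk,
)


class PipelineError(RuntimeError):
    """Hard failure of a pipeline stage; carries machine-readable details."""

    def __init__(self, message: str, errors: list[str] | None = None) -> None:
        super().__init__(message)
        self.errors = errors or []


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source: ``input_csv`` (a ratings file in one of the
    documented dialects) or ``generator`` (a synthetic-cohort config).
    ``seed``, when given, overrides the generator's seed so one pipeline
    seed governs the whole run.
    """

    input_csv: str | Path | None = None
    dialect: str = "long"
    generator: GeneratorConfig | None = None
    fence_k: float = 1.5
    alpha: float = 0.05
    bonferroni_correlations: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise PipelineError(
                "exactly one input source required: input_csv or generator"
            )
        if not (0.0 < self.alpha < 1.0):
            raise PipelineError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.fence_k < 0:
            raise PipelineError(f"fence_k must be >= 0, got {self.fence_k!r}")


@dataclass
class PipelineReport:
    """Structured results of one pipeline run."""

    provenance: dict
    n_per_group_before: dict[str, int]
    exclusions: list[dict]
    n_per_group: dict[str, int]
    cell_stats: dict[str, dict[str, float]]  # "<group>/<valence>" -> mean/sd/n
    anova: AnovaTable
    paired_t: dict[str, TestResult]
    normality: dict[str, TestResult]
    homogeneity: dict[str, TestResult]
    correlations: dict[str, dict[str, TestResult]]  # cell -> instrument -> result
    gender_lrt: TestResult | None
    validation_warnings: list[str]
    config_echo: dict
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "n_per_group_before_screening": self.n_per_group_before,
            "exclusions": self.exclusions,
            "n_per_group_analyzed": self.n_per_group,
            "cell_stats": self.cell_stats,
            "anova": self.anova.to_dict(),
            "paired_t": {g: r.to_dict() for g, r in self.paired_t.items()},
            "normality": {c: r.to_dict() for c, r in self.normality.items()},
            "homogeneity": {c: r.to_dict() for c, r in self.homogeneity.items()},
            "correlations": {
                cell: {q: r.to_dict() for q, r in by_q.items()}
                for cell, by_q in self.correlations.items()
            },
            "gender_lrt": None if self.gender_lrt is None else self.gender_lrt.to_dict(),
            "validation_warnings": self.validation_warnings,
            "config": self.config_echo,
            "seed": self.seed,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Emotional contagion analysis report", ""]
        lines.append(
            f"Participants analyzed: "
            + ", ".join(f"{g}: {n}" for g, n in sorted(self.n_per_group.items()))
        )
        if self.exclusions:
            lines.append("")
            lines.append("Excluded as boxplot outliers:")
            for e in self.exclusions:
                lines.append(f"- {e['participant_id']}: {e['reason']}")
        lines += ["", "## Contagion cell means", ""]
        lines.append("| group | faces | mean | SD | n |")
        lines.append("|---|---|---|---|---|")
        for cell, st in sorted(self.cell_stats.items()):
            group, valence = cell.split("/")
            lines.append(
                f"| {group} | {valence} | {st['mean']:.2f} | {st['sd']:.2f} | {st['n']:d} |"
            )
        lines += ["", "## Split-plot ANOVA", ""]
        lines.append("| effect | F | df | p | partial eta^2 |")
        lines.append("|---|---|---|---|---|")
        for e in self.anova.effects():
            lines.append(
                f"| {e.effect} | {e.f:.3f} | ({e.df}, {e.error_df}) "
                f"| {e.p:.3g} | {e.partial_eta_sq:.3f} |"
            )
        lines += ["", "## Paired t-tests (angry - happy)", ""]
        lines.append("| group | t | df | p | p (Bonferroni) |")
        lines.append("|---|---|---|---|---|")
        for group, r in sorted(self.paired_t.items()):
            lines.append(
                f"| {group} | {r.statistic:.3f} | {r.df:.0f} "
                f"| {r.p_raw:.3g} | {r.p_adjusted:.3g} |"
            )
        lines += ["", "## Assumption checks", ""]
        for cell, r in sorted(self.normality.items()):
            lines.append(f"- Shapiro-Wilk {cell}: W = {r.statistic:.3f}, p = {r.p_raw:.3g}")
        for valence, r in sorted(self.homogeneity.items()):
            lines.append(
                f"- Brown-Forsythe ({valence} faces): F = {r.statistic:.3f}, "
                f"p = {r.p_raw:.3g}"
            )
        if self.correlations:
            lines += ["", "## Correlations with questionnaire totals", ""]
            cells = sorted(self.correlations)
            lines.append("| questionnaire | " + " | ".join(cells) + " |")
            lines.append("|---" * (len(cells) + 1) + "|")
            for q in QUESTIONNAIRES:
                row = [q]
                for cell in cells:
                    r = self.correlations[cell].get(q)
                    row.append("" if r is None else f"{r.statistic:.2f} ({r.p_raw:.3f})")
                lines.append("| " + " | ".join(row) + " |")
        if self.gender_lrt is not None:
            r = self.gender_lrt
            lines += [
                "",
                f"Gender LRT: chi2(1) = {r.statistic:.2f}, p = {r.p_raw:.3g}"
                + (f" ({r.note})" if r.note else ""),
            ]
        return "\n".join(lines) + "\n"


def _load(config: PipelineConfig) -> StudyDataset:
    if config.input_csv is not None:
        path = Path(config.input_csv)
        if not path.exists():
            raise PipelineError(f"input file not found: {path}", [str(path)])
        return read_ratings_csv(path, dialect=config.dialect)
    generator = config.generator
    assert generator is not None
    if config.seed is not None:
        generator = replace(generator, seed=config.seed)
    dataset, _ = generate_dataset(generator)
    return dataset


def _cell_values(
    summaries: list[ContagionSummary],
) -> dict[str, np.ndarray]:
    cells: dict[str, list[float]] = {}
    for s in summaries:
        for valence in VALENCES:
            cells.setdefault(f"{s.group}/{valence}", []).append(s.mean_for(valence))
    return {cell: np.array(vals) for cell, vals in sorted(cells.items())}


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis chain; see module docstring for stage order."""
    config.validate()
    dataset = _load(config)

    violations = validate_dataset(dataset)
    hard = hard_violations(violations)
    if hard:
        raise PipelineError(
            f"{len(hard)} hard validation violation(s); aborting",
            [f"{v.participant_id}: {v.message}" for v in hard],
        )
    warnings_list = sorted(
        f"{v.participant_id}: {v.message}" for v in violations if not v.is_hard()
    )

    summaries = summarize_dataset(dataset)
    n_before = {g: n for g, n in dataset.group_sizes().items() if n}

    flags = detect_outliers(summaries, fence_multiplier=config.fence_k)
    excluded_ids = sorted({f.participant_id for f in flags})
    exclusions = [
        {"participant_id": f.participant_id, "reason": f.reason} for f in flags
    ]
    kept = [s for s in summaries if s.participant_id not in excluded_ids]
    kept_dataset = StudyDataset(
        participants=[
            p for p in dataset if p.participant_id not in excluded_ids
        ],
        metadata=dict(dataset.metadata),
    )

    cell_values = _cell_values(kept)
    cell_stats = {
        cell: {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
        }
        for cell, vals in cell_values.items()
    }

    anova = mixed_anova_2x2(kept)
    paired = paired_t_bonferroni(kept)
    normality = {cell: shapiro_wilk(vals) for cell, vals in cell_values.items()}
    homogeneity = {}
    for valence in VALENCES:
        by_group = {
            cell.split("/")[0]: vals
            for cell, vals in cell_values.items()
            if cell.endswith("/" + valence)
        }
        homogeneity[valence] = brown_forsythe(by_group)

    correlations = _questionnaire_correlations(kept_dataset, kept, config)

    gender_lrt = None
    genders = {p.gender for p in kept_dataset if p.gender is not None}
    if len(genders) >= 2:
        gender_lrt = gender_effect_lrt(trial_score_table(kept_dataset))

    return PipelineReport(
        provenance={
            "source": dataset.metadata.get("source", "synthetic"),
            "metadata": _jsonable(dataset.metadata),
        },
        n_per_group_before=n_before,
        exclusions=exclusions,
        n_per_group={g: n for g, n in kept_dataset.group_sizes().items() if n},
        cell_stats=cell_stats,
        anova=anova,
        paired_t=paired,
        normality=normality,
        homogeneity=homogeneity,
        correlations=correlations,
        gender_lrt=gender_lrt,
        validation_warnings=warnings_list,
        config_echo={
            "input_csv": None if config.input_csv is None else str(config.input_csv),
            "dialect": config.dialect,
            "generator": None
            if config.generator is None
            else config.generator.to_dict(),
            "fence_k": config.fence_k,
            "alpha": config.alpha,
            "bonferroni_correlations": config.bonferroni_correlations,
            "seed": config.seed,
        },
        seed=config.seed,
    )


def _questionnaire_correlations(
    dataset: StudyDataset,
    summaries: list[ContagionSummary],
    config: PipelineConfig,
) -> dict[str, dict[str, TestResult]]:
    totals = {p.participant_id: p.questionnaires for p in dataset}
    if not any(totals.values()):
        return {}
    m = 2 * len(QUESTIONNAIRES) * 2 if config.bonferroni_correlations else None
    out: dict[str, dict[str, TestResult]] = {}
    for valence in VALENCES:
        groups = sorted({s.group for s in summaries})
        for group in groups:
            members = [s for s in summaries if s.group == group]
            cell = f"{group}/{valence}"
            scores = np.array([s.mean_for(valence) for s in members])
            for q in QUESTIONNAIRES:
                y = np.array(
                    [totals[s.participant_id].get(q, np.nan) for s in members]
                )
                if np.isfinite(y).sum() < 3:
                    continue
                try:
                    result = pearson_corr(
                        scores, y, labels=(cell, q), bonferroni_m=m
                    )
                except Exception as exc:  # zero variance etc. -> recorded, not fatal
                    result = TestResult(
                        method="Pearson r",
                        statistic=float("nan"),
                        df=float("nan"),
                        p_raw=float("nan"),
                        n=int(np.isfinite(y).sum()),
                        note=str(exc),
                    )
                out.setdefault(cell, {})[q] = result
    return out


def _jsonable(obj: object) -> object:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def archive_run(
    report: PipelineReport,
    outdir: str | Path,
    dataset: StudyDataset | None = None,
    formats: tuple[str, ...] = ("json", "md"),
) -> list[Path]:
    """Write report (and optionally the input data) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = outdir / "report.json"
        path.write_text(report.to_json(), encoding="utf-8")
        written.append(path)
    if "md" in formats:
        path = outdir / "report.md"
        path.write_text(report.to_markdown(), encoding="utf-8")
        written.append(path)
    if dataset is not None:
        path = outdir / "ratings.csv"
        write_ratings_csv(dataset, path, dialect="long")
        written.append(path)
    return written
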