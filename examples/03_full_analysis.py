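"""Run the full analysis pipeline on a synthetic cohort.

Generates a study-sized cohort, screens boxplot outliers, and runs the
2 (induction group) x 2 (face valence) split-plot ANOVA with its
assumption checks, the per-group paired t-tests, the questionnaire
correlations and the gender likelihood-ratio test.
"""

from affectcontagion import PipelineConfig, default_calibrated_config, run_pipeline

report = run_pipeline(PipelineConfig(generator=default_calibrated_config(), seed=42))

print("participants before screening:", report.n_per_group_before)
print("excluded as outliers:", [e["participant_id"] for e in report.exclusions])
print("\ncell means (SD):")
for cell, st in sorted(report.cell_stats.items()):
    print(f"  {cell:32s} {st['mean']:.2f} ({st['sd']:.2f})")

ia = report.anova.interaction
print(
    f"\ninteraction group x valence: F(1, {ia.error_df}) = {ia.f:.3f}, "
    f"p = {ia.p:.2e}, partial eta^2 = {ia.partial_eta_sq:.3f}"
)
for group, t in sorted(report.paired_t.items()):
    print(
        f"paired t ({group}, angry - happy): t({t.df:.0f}) = {t.statistic:.2f}, "
        f"p_adj = {t.p_adjusted:.2e}"
    )
if report.gender_lrt is not None:
    g = report.gender_lrt
    print(f"gender LRT: chi2(1) = {g.statistic:.2f}, p = {g.p_raw:.3f}")

print(
    "\nA significant interaction with opposite-signed paired t statistics"
    "\nis the double dissociation: induced affect selectively boosts"
    "\ncontagion to affectively congruent faces."
)
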