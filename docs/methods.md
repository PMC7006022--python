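# Methods

## The contagion statistic

Emotional contagion between a rater's induced affective state and their
judgment of a face is quantified in a three-dimensional affective space of
monopolar 0–100 ratings — negativity *n*, positivity *p*, arousal *a*.
Positivity and negativity are deliberately independent axes (an evaluative-
space view): a state can be high on both, which a single bipolar valence
scale cannot express.  Writing `(n_v, p_v, a_v)` for the video-induced
state and `(n_f, p_f, a_f)` for the judged face affect,

    ec = 1 − sqrt( ((n_v−n_f)² + (p_v−p_f)² + (a_v−a_f)²) / (100² · 3) )

The divisor is the squared maximal distance between two points of the
`[0,100]³` cube (its diagonal, `100·√3`), so `ec ∈ [0,1]`: 1 when the two
coordinates coincide, 0 at opposite corners.  The statistic is symmetric
in its arguments, weighs the three dimensions equally, and is invariant
under dimension permutations; each property is property-tested, and the
implementation is checked against a brute-force recomputation to 1e-12.

Boundary condition: two coordinates can be close for reasons unrelated to
affect transfer (e.g. both near-neutral), in which case a high score does
not demonstrate contagion.  The statistic is meaningful only where a
contagion process can reasonably be assumed.

## Aggregation and outlier screening

Per-trial scores are averaged within each face-valence category, giving
each participant one `mean_happy` and one `mean_angry`; these cell means
are the dependent variable of all participant-level inference.  The
trial-level score table is also exported, and feeds the mixed-effects
gender analysis.

Outlier screening operates on the cell means, within each induction group
and valence cell separately, using Tukey fences `[Q1 − k·IQR, Q3 + k·IQR]`
(quartiles by linear interpolation, `k = 1.5` by default and configurable,
at least 4 participants per group required).  The pipeline order is fixed
and logged: screen → exclude (once, with named reasons) → analyze.  Both
the screening variable and the fence multiplier are package choices; other
reasonable screens (e.g. on raw ratings) exist and can be emulated by
pre-filtering the CSV.

## Split-plot ANOVA

The design is 2 × 2 with induction group between subjects and face valence
within subjects.  Sums of squares use group-size-weighted means, the
classical decomposition for this design when every subject contributes
both within-subject levels (group sizes may differ; with one between
factor and one 2-level within factor the usual Type I/II/III distinctions
collapse).  With `S_ij` the subject means, `M_ik` the cell means,
`M_i` the group means and `G` the grand (observation-weighted) mean:

- between stratum: `SS_group = 2·Σ_i n_i (M_i − G)²`, error
  `SS_subj = 2·Σ_ij (S_ij − M_i)²` on `N − 2` df;
- within stratum: `SS_valence = N·Σ_k (M_·k − G)²` with `M_·k` the
  size-weighted valence margin, `SS_interaction = Σ_ik n_i (M_ik − M_i −
  M_·k + G)²`, error `SS_res = Σ_ijk (y_ijk − S_ij − M_ik + M_i)²` on
  `N − 2` df.

Equivalently, the interaction F is the squared pooled two-sample t
comparing the angry-minus-happy difference scores between groups.  Both
within-stratum effects are tested against the participant-level residual
(`N − 2` df); no observation-level error stratum is used.  Effect sizes
are partial eta squared, `SS_effect / (SS_effect + SS_error)`, which
satisfies the identity `ηp² = F·df1 / (F·df1 + df2)` (asserted in tests).
The implementation is verified to 1e-10 against an independent brute-force
oracle that obtains every SS as a residual-sum difference between nested
dummy-coded least-squares fits, and against `pingouin.mixed_anova` on
balanced designs.

Degenerate inputs: if an error stratum is exactly zero, F is reported as 0
with p = 1 when the effect SS is also zero, and as `inf` with p = 0
otherwise (tolerance 1e-12 on sums of squares).

## Assumption checks and follow-ups

- Shapiro–Wilk per design cell (constant cells are flagged, not raised).
- Brown–Forsythe across groups per valence cell: one-way ANOVA on
  absolute deviations from group medians (`scipy.stats.levene`,
  `center="median"`), verified against a hand-computed toy.
- Paired t (angry − happy) within each group; Bonferroni with m = number
  of groups (2), `p_adj = min(1, m·p_raw)`.
- Pearson correlations between each design cell's scores and each
  questionnaire total (ECS, IRI, BES, QPC), pairwise deletion of missing
  totals, two-sided p via the t transform.  No multiplicity adjustment by
  default, with an optional Bonferroni switch.
- Gender: likelihood-ratio test between nested linear mixed models fitted
  by maximum likelihood on trial-level scores (`statsmodels` MixedLM) —
  fixed effects group + valence with a random intercept per participant,
  versus the same plus a fixed gender effect; LR on 1 df.  A random
  intercept is the richest structure this outcome supports: the model's
  response *is* the contagion score, so "random slopes for contagion"
  would be circular, and per-participant valence slopes are weakly
  identified with 10 trials per cell.  Non-convergence and boundary
  estimates are flagged in the result, never raised.  Under the null the
  ML-based LRT is mildly anticonservative at small samples (empirically
  ≈0.06–0.07 at 15 participants/group); the test suite allows for this.

## The synthetic cohort generator

Per participant *j* in group *i*, trial *t* on a face of category *k*:

    b_j         ~ N(0, participant_sd² I₃)
    video_j     ~ TN_[0,100](μ_i + b_j, rating_sd²)        per dimension
    judgment_jt ~ TN_[0,100](A_k + δ·(video_j − A_k), rating_sd²)

with `μ_i` the group video anchor, `A_k` the face-category anchor and
`δ ∈ [0,1]` the assimilation strength — the fraction of the
anchor-to-induced-state displacement that leaks into face judgments,
formalizing the affect-as-information heuristic.  The participant shift
`b_j` models how differently the same clip moves different people; it
enters judgments only through the participant's video rating, which is
what induces the participant-level dependence across trials that the
split-plot error structure assumes.  Faces are presented in random order;
gender (default 50.7% women) and age (normal, mean 21.6, SD 3.7, clipped
to 18–60) are drawn independently of all effects.  Questionnaire totals
are built Gaussian-copula-style — `ρ` times the standardized mean
contagion plus `sqrt(1−ρ²)` independent noise, mapped to plausible
instrument scales and rounded to integers — with default `ρ = 0`.

Truncated normals are sampled exactly by the inverse-CDF transform
(`Φ⁻¹(Φ(a) + u·(Φ(b)−Φ(a)))`); the CDF values are clipped at 1e-12 to
guard underflow when a mean sits far outside the scale, and the draw is
finally clipped to [0,100].  All randomness descends from one integer seed
through `numpy.random.SeedSequence.spawn`, one substream per participant,
so identical configurations give byte-identical CSV output.

A null variant collapses both video anchors and both face anchors to their
midpoints, making the four design cells distributionally identical — no
group, valence or interaction effect exists by construction.  It is used
to verify that the interaction test holds its nominal level (measured
0.051 over 2000 replicates at 20 participants/group, α = 0.05).

### Parameters and defaults

| parameter | meaning | units | default |
|---|---|---|---|
| `n_negative`, `n_positive` | group sizes | participants | 32, 35 |
| `video_anchor_*` | mean induced state per group | rating (0–100)³ | calibrated |
| `face_anchor_*` | mean judgment per face category absent assimilation | rating (0–100)³ | calibrated |
| `assimilation` (δ) | pull of judgments toward the induced state | fraction | 0.10 (calibrated) |
| `rating_sd` | pre-truncation SD of each rating | rating points | 4.0 (calibrated) |
| `participant_sd` | SD of the participant-level shift | rating points | 38.82 (calibrated) |
| `questionnaire_corr` | target corr. of totals with mean contagion | r | 0 |
| `proportion_women` | gender mix | fraction | 0.507 |

### Calibration of the defaults

`default_calibrated_config()` returns numbers fixed once by a search
(`affectcontagion.calibrate`, rerunnable via
`scripts/calibrate_defaults.py`): `scipy.optimize.least_squares` over δ,
the four anchors and the two noise scales (15 parameters), minimizing
squared deviations of simulated cell means *and* cell SDs from the target
pattern — means 0.76 / 0.41 / 0.54 / 0.71 and SDs 0.08 / 0.18 / 0.15 /
0.13 for negative·angry / negative·happy / positive·angry /
positive·happy.  The objective simulates the exact generative model
(truncation included, 10 trials per cell) under common random numbers, so
it is smooth and fast; a weak regularizer keeps anchors near plausible
regions, since eight targets do not identify 15 parameters, and δ is
bounded below at 0.10 so the cohort genuinely exhibits assimilation rather
than reproducing the pattern through anchor geometry alone.  The check run
at 2000/group reproduces the four means within 0.002; the SD pattern is
matched in aggregate (realized 0.096–0.137) but its cell-to-cell contrast
is only partially attainable under this noise model.  All calibrated
numbers carry provenance "calibrated"; they are not measurements.

### What the generator does and does not emulate

It emulates the design (two induction groups, 10+10 face judgments on
bounded monopolar scales, randomized order), an assimilation effect,
participant heterogeneity, and questionnaire totals with a configurable
correlation to contagion.  It does not emulate pre-induction baselines
(none exist in the design), item-level questionnaire responses,
presentation-order or carryover effects, response-style artifacts (e.g.
end-of-scale heaping), dimension-specific assimilation, or missing data.
Passing tests therefore demonstrate internal consistency of the pipeline
under a plausible data-generating process — not validity on real cohorts.

## Problem sizes used by the test suite

Chosen to make the checks informative at interactive runtimes: 10⁴ random
coordinate pairs for the statistic's properties; toy designs of ≤6
participants for the ANOVA oracle; 2000 null replicates at 20/group for
the type-I calibration; 2000/group for cell-mean recovery (±0.02); 100
replicates at 15/group for the gender-LRT null; 400–500/group for
assimilation recovery and questionnaire-correlation checks.

## Known limitations

- The within-stratum effects are tested against the participant-level
  residual (`N − 2` df); analyses that use an observation-level error
  stratum for the valence main effect will report different df and F.
- The ANOVA's weighted decomposition is specific to the 2 × 2
  one-between/one-within design; it does not generalize to more levels.
- The Pearson correlations assume interval-scale questionnaire totals and
  are sensitive to range restriction after outlier exclusion.
- `ec` compresses near the top of the scale: cells with high contagion
  necessarily show smaller SDs, which limits how well an arbitrary
  mean/SD pattern can be reproduced by any generator in this family.
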