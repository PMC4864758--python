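# Methods

This note records the modelling choices behind `cuefusion`: the observer
model and its assumptions, the stimulus construction, the scoring and
inference conventions, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-engineer
from the code.

## Task and design

Observers judge whether two adjacent slanted elliptical discs share the same
slant.  The standard disc is slanted 45° from frontoparallel; the comparison
either matches it or differs by ±12.5°, signalled by texture only (T+, T−),
disparity only (D+, D−), both congruently (T+D+), or in conflict (T+D−:
+12.5° in texture, −12.5° in disparity).  Each condition has 30 trials, half
"same" and half "different" (180 trials per subject), delivered in 18 blocks
of 10 trials that mix a condition pair 5+5 (D+/D−, T+/T−, T+D+/T+D−) so that
no block predicts the direction of a slant difference.  The T− condition is
generated and scored — the block structure requires it — but flagged out of
analysis, because the texture cue degenerates toward vertical slants and
yields near-floor scores.

## Stimulus geometry

Coordinates are right-handed, origin at screen centre, x rightward, y upward,
z toward the viewer, all lengths in cm; the eyes sit at z = 175 (viewing
distance) and x = ±IOD/2 (IOD default 6.2 cm), the screen is z = 0, and the
disc pair spans 13° of visual angle.  Discs are ellipses 16 cm wide with a
per-trial length ratio drawn uniformly from [1, 1.5], centred at ±10 cm
depth, slanted about their horizontal axis.

*Texture* is a Voronoi tessellation around a 1 cm grid jittered uniformly by
±0.225 cm per axis, clipped to the disc; *dots* are a 1 cm grid jittered by
±1.5 cm laid out directly in the screen frame and clipped to the projected
disc outline, so their image density is uniform and carries no slant
information.  *Cue-conflict stimuli* are built by reprojection: the
cyclopean (mid-eye) image is rendered from the plane at the texture slant;
each image point is then assigned the depth of the plane at the disparity
slant along its cyclopean ray; both eyes' views are projected from those 3D
positions.  With equal slants this reduces exactly (to < 1e-9 cm) to direct
stereo projection of a single physical plane, the cyclopean image is
invariant to the disparity slant by construction, and triangulating the
two-eye geometry recovers the disparity slant to < 0.01°.

Decisions the source design left open, fixed here: the cyclopean eye defines
the reprojection reference; monocular (texture-only) conditions render the
left-eye image; dot jitter is applied in the screen frame; the disc outline
follows the texture-slant plane so the monocular image never leaks disparity
information; Voronoi cells are clipped with half-open inclusion at the
boundary and a boundary-split cell keeps its largest fragment; the
inter-disc gap is whatever centres two 16 cm discs inside the 13° span; the
standard disc sits left or right uniformly at random.

## Observer model

Each disc yields independent Gaussian slant estimates ŝ_T ~ N(s_T, σ_T²) and
ŝ_D ~ N(s_D, σ_D²).  A Gaussian coupling prior of width σ_c on the cue
discrepancy yields the closed-form MAP percept pair given in the README;
the closed form is verified in tests against a dense two-stage grid search
over the posterior rather than trusted from the derivation.  The single
fused readout (reliability-weighted average, w_T = σ_D²/(σ_T²+σ_D²)) is
what mandatory-fusion observers compare across discs; note that reading the
coupled percept pair out with reliability weights is invariant to σ_c, so
partial coupling expresses itself through the per-cue percepts, not through
the fused scalar.

Decision rule (a differencing rule with a fixed criterion, the standard
choice for roving same–different designs): respond "different" iff the
absolute between-disc difference of the percept exceeds c = 6.25° (half the
slant increment), shared across conditions within an observer.  Regimes:

- **mandatory_fusion** — couple the cues (σ_c = 0 by default) and compare
  the coupled percepts (max over the pair; identical to the fused scalar at
  σ_c = 0).
- **no_fusion** — never couple.  On combined-cue trials the default is
  trial-wise *cue switching*: attend one cue per trial with probability ½.
  An alternative rule, always using the more reliable cue, is available as
  `no_fusion_rule="best"`.  Switching is the default because best-cue
  reporting is statistically indistinguishable from integration under the
  dual-test logic: across subjects with heterogeneous reliabilities,
  max(d′_T, d′_D) − d′_T has strictly positive mean, so a best-cue cohort
  passes *both* congruent comparisons at high trial counts and would be
  classified as an integrator.  Cue switching is also the standard account
  of non-integrating children in this literature.
- **selective_fusion** — couple only when the within-disc discrepancy
  |ŝ_T − ŝ_D| stays below k·√(σ_T²+σ_D²) on both discs (k = 2 by default,
  i.e. a ~95% acceptance gate under congruent cues); on a detected conflict,
  monitor the cues separately and respond "different" iff either cue's
  between-disc difference exceeds the criterion.

A lapse parameter (probability of a uniformly random response, default 0,
capped at 0.1) is available because real adolescent data plainly contain
lapses; it is off in all shipped defaults.

Analytic hit/false-alarm rates are closed-form for single cues and all
σ_c = 0 regimes.  For selective fusion the gate is treated as deterministic
per trial type (conflict stimuli always gate out, congruent ones never do);
with the task's 25° conflict and the default gate this misstates the gate on
roughly 5% of trials and the resulting d′ by far less than the Monte-Carlo
resolution of any test that uses it.  Rates for partial coupling
(0 < σ_c < ∞) have no closed form here and raise `NotImplementedError`;
simulate instead.

## Scoring and inference

d′ = z(H) − z(FA) with "different" as the signal response — the plain
yes/no-style convention, not the differencing-model transform (the study
this models reports plain d′; an optional `correction="none"` flag exposes
raw rates).  Extreme proportions are handled by the log-linear correction
(add 0.5 to each count, 1 to each denominator) by default.  Note the
correction is not innocuous at n = 15: at rates near 0.87 it shifts d′ by
~0.2, so corrected and raw d′ agree within 0.05 only for rates in roughly
[0.4, 0.6].

Subjects at or below chance (d′ ≤ 0, boundary included) on any of T+, D−,
D+ are excluded before analysis; combined-cue performance never excludes.
Integration scores: congruent = d′(T+D+) − max(d′(T+), d′(D+)); incongruent
= d′(T+D−) − min(d′(T+), d′(D−)).  The four planned paired comparisons run
at α = 0.05 each; "integration" of a cue pairing requires *both* of its
comparisons significant and in the predicted direction, and the
(congruent, incongruent) outcome pair maps to mandatory (yes, yes),
selective (yes, no), none (no, no), or indeterminate (no, yes) — the last
labelled so because a conflict-only effect has no interpretation in the
framework.  Requiring both tests keeps the joint type-I rate at α² = 0.0025
under independence; with the two comparisons sharing the combined condition
the correlation (ρ = 0.5) in fact raises the joint directional rate to
≈ 0.0046, so the α² figure should be read as the independence bound, not a
guarantee for the correlated pair.  A constant nonzero difference vector in
a planned comparison (possible in tiny tables) is treated as directional
certainty (p = 0) rather than an abort.

Effect sizes follow the source conventions: Cohen's d = |t|/√n for paired
tests; pooled-variance Student t (df = n₁+n₂−2) for group comparisons from
summary statistics; partial η² = F·df₁/(F·df₁+df₂).  The 2×2 mixed ANOVA
(condition within, group between) is computed from the explicit
subject-level sum/difference decomposition — subject means carry the
between-subject effect, per-subject condition differences carry condition
and interaction, with the unweighted condition contrast under unequal group
sizes (the convention of standard factorial ANOVA software, cross-checked
against an independent OLS cell-means oracle and `pingouin.mixed_anova` in
the tests).

## Synthetic cohorts

`CohortSpec` defaults emulate the modelled study's shape: 16 subjects in a
selective-fusion group and 14 in a mandatory-fusion group, 30
trials/condition, criterion 6.25°, gate k = 2.  Per-subject σ_T and σ_D are
drawn independently from a lognormal with median 4° and geometric SD 1.3,
chosen so single-cue d′ lands near the observed 1.0–1.7 range under the
default criterion; no subject-level parameters were ever published, so these
are conventions, not estimates.  Every subject owns RNG streams keyed by
(seed, SHA-256 of the subject id), so enlarging a cohort never perturbs
existing subjects, and a (spec, seed) pair reproduces the trial table
bitwise.

What the generator deliberately does **not** emulate: lapses and attention
drift (available but off), learning or fatigue across blocks, criterion
drift or group differences in criterion, practice trials, stereo-screening
failures, and any correlation between σ_T and σ_D within subject.  Passing
recovery tests therefore show that the *analysis chain* is sound under the
stated observer model — not that real adolescents satisfy that model.

Regime recovery: cohorts of 16 subjects at 300 trials/condition are
classified as their generating regime in ≥ 90% of replicates (in practice
~100%); the infinite-trials limit (analytic d′) recovers all regimes
exactly.  At the study-faithful 30 trials/condition the battery is honestly
underpowered: the mandatory group classifies essentially always, but a
selective cohort reads as "no fusion" in roughly a third of replicates —
`cuefusion recover` quantifies exactly this design power.

## Problem sizes and numerics

Monte-Carlo checks use 1e5 trials for observer-level d′ (resolution ~0.01),
1e4 replicates for type-I calibration (±0.007 at 3σ), 200 replicate cohorts
for the recovery criterion, and 100-seed pooling for the dot-uniformity
χ² check.  Projection tolerances: 1e-9 cm for geometric identities, 1e-6 cm
for triangulated plane residuals.  The Voronoi ellipse outline is a 256-gon,
so tile areas sum to πab only to the chord deficit (~5e-4 relative).
Degenerate inputs fail loudly: zero-width discs, points at or behind an eye,
rays parallel to the disparity plane, odd trial counts, zero-variance test
inputs (except the all-equal case, which is a well-defined null result).

## Known limitations

- The decision model (differencing rule, fixed shared criterion) is an
  assumption; the source design cannot distinguish averaging from criterion
  shifts, and neither can ours from the outside.
- Partial coupling (finite nonzero σ_c) is simulable but has no analytic
  d′ path and no shipped calibration to data.
- The selective-fusion gate is stimulus-driven and binary; graded or
  probabilistic gating (e.g. model averaging) is not implemented.
- Group labels in shipped defaults are design mnemonics ("ASD"/"TD" regime
  assignments), not claims about individuals; the generator's population
  parameters are conventions chosen for plausibility, not fits.
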