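# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `ccdm`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Experimental design

Displays place one target and three distractors on 8 abstract locations
(indices 0–7; left hemifield 0–3, right 4–7; no screen geometry, since none
of the downstream statistics depends on it). The side-balance rule — two
items per hemifield, i.e. exactly one distractor on the target's side —
yields `2·s·(s−1)·C(s,2)` configurations for `s` positions per side, 144
for `s = 4`. Each session runs 32 blocks of 8 trials (4 old displays
repeated verbatim, 4 new displays regenerated per block at fixed target
positions); epochs collapse 4 consecutive blocks, giving an 8-point
learning axis. Old target positions (2 per hemifield) and new target
positions (the complementary 4) are disjoint, so cueing cannot reflect
target-position learning. The two sessions use disjoint old sets.

Block-level balance in the multisensory session is not fixed by the
session-level 128/128 trial-type split alone; we counterbalance within
block pairs (each old display and each new target position is visuotactile
exactly once per pair), so every old display accrues 16 trials per trial
type and trial type is never confounded with epoch. Target orientation is
balanced by construction within each display-by-trial-type stream (64 per
orientation per trial type in the multisensory session). An independent
validator recounts all of these invariants on every generated schedule.

Tactile stimuli are described at specification level only: T1 is a 150-Hz
carrier gated at 5 Hz with 30% duty cycle (mean cycle rate 5 Hz); T2 uses
60% duty with a 200-ms gap after every two cycles, giving
`2 / (2·0.2 s + 0.2 s) = 10/3 ≈ 3.3` cycles/s; distractors vibrate
continuously at 150 Hz.

## Diffusion kernel

The decision model is a two-boundary Wiener process with drift `v`,
boundary separation `a`, start point `z = a/2` (unbiased; errors and
corrects are the two absorption events under accuracy coding), non-decision
time `t`, and diffusion coefficient fixed at 1 — one of the two standard
scale conventions; all parameter values in this package are in
unit-diffusion scale. No inter-trial variability parameters are included.

The defective first-passage density is evaluated through the classical dual
series for the scaled process: the small-time representation
(Gaussian-image sum) and the large-time representation (sine series), with
the representation chosen per evaluation to minimise the number of terms
for a truncation error of 1e−10 on the scaled density (≤ 1e−7 after
rescaling over the parameter ranges used here). The upper-boundary density
is obtained by the reflection `v → −v, w → 1 − w`. The absorption
probability uses the closed form `(1 − e^(−2vz)) / (1 − e^(−2va))` with the
drift-free limit `z/a`. Both identities — total mass 1 and upper mass equal
to the closed form — are verified by quadrature to 1e−6 over a parameter
grid in the tests.

The trial simulator is Euler–Maruyama with explicit seeds: `dt = 1e−4`
where the simulator serves as an oracle (its boundary-crossing bias at
`dt = 1e−3` is visible at the third decimal of the choice fraction) and
`dt = 1e−3` for bulk cohort synthesis. Trials that reach neither boundary
before the 6-s display deadline are flagged as timeouts; timeouts are
excluded from all likelihoods with their count logged.

## Synthetic cohorts

A cohort is generated from an explicit `GroundTruth`: per condition cell
(3 trial types × old/new) a group-mean drift `v` and non-decision time `t`
with between-subject normal SDs (defaults 0.15 and 0.05 s — large enough
to make hierarchical recovery non-trivial at 256 trials/session, small
enough to keep it feasible), and a boundary trajectory
`a(N) = β₀ + β₁(cell)·N` with intercept and slopes shared across subjects.
The RT clock starts at visual onset: any tactile preview influences only
`t`, never an additive RT offset.

The `paper_like` scenario encodes the qualitative finding pattern: higher
drift for old than new displays (gaps 0.20/0.40/0.30 for
unisensory-visual / multisensory-visual / multisensory-visuotactile),
shorter non-decision time in the multisensory session (0.40 vs 0.45 s),
and boundary slopes below −0.063 per epoch in every cell, steeper for old
displays (−0.105 vs −0.064…−0.070). Two pressures trade off in choosing
the drift gaps: a constant old/new drift difference implies a nonzero
cueing effect already in epoch 1 (larger gaps make the initial effect
unrealistically large and strain the shared-RT₀ curve fits), while smaller
gaps become undetectable at 14 subjects under the prescribed trimming (see
below). The chosen gaps are the smallest round values for which the
practice-dependent component (the slope difference) still dominates the
cueing growth and the group contrast remains decisively recoverable. The
`null` scenario equalises all six cells (a common negative slope still
encodes procedural speed-up); note that subject-level parameters are still
drawn per cell, so `null` removes group-level differences, not
subject-level cell variability.

What the generator does **not** emulate: RT contamination (fast guesses,
attentional lapses), session-order and fatigue effects, explicit-recognition
behaviour, and any saturation of the boundary decline (the linear epoch
trend keeps declining through epoch 8). Passing tests therefore demonstrate
that the pipeline recovers truth under its own model family, not that real
search data satisfy these assumptions.

## Preprocessing

The outlier rule: for RT analyses, error trials are dropped, then RTs below
200 ms, then RTs beyond 2.5 SD of the individual's mean, where mean and SD
are computed once on the post-floor correct-trial distribution and applied
in a single pass (not iterated). For diffusion modelling, error trials are
retained (the likelihood uses both response types) and the same RT rules
are applied with subject statistics over correct and error trials jointly.
Trimming scope is per subject per session; the per-subject-overall count is
also computed and logged. One known artifact, quantified during
development and visible in the recovery experiments: a session-wide
trimming threshold removes proportionally more slow new-display trials than
old-display trials, which compresses fitted old−new drift contrasts by
roughly 0.1 in unit-diffusion scale at the default ground truth.

## Behavioral statistics

Epoch cells are subject × trial type × configuration × epoch means; the
cueing effect is `RT(new) − RT(old)` per cell. The repeated-measures ANOVA
uses the standard within-subject decomposition (statsmodels `AnovaRM`),
reporting per effect: F, integer dfs (primary), p, partial
η² = `F·df1 / (F·df1 + df2)` (algebraically `SS_eff/(SS_eff+SS_err)`), and
the Greenhouse–Geisser ε computed from orthonormal contrast covariances
(Kronecker products across the effect's factors), with the ε-corrected p
reported alongside. Post-hoc pairwise t-tests are Bonferroni-corrected.

## Learning curves

`RT_N = RT_a + (RT_0 − RT_a)·e^(−αN)` is fitted to group epoch means by
bounded least squares with a single RT₀ entering all six cells' residuals
jointly — the operationalisation of the assumption that nothing has been
learned before epoch 1, which also forces the fitted cueing curve
(new − old) through 0 at epoch 0. α is free per cell (the cells show
distinct curvature); bounds are α ∈ [0.05, 3] and RT_a within the observed
range ± 200 ms; 20 multi-starts spread initial α log-uniformly over the
bounds (the objective is mildly multimodal in α); objective tolerance
1e−10. Fit quality is the scatter index SI = (RMSE / mean observed) × 100%,
reported per trial type over its old+new epoch means (the ~1000-ms scale on
which a few-percent SI is meaningful; an SI of the cueing differences
themselves is also available).

Asymptotic cueing amplitudes `RT_a(new) − RT_a(old)` are extrapolations:
when group curves have not plateaued by epoch 8 — which the linear
boundary-decline generator guarantees — they are weakly identified and can
be unstable under resampling. Confidence intervals are therefore
subject-level percentile bootstrap (resample subjects, refit, collect
amplitudes; 2000 resamples by default), and the fitted epoch-8 cueing value
is reported alongside as the well-identified summary. A Cramér–Rao
computation during design showed that with 20-ms independent noise on each
epoch mean the learning magnitude RT₀ − RT_a cannot be estimated to better
than ≈ 20 ms median absolute error; recovery claims are therefore stated at
cohort scale (noise averaged over 14 subjects).

## Hierarchical Bayesian estimation

The model space crosses `{v, a, t}` with `{fixed, by-condition,
epoch-covariate}` dependence: 1 baseline + 6 partial + 1 full + 7 covariate
= 15 models; the covariate form is `par = β₀ + β₁(cell)·N` with a common
intercept and per-cell slopes, on the raw epoch index 1…8 (uncentered; a
centering switch exists but defaults off). Model 9 is the boundary
covariate model (`a ~ epoch:C(condition)`, `v` and `t` by condition).

Subject-level parameters are partially pooled: `θ_s ~ N(μ, σ)` per
dependence column with weakly informative group priors — μ: N(2, 3) for v,
N(1.5, 1) truncated positive for a/β₀, N(0.4, 0.35) truncated positive for
t, N(0, 0.5) for slopes; σ: half-normal(0.5). These keep the posterior
data-dominated at 512 trials/subject. Validity (a > 0 and t ≥ 0 at every
epoch 1…8) is enforced by proposal rejection, never by data deletion; a
trial with `rt ≤ t` contributes zero density and rejects the proposal.

Sampling is adaptive Metropolis-within-Gibbs over a compiled
(numba) likelihood kernel shared with the simulator: univariate
random-walk updates for every subject-level and group-level scalar, plus
two non-local moves that cure the slow directions of this posterior — a
*ridge* move proposing correlated β₀/β₁ shifts that preserve the mid-epoch
boundary value, and a *hierarchical translation* move shifting a group mean
together with all its subject values. Proposal scales adapt toward ~35%
acceptance during burn-in only and are frozen afterwards, preserving
detailed balance of the retained draws. Defaults mirror the study-scale
schedule (15 000 draws, 5 000 burn-in) with 2 chains; the test suite and
acceptance script use reduced budgets (≈ 2 000 draws) sized so the full
recovery experiments run at desk scale. Convergence is monitored with
rank-normalized split R-hat on all group parameters; any value above 1.1
flags the result with an explicit warning (never silently). At the reduced
budgets the slowest statistics (group SDs) can remain above the flag
threshold while group means and contrasts are stable across chains; the
flag is reported as-is.

Model comparison uses the conditional DIC (deviance at subject-level
parameters): `D̄` from per-draw deviances (maintained incrementally during
sampling), `D̂` at the posterior means of subject-level parameters,
`pD = D̄ − D̂`, `DIC = D̄ + pD`, with the conventional ±10 significance
band. Absolute DIC values are convention- and sampler-dependent and are
not comparable across implementations; all claims here are about
*differences* under one implementation. Hypothesis tests report P_P|D, the
fraction of retained group-level draws in the stated region. Posterior
predictive checks resimulate full datasets (one simulated trial per
observed trial at its epoch) from thinned subject-level snapshots and
compare observed and predicted mean RT per subject × condition.

## Problem sizes

Desk-scale runs use: 14 subjects × 2 sessions for single-fit recovery
(2 000 draws, 700 burn-in, 2 chains); 6 subjects and single chains for the
10-replicate DIC structure-recovery experiment; 50 000 paths at
`dt = 1e−4` for simulator–density agreement; 200 replicates for
learning-curve Monte-Carlo recovery; bootstrap budgets of 100–500 where
the full 2 000 would add nothing to the property under test. These sizes
are the package's chosen defaults for its own validation experiments.

## Known limitations

- The sampler is random-walk based; for much larger designs a
  gradient-based sampler would mix faster. The non-local moves mitigate
  but do not eliminate slow group-SD mixing at short budgets.
- The exponential amplitude is an extrapolation; see the learning-curve
  section. Prefer the epoch-8 fitted cueing value when curves have not
  plateaued.
- The session-wide trimming rule biases fitted drift contrasts toward zero
  (quantified above); analyses that need unbiased drift contrasts should
  consider per-cell trimming or none for the diffusion stage.
- The null scenario retains subject-level per-cell variability; parsimony
  experiments that require fully exchangeable cells must set the
  between-subject SDs to zero explicitly.
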