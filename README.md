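# ccdm — contextual-cueing diffusion modelling

`ccdm` is a reproducible analysis pipeline for multisensory **contextual
cueing** in visual search: the reaction-time advantage for targets embedded
in repeated ("old") spatial distractor arrangements over freshly generated
("new") ones, and the question of *which* decision process that advantage
acts on when search contexts are learned under unisensory (visual) versus
multisensory (visuo-tactile) conditions.

The package covers the full chain for a 14-subject, two-session experiment
(256 trials per session, 32 blocks of 8, three trial types:
unisensory-visual, multisensory-visual, multisensory-visuotactile):

1. **Design** — enumeration of the 144 side-balanced display
   configurations, sampling of old/new display sets (4 target positions
   per set, two per hemifield), and fully balanced block/epoch schedules.
2. **Synthetic cohorts** — trial-level data generated from an explicit
   diffusion-model ground truth, so every downstream stage is testable
   without external data.
3. **Behavior** — outlier filtering (errors, RT < 200 ms, ±2.5 SD),
   epoch aggregation (4 blocks per epoch), contextual-cueing effects, and
   repeated-measures ANOVA with partial η² and Greenhouse–Geisser ε.
4. **Learning curves** — the exponential law of practice
   `RT_N = RT_a + (RT_0 − RT_a)·e^(−αN)` fitted jointly over all six
   trial-type × configuration cells with a *shared* starting level RT_0,
   which forces the fitted cueing curve through zero at epoch 0; fit
   quality as the scatter index SI = (RMSE / mean observed) × 100%.
5. **Hierarchical drift–diffusion modelling** — a Wiener first-passage
   kernel (drift `v`, boundary separation `a`, non-decision time `t`,
   unbiased start `z = a/2`, unit diffusion), hierarchical Bayesian
   estimation over a 15-model space (parameters fixed, condition-dependent,
   or linear in epoch: `par = β₀ + β₁(condition)·N`), DIC model comparison,
   posterior-mass hypothesis tests (P_P|D), rank-normalized split R-hat,
   and posterior predictive checks.

## Worked example

```python
from ccdm import behavior, hbayes, learning_curve, synthetic_data

truth = synthetic_data.default_ground_truth("paper_like", n_subjects=14)
trials = synthetic_data.simulate_cohort(truth, seed=3)          # 7168 trials

rt_trials, report = behavior.filter_trials(trials, purpose="rt_analysis")
epochs = behavior.aggregate_epochs(rt_trials)
_, cc = behavior.contextual_cueing(epochs)
print(round(100 * report.extreme_rt_fraction, 1), "% extreme RTs")
print(cc.groupby("trial_type")["cc_ms"].mean().round(0))
```

```
3.0 % extreme RTs
trial_type
multisensory_visual           80.0
multisensory_visuotactile     57.0
unisensory_visual            110.0
Name: cc_ms, dtype: float64
```

Positive values are an old-display advantage in ms, growing over epochs as
contexts are learned. Fitting the diffusion-model space to the same cohort
(error trials retained, reduced MCMC budget):

```python
filtered, _ = behavior.filter_trials(trials, purpose="ddm")
specs = {s.model_id: s for s in hbayes.build_model_space()}
m9 = hbayes.fit_hierarchical(specs[9], filtered,
                             mcmc={"n_draws": 2000, "n_burn_in": 700,
                                   "n_chains": 2, "seed": 7})
print(hbayes.old_new_contrast(m9, "v"))
```

```
ContrastResult(description='v(old) > v(new), averaged over trial types', p_percent=100.0)
```

Model 9 — boundary separation declining linearly with epoch per condition,
drift and non-decision time condition-dependent but epoch-invariant —
recovers the generating structure: the posterior puts essentially all mass
on a higher drift for old displays, and every boundary slope β₁ comes out
negative (boundaries relax with practice, more steeply for old displays).

The same stages are available from the shell:

```bash
ccdm simulate --scenario paper_like --seed 3 --out trials.csv
ccdm behavior trials.csv --out-dir out/
ccdm ddm trials.csv --model-ids 1,9 --out-dir out/
ccdm report --out-dir out/full            # full pipeline + manifest
```

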