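# beastsim

Simulation and inference pipeline for a **BEAST-style social-information
experiment**: an incentivised numerosity-estimation task (Berlin Estimate
AdjuStment Task) measuring how much adolescents move their estimates towards
social information from an adult versus a peer, and whether household
composition (nuclear vs extended) modulates that difference.

The package is for behavioural researchers who want to (a) simulate the full
experimental design end to end, (b) run the complete measurement and
inference chain on trial-level data in the task's standard CSV layout, and
(c) validate the chain by parameter recovery and null calibration before
pointing it at real data.

## The task and the statistic

In each round a participant estimates the number of animals (50–60) in a
briefly shown image (first estimate *E₁*), sees the estimate *X* of another
person, and estimates again (*E₂*). The displayed value is controlled: a
target *X′ = E₁·(1 ± Δ)* is placed a fraction Δ away from *E₁* in the
direction of the true count (Δ = 0.25, 0.15, 0.20, 0.15, 0.25 over rounds
1–5; a coin flip picks the direction when *E₁* is exactly correct), and *X*
is the value in a pre-recorded estimate bank (144 adult / 84 student
estimates per round) closest to *X′*. Payoff: 100 points at zero error,
−5 per animal, floored at 0; one bonus item per completed 20 points plus two
participation items.

Social-information use in a round is the adjustment fraction

    s = (E₂ − E₁) / (X − E₁)

with s = 0 "stay", s = 1 "copy", 0 < s < 1 "compromise"; the rare s < 0
(contrarian) and s > 1 (overshoot) rounds are omitted by default (options:
include, or clip to [0, 1]). A participant's use of a source is
*S* = mean valid *s* per condition (*S_peer*, *S_adult*). Inference:
a paired t-test of *S_adult* vs *S_peer*; a linear mixed model of *S* on
model type × household type + gender + age with participant nested in
school as random effects; logistic mixed models of round-level stay and
copy decisions; and a mixed model comparing |estimate − truth| between
first and second estimates.

The synthetic cohort generates behaviour from a heuristic mixture
(stay/copy/compromise/contrarian/overshoot, condition-specific weights,
Beta-distributed compromise fractions) whose analytic expectations serve as
recovery oracles — see `docs/methods.md`.

## Worked example

```python
import beastsim as bs

schedule = bs.make_stimulus_schedule(seed=7)          # 5 rounds, 50-60 animals
bank     = bs.build_bank(schedule, seed=11)           # 144 adult / 84 student per round
config   = bs.CohortConfig()                          # 264 profiles, 256 analysable
trials   = bs.simulate_experiment(config, bank, seed=5)

adjustments = bs.filter_valid(bs.compute_adjustments(trials), "omit")
summaries   = bs.participant_summary(adjustments)
print(bs.paired_test(summaries).summary())
```

prints

```
Paired t-test on per-participant mean adjustment (S_adult - S_peer)
  n pairs      : 256
  mean S_peer  : 0.4554
  mean S_adult : 0.4692
  t = 0.8569, d.f. = 255, p = 0.3923, Cohen's d = 0.0536
```

i.e. in this single simulated cohort participants moved 45.5% of the way
towards peer estimates and 46.9% towards adult estimates (the generator's
long-run means are 43.7% and 47.5%; a 3.8-point condition difference is a
small effect, and the recovery harness measures ~36% power for it at this
cohort size, so a non-significant single cohort, as here, is common).
Fitting the
adjustment mixed model on the same cohort:

```python
profiles = bs.sample_cohort(config, bs.child_seed(5, "cohort"))
fit = bs.AdjustmentModel.from_tables(summaries, profiles).fit()
print(fit.summary())        # coefficient table, n = 512, N = 256
```

The `beastsim` CLI chains the same stages from a YAML config:
`beastsim bank`, `beastsim simulate`, `beastsim analyze metrics`,
`beastsim analyze models`, `beastsim recover` (parameter-recovery /
calibration harness). Every command logs a config hash and seed; identical
(config, seed) runs produce byte-identical CSVs.

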