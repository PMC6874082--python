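# Methods

This note documents the models, defaults and numerical choices behind
`beastsim`, and what the validation suite does and does not establish.

## Task engine

The engine reproduces the experimental algorithm exactly as an algorithm:

* **Stimuli.** Five rounds; true counts drawn uniformly on the integers
  50–60; a distinct (cosmetic) species label per round; 6 s display time is
  carried as metadata only — no timing is enforced.
* **Displacement schedule.** Δ = (0.25, 0.15, 0.20, 0.15, 0.25) for rounds
  1–5; the schedule type rejects entries outside [0.15, 0.25]. The target
  value is X′ = E₁(1 + Δ) below truth and X′ = E₁(1 − Δ) above it, with a
  fair coin choosing the direction at E₁ = truth. X′ stays real-valued and
  is never rounded; integer snapping happens only when the nearest bank
  value is selected.
* **Bank selection.** Candidates equal to E₁ are excluded *before*
  nearest-value search so that s = (E₂−E₁)/(X−E₁) is always defined (the
  15–25% displacement makes X′ ≠ E₁, but a bank value could still equal E₁).
  Exact distance ties are broken by a seeded uniform draw among the tied
  values. Bank sampling is non-consuming: one fixed pool serves every
  participant.
* **Counterbalancing.** Block order alternates deterministically by
  enrolment index (even → peer block first). Deterministic alternation
  gives exact balance; the original assignment scheme is unknown beyond
  "counterbalanced".
* **Payoff.** points = max(0, 100 − 5·|estimate − truth|);
  bonus items = ⌊points/20⌋ ("one item for every 20 points" read as
  completed steps), plus 2 participation items.

## Estimate bank

24 adult and 14 student members each contribute one first estimate per
round per iteration over 6 independent iterations → 144/84 estimates per
round. Iterations are independent draws because the task gives no feedback
to learn from. Adults and students share the first-estimate model by
default: participants received no information about source skill, and no
accuracy difference between the original pools is documented; separate
parameter sets are accepted where that assumption should be relaxed. Only
the construction counts of the original pool are reproducible — its
empirical estimate distributions were never published, so the bank is a
generative stand-in, not a reconstruction.

## Behaviour model (synthetic cohort)

**First estimates**: E₁ = round(true·e^z), z ~ N(bias_mu, bias_sigma),
clamped to ≥ 1. Defaults bias_sigma = 0.15 (a ~15% coefficient of
variation, typical for rapid numerosity estimation) and
bias_mu = ln 0.9 − σ²/2, so that E[E₁/true] = 0.90 exactly — the ~10%
average underestimation the task paradigm reliably produces. Dispersion is
a calibration choice: only the mean underestimation is externally
constrained.

**Second estimates**: a five-component heuristic mixture over the intended
adjustment fraction s\*:

| component  | s\*                   | peer weight | adult weight |
|------------|----------------------|-------------|--------------|
| stay       | 0                    | 0.315       | 0.280        |
| copy       | 1                    | 0.135       | 0.170        |
| contrarian | −0.2 (fixed)         | 0.022       | 0.022        |
| overshoot  | 1.2 (fixed)          | 0.056       | 0.056        |
| compromise | Beta(1.9866, 1.5134) | 0.472       | 0.472        |

E₂ = round(E₁ + s\*(X − E₁)), clamped to ≥ 1.

Calibration logic: with the omit filter (0 ≤ s ≤ 1) the expected adjustment
is (p_copy + p_comp·μ)/(p_stay + p_copy + p_comp) with μ = a/(a+b) = 0.5676
(concentration a+b = 3.5). The defaults make the filtered means exactly
43.70% (peer) and 47.50% (adult) — the reported condition means — while the
contrarian/overshoot weights reproduce the reported 2.2%/5.6% invalid-round
rates, and the stay/copy asymmetry (more staying towards peers, more copying
towards adults) matches the observed direction of the round-level effects.
The condition difference is therefore carried by the stay/copy weights;
`adult_shift` and `household_shift` are additional additive shifts on the
compromise mean (both default 0) used by the recovery harness to generate
power and type-I scenarios, and an optional `age_coef` (default 0) lets age
matter when a scenario requires it. Contrarian/overshoot magnitudes are
fixed constants rather than draws because those rounds are discarded by the
default filter — only their rates are observable.

Rounding E₂ to an integer quantises realised s in steps of 1/|X−E₁|
(typically ~7–15), which converts near-boundary compromise draws into exact
stays/copies; the effect is mean-preserving and the measured recovery bias
of the cohort mean S is < 0.4 percentage points.

**Demographics.** 264 profiles: schools 154/110, genders 129/135, 8 with
missing household information (excluded from analysis), the remaining 256
split 148 extended / 108 nuclear. Each margin is laid out exactly and
permuted independently, randomising the cross-tabulation while keeping
every margin deterministic. Ages are discretised normal draws
(mean 13.38, sd 0.88) clipped to 11–15; moments are targeted, not enforced.
Extended means a cohabiting grandparental generation; a config flag recodes
household type to also count cohabiting aunts/uncles (robustness
definition). The aunts/uncles rates themselves (50% of extended, 10% of
nuclear households) are plausible but unconstrained by published summaries.
`CohortConfig.scaled(n)` produces consistent smaller cohorts by
largest-remainder apportionment of every margin.

**What the generator does not emulate:** learning or order effects across
rounds and blocks (none are modelled because no feedback is given),
confidence-dependent weighting of advice, inter-individual trait
correlations between margins (cross-tabs are random), and any dependence of
first-estimate accuracy on age or school. Tests passing on this generator
show the *measurement and inference chain* is correct and calibrated, not
that real adolescents behave like the mixture.

## Inference

* **Paired test**: t on within-participant differences S_adult − S_peer
  over complete pairs (a positive t ⇒ stronger adjustment towards adults);
  paired Cohen's d = mean difference / sd of differences.
* **Adjustment model**: linear mixed model on the ≤ 2 condition-level S
  rows per participant; fixed effects model_type + household_type +
  interaction + gender + age; random intercepts for school and participant
  within school (statsmodels MixedLM, REML, Wald z p-values). Age is
  centred at 13 years in every model frame: slopes are per year and
  unchanged, intercepts refer to a 13-year-old. With only two schools the
  school variance is weakly identified; boundary/singular components are
  reported with a warning rather than treated as failure, and
  `include_school=False` drops the school level. `random_effects=False`
  reduces the model to OLS, which the tests pin against a normal-equations
  oracle.
* **Stay/copy models**: round-level logistic mixed models (outcome s = 0
  resp. s = 1), same fixed/random structure, fitted by Laplace/MAP
  approximation (statsmodels `BinomialBayesMixedGLM.fit_map`). The MAP
  mode and curvature sd were checked against an lme4 `glmer` fit on an
  identical frame and agree to ~3 decimals; the faster mean-field
  variational option (`method="vb"`) is retained but understates SEs and
  is not the default. By default the outcomes are defined on the filtered
  rounds (0 ≤ s ≤ 1); `rounds="all"` keeps every defined round — the
  round-level denominator in published analyses is not recoverable from
  text, so both are exposed.
* **Accuracy model**: |estimate − truth| on period (first/second) with
  period nested in participant nested in school as random intercepts; a
  signed-deviation option exists, absolute is the default because "closer
  to the correct value" is a magnitude claim.
* Exact replication of published coefficient values is out of scope (the
  raw data are unavailable); signs, magnitudes and calibration are the
  validation currency.

## Recovery harness

Each replicate re-runs the entire pipeline (schedule → bank → cohort →
sessions → metrics) from its own child seed and records cohort mean S per
condition, realised contrarian/overshoot rates, and (optionally) the
adjustment-model p-values. Against the analytic mixture expectations it
reports bias and RMSE; rejection rates give power (for the configured
condition effect) and type-I error (for the household interaction under
household_shift = 0). Measured at the defaults: recovery bias < 0.4 pp;
model_type power ≈ 0.36 at 256 participants (the calibrated 3.8 pp effect
is small); interaction rejection ≈ 0.05 under the null.

## Numerical and scale choices

* Seed scheme: SeedSequence([master, stage_id, index]) per stage
  (schedule/bank/cohort/sessions/harness), so stages re-run independently;
  child seeds are reduced mod 2³¹.
* Validation runs use scaled cohorts chosen to keep the suite quick while
  preserving calibration: 50 replicates at the full 256-participant scale
  for mean-recovery checks (Monte-Carlo SE of the replicate mean ≈ 0.2 pp,
  far inside the ±1.5 pp check), and 500 replicates at 64 participants for
  the type-I check (95% binomial band 0.031–0.069 around α = 0.05).
* CSV outputs pin float formatting (s and S to 6 decimals, estimates as
  integers) so identical (config, seed) runs are byte-identical.
* Degenerate inputs: constant binary outcomes are flagged unfitted rather
  than fitted; a zero-variance paired test returns t = 0 with a degenerate
  flag; participants with zero valid rounds in a condition contribute no
  row for it (no imputation), mirroring how missing condition rows arise
  in the published n counts.

## Known limitations

* Two schools cannot identify a school variance; the nested structure is
  kept for fidelity, not because the component is estimable.
* GLMM p-values rest on the Laplace approximation and a normal Wald test;
  no Satterthwaite/Kenward-Roger small-sample corrections are provided.
* The compromise law, first-estimate dispersion and aunts/uncles rates are
  calibration choices constrained only by published summary observables;
  different choices reproducing the same observables would validate the
  pipeline equally well.
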