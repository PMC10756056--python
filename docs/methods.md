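# Methods

## Learning model

Both learners estimate one value `w_m` per stimulus dimension and score a
compound stimulus additively, `Q = Σ_m x_m w_m`, where `x_m` is the realized
feature (the sampled size on dimension 1, 0/1 elsewhere).  After reward `R`
for the chosen stimulus, every present feature updates by
`w_m ← w_m + α_m δ x_m` with prediction error `δ = R − Q`.  Only the chosen
stimulus's features are updated: the individual experiences one reward per
trial, and learning about the unchosen option would require an outcome it
never observed.

The constant learner keeps `α_m = α₀` forever.  The flexible learner runs
Autostep, in this order per trial, restricted to present features:

1. normalizer: `v_m ← max(|δ x_m h_m|, v_m + (α_m x_m²/τ)(|δ x_m h_m| − v_m))`
2. rate (if `v_m > 0`): `α_m ← α_m · exp(μ δ x_m h_m / v_m)`
3. overshoot guard: `α_m ← α_m / max(Σ_m α_m x_m², 1)`
4. weight: `w_m ← w_m + α_m δ x_m`
5. trace: `h_m ← h_m · max(0, 1 − α_m x_m²) + α_m δ x_m`

`h_m` is a decaying memory of recent weight changes; `δ x_m h_m` is positive
when the current change continues a recent trend (rate should grow) and
negative when it reverses it (rate should shrink).  `v_m` normalizes that
signal to its own recent maximum, making the log-scale rate step scale-free.
The guard in step 3 caps the summed effective rate at 1 so a single trial
can never overshoot the target; the `max(0, ·)` in step 5 keeps the trace
from changing sign explosively when an individual rate is at the cap.
Absent dimensions are left bit-identical, which is why learning-set
formation shows no "learning to learn" here: each new pair starts from
untouched rates.

With `μ = 0` the flexible learner reduces exactly to the constant learner
(the test suite asserts trajectory equality), which pins the two
implementations to a single semantics.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `α₀` | 0.04 | initial/constant learning rate; learns a unit value difference over ~50–100 trials |
| `μ` | 0.2 | Autostep meta learning rate (log-scale step applied to `α`) |
| `τ` | 10⁴ | normalizer time scale (trials, weighted by `α x²`) |
| `ω` | 5 | soft-max sharpness; a value gap of 1 is chosen with p ≈ 0.993 |
| `σ_x` | 0.25 | log-scale SD of the size dimension |
| `σ_R` | 0.10 / 0.50 / 0.02 | log-scale SD of reward noise (complex world / high-stochasticity variants / reversal & learning set) |
| `w₀` | 0 | initial estimates (naive individuals) |
| replicates | 100 | independent individuals per experiment |

`μ` and `τ` deserve comment.  Autostep's published recommendation is that
results are robust over a wide `μ` range with `τ = 10⁴`; in these
environments `τ` is immaterial (we scanned 10³–10⁴) and `μ` sets how fast
rates respond to volatility.  `μ = 0.2` reproduces the reference
post-transition losses of the flexible learner (smaller `μ` adapts more
sluggishly and drifts toward constant-rate behavior); all qualitative
signatures (rate spikes at reversals, rate suppression under stochasticity,
learning-set flatness) hold across the scanned range.

## Environments

The generator emulates a forager whose world grows more complex: ten
compound-stimulus types over ten dimensions (one quantitative "size"
dimension with per-type means 1.0 or 2.0, nine 0/1 features with true
per-unit values 1.0, 0, 1.0, −1.0, 2.0, 1.0, −1.0, 2.0, 1.0, −1.0), shipped
as `data/stimulus_table.csv`.  Sizes are log-normal with the half-variance
correction `y = ln(mean) − σ_x²/2` so the arithmetic mean equals the
nominal size; rewards are log-normal around the true expected value with
the same correction (mean-preserving; a `median_preserving` switch drops
it).  Every type-level expected value is positive (1, 2, 3, 1, 3, 2, 1, 3,
2, 1), but a small realized size can push a realized value of the
negative-feature types (CS4/CS7/CS10) to ≤ 0 (~0.4% of draws); such values
are clamped to 0.01 before noise, and the recorded expected rewards use the
clamped value — the raw ratio `V_chosen/V_max` is ill-behaved near zero
denominators, the clamped one is the mean reward the stimulus actually
delivers.

Scenario schedules:

* `case1` / `case2` — 1000 trials with CS1–CS2, then 1000 trials with
  CS1–CS4 / CS1–CS10 (`σ_R = 0.10`).
* `case3`–`case6`, `case1_long`, `case2_long` — the high-stochasticity
  (`σ_R = 0.50`) and long-horizon (10,000 trials per phase) variants:
  case3/case4 raise the noise, case5/case6 raise noise and horizon,
  `*_long` raise the horizon only.  This naming is the package's own.
* `reversal` — two binary dimensions; four 100-trial phases; the rewarded
  stimulus (R = 1) and unrewarded stimulus (R = 0) swap each phase
  (`σ_R = 0.02`; R = 0 is delivered noiselessly, since log-normal noise
  around zero is undefined and would anyway carry no information).
* `learning_set` — eight binary dimensions; four 100-trial phases, each
  with a brand-new rewarded/unrewarded pair.

Pair sampling: in the complex-world cases the two stimuli of a trial are
*two independent draws* from the phase's active types, so the same type can
appear on both sides (such trials are still informative: two sizes are
realized).  The reversal and learning-set tasks present the fixed
rewarded/unrewarded pair every trial.  A scenario-level `allow_same_type`
switch exposes the alternative (distinct-pair) convention; under it the
complex-world losses run roughly one percentage point higher.

What the generator does *not* emulate: interacting agents, non-additive
(configural) reward structure, correlations between size and other
features, state-dependent foraging.  Passing tests therefore show that the
learning rules behave as specified under this statistical structure, not
that real cleaner fish learn this way.

## Performance measures

* Block summaries: means of rates, weights, proportion correct (chose the
  higher-valued stimulus; exact ties count correct — a measure-zero event
  when sizes are realized) and proportion of reward per block of 10 trials,
  pooled over replicates.
* Proportion of reward: per trial `V_chosen / V_max` on expected (clamped)
  rewards; a trial with `V_max = 0` (possible only in degenerate
  configurations) counts as 1.  Losses are `100 (1 − proportion)`.  Both
  the per-trial-mean and the ratio-of-sums aggregation are implemented;
  learner losses are reported with the per-trial mean.
* RMSE: root mean square of `Q_chosen − V_chosen` over a window, the
  precision of the value estimates irrespective of choice quality.
* Trials to criterion: first block of a phase with pooled proportion
  correct ≥ 0.8.  The threshold is this package's choice, used for
  property checks only.
* Frozen-policy evaluation: a non-learning soft-max or greedy chooser with
  fixed weights, scored with the same loss.  The size-only baseline
  (weights frozen at the phase-1 truth: size 1, all else 0) is reported
  with greedy choice and the ratio-of-sums loss — the convention under
  which it reproduces the reference levels (≈7.4%/22% for cases 1/2); with
  soft-max choice and per-trial averaging it lands ~1–2 points higher, and
  both variants are exposed.

## Numerical and design notes

* Reproducibility: one root seed per experiment; replicate `r` runs on an
  independent child stream (`SeedSequence.spawn`), so any single replicate
  can be replayed bit-exactly from its child seed.
* Phase changes are silent: no reset of `w`, `α`, `h`, `v` at boundaries —
  coping with unannounced change is the phenomenon under study.
* Records hold post-update snapshots of `w` and `α`; block averages are
  computed from those.
* Constant-learner serial reversal shows a modest speed-up across
  reversals (criterion reached ~2 blocks earlier by reversal 3) caused by
  residual weight on the previously rewarded dimension — the value gap to
  unlearn shrinks each time.  This is a property of the delta rule with
  incomplete extinction, distinct from the flexible learner's rate-driven
  acceleration, which is both larger and present already in the first
  reversal; the tests separate the two mechanisms accordingly.

## Known limitations

* Autostep's `μ` is the one behaviorally consequential free parameter; the
  default is matched to the reference post-transition losses rather than
  derived from first principles.
* The high-stochasticity and long-horizon variants are runnable
  configurations; only their phase-1 rate-suppression signature is covered
  by the test suite.
* The environment is stationary within phases; drifting reward means
  (continuous volatility) are not modeled.
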