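# Methods

## Task and designs

The simulated paradigm is a two-alternative cognitive-effort choice task.
On every trial a participant chooses, within 5 s, between a **baseline**
option (1 credit for minimal effort) and an **effortful** option offering
2–12 credits for mentally adding a trial-specific addend to each of three
digits and reporting, within 3 s, the units digit of each sum (adding 3 to
2, 6, 7 gives "590" — sums 5, 9, 10, keeping only the final digit of each;
the single published example of the rule forces this mod-10 convention and
it is applied globally).

Two factorial designs are built in:

| | effort levels (addends) | rewards (credits) | targets | trials |
|---|---|---|---|---|
| Study 1 | 1, 3, 5, 7, 9 | 2, 4, 6, 8, 12 | self, charity | 150 |
| Study 2 | 1, 3, 5, 6, 7 | 2, 4, 6, 8, 12 | self, charity, stranger | 225 |

Each participant sees 75 trials per target, every target × effort × reward
cell exactly 3 times, in a seeded uniform permutation of the balanced cell
list (targets fully interleaved; the source studies intermixed targets
within blocks but do not constrain run lengths, so no run-length constraint
is imposed). Effort enters the models as an ordinal rank 1–5. In Study 1,
pre-testing rated add-7 harder than add-9, so the rank map places addend 7
at rank 5 and addend 9 at rank 4; the map is configurable.

## Discounting model family and likelihood

Subjective value of the effortful option, with `E = rank/5`:

- linear `SV = r(1 − kE)`
- parabolic `SV = r(1 − kE²)`
- hyperbolic `SV = r/(1 + kE)`

The `E = rank/5` scaling is a design choice: at `k = 1` the hardest level
discounts a reward fully under the linear form, so `k` reads as "fraction
of value destroyed by maximal effort". Negative subjective values are
allowed (worse than nothing) and not floored. The baseline option is fixed
at its 1-credit value, never discounted.

Choice follows a two-option softmax, implemented as the logistic of the
value difference: `P(effortful) = expit(β(SV − 1))`. Crossing the three
forms with shared vs. per-target `k` and `β` yields 12 specifications with
canonical names like `linear_kTarget_betaShared`.

The per-participant likelihood is Bernoulli over trials; probabilities are
clipped to `[1e−10, 1 − 1e−10]` to keep the log finite. Parameter bounds:
`k ∈ [0, 1.5]` for linear/parabolic (values above 1 push SV negative at
high effort), `k ∈ [0, 20]` for hyperbolic (its discounting is much
shallower per unit `k`), `β ∈ [0, 30]` credits⁻¹ — together spanning
indifference to near-deterministic choice on the 2–12 credit range without
numerical overflow.

## Fitting and model comparison

Each participant × specification is fitted by minimizing the negative log
likelihood with Powell's bounded derivative-free search from `n_starts`
(default 20; 10 in the pipeline) uniform random starting points drawn from
a seeded generator; the best start is reported, with a convergence flag.
Objective tolerance is 1e−8. Multi-starting guards against the likelihood's
plateaus at extreme `β`; on easy instances a single start matches the
20-start optimum to 1e−4 (tested).

BIC uses the participant's own trial count (150/225) as the sample size.
Cohort comparison aggregates summed, mean, and median BIC and counts
per-participant winners. Paired contrasts of fitted parameters between
targets use a paired two-sided t-test with effect size
`r = sqrt(t²/(t² + df))`.

Validation utilities: `parameter_recovery` (simulate → refit; reports
true-vs-recovered Pearson r, bias, RMSE per parameter, and checks that the
fitted NLL never exceeds the NLL at the generating parameters) and
`predictive_check` (point-biserial correlation between fitted trialwise
probability and the observed choice; undefined-and-flagged when either side
has zero variance, e.g. a `β = 0` fit). Under ceiling response patterns
(near-always-effortful participants) `k` is recovered well but `β` is
weakly identified — an inherent identifiability limit, since any
sufficiently large `β` produces the same degenerate choices.

## Synthetic cohorts

Choices are generated from exactly the model family that is fitted, with
per-participant, per-target `k` and `β`. Behavioral features are Gaussian
choice decision time truncated to (0, 5 s], Bernoulli task accuracy, and
Gaussian task RT truncated to (0, 3 s], parameterized per target so that
self-vs-other separability is directly controllable. An optional fatigue
term adds a linear drift (reaching `fatigue_slope` logits at the final
trial) to the effortful-choice log-odds; it is off by default.

The default `CohortModel` encodes the study conditions the simulations are
meant to emulate. On this effort scale, interior choice rates require
`k` roughly in 0.8–1.4 (computed analytically from the cell-average choice
probabilities), so `k_self ~ N(0.9, 0.25)` clipped to [0, 1.4], with mean
increments of +0.10 for charity and a further +0.12 for stranger
(discounting is steeper for others, steepest for strangers); `β_self ~
U(3, 10)` shrunk by U(0.6, 1) for other targets (less consistent choices
for others). Recruits drawn below `k ≈ 0.75` sit at the ≥85% effortful
ceiling and are removed by the exclusion filter, mirroring the heavy
ceiling exclusion rates of the empirical cohorts. Other-target features are
slowed by a 0.1 s base shift plus 0.6 s per unit of `k_other − k_self`,
coupling decodability to prosocial discounting; an optional compassion-like
covariate (1–5) decreases with that shift, with coupling and noise chosen
to give covariate–accuracy correlations in the moderate negative range.
Defaults are fixed here once; studies wanting different conditions override
`CohortModel` fields or pass their own sampler.

What the generator does **not** emulate: sequential dependencies (beyond
the optional fatigue drift), arithmetic-difficulty effects on accuracy/RT
(accuracy is a free parameter, not tied to the addend), the ≥90% accuracy
payment rule, and any within-session learning. Passing tests therefore show
that the estimation and decoding machinery is correct and well calibrated
under the stated generative assumptions — not that real behavior follows
them.

## Exclusions

Participants choosing the effortful option on ≥85% or ≤15% of trials are
excluded (both cutoffs inclusive and configurable). The preregistration
wording ("more than 85% or less than 15%") is strict while the reported
counts use the inclusive phrasing ("85% or more" / "15% or fewer"); the
inclusive reading is adopted.

## Two-stage choice regression

The trialwise choice analysis is a deliberate **surrogate** for a maximal
random-effects mixed logistic model, at summary-statistics scale: stage 1
fits a ridge-penalized logistic regression (sklearn, C = 1.0 — weak enough
to leave well-identified coefficients essentially unpenalized, strong
enough to keep separation finite) of choice on normalized effort,
normalized reward, and target dummies (vs. self) per participant; stage 2
t-tests each coefficient against zero across participants with effect size
r. The 5 ordinal effort/reward levels map linearly onto [−1, 1]
({−1, −0.5, 0, 0.5, 1}). Coefficient signs and relative magnitudes — not
z-values — are the quantities comparable to a full mixed model.

## Decoding and overlap

Per participant and target pair (self vs. charity, self vs. stranger), a
linear SVM (C = 1.0, never tuned) decodes the trial's target from five
features: choice decision time, task accuracy, task RT, effort, reward.
Choice is never a feature (it would leak the behavior that overlap scores
are later correlated with); requesting it raises an error. Folds are
stratified five-fold, shuffled with a seed; features are z-scored within
each training fold only (margin classifiers need comparable scales; scaling
on the full data would leak test-fold statistics). Accuracy is reported in
percent; regressions use proportion units, converted centrally.

Group analyses: OLS of the prosocial delta (rate(other) − rate(self)) on
accuracy; paired t-test of stranger-pair vs. charity-pair accuracies; OLS
of accuracy on a participant covariate. Degrees of freedom are reported as
n − 2 (OLS) and n − 1 (paired t) from the data actually used.
A multiclass one-vs-rest variant can decode effort or reward level instead
of target.

**Null calibration and anti-learning.** With features carrying no label
information, expected decoding accuracy is 50% — but only when features are
i.i.d. across trials. If the discrete effort/reward features are taken from
the balanced factorial schedule, every cell is *exactly* equated across
classes, which induces a negative dependence between training and test
folds and a below-chance bias of several points ("anti-learning") even with
zero signal. The calibration utility `simulate_null_features` therefore
draws all five features i.i.d. (times and accuracy from the feature model,
effort/reward uniform over their levels); with 200 simulated participants
of 150 trials the mean accuracy is statistically indistinguishable from 50%
(within two standard errors). In the real analyses the time/accuracy
features are not design-balanced, but the residual conservative bias from
the balanced effort/reward columns is worth keeping in mind when reading
absolute accuracies near chance.

## Pipeline

`run_pipeline` chains simulate → exclude → describe → fit → compare →
decode → report into one run directory of tidy CSVs plus a config snapshot
and log; stages re-run individually from the cached CSVs, and the CLI
(`proseffort`) exposes one subcommand per stage. A single global seed
expands deterministically into per-stage seeds via
`SeedSequence([seed, stage_index])`, and per-participant streams are
spawned from the stage seed, so reruns are byte-identical.

## Problem sizes and numerical choices in the test suite

Tests run at desk scale by design: recovery studies use 40 participants at
10 starts; form-identification uses 25 replicates of 3-participant cohorts
per form at 5 starts (pilot identification was perfect at this size);
null calibration uses 200 participants; directional cohort checks use
40–150 participants (larger where cell-level orderings must clear binomial
noise at every effort level). Oracle-equivalence checks compare NLL, BIC,
OLS, paired t, and point-biserial r against independently coded closed
forms at 1e−8 on hand-built tables.

## Known limitations

- Per-participant MLE only; no hierarchical shrinkage or Bayesian
  estimation, so near-ceiling participants have weakly identified `β`.
- The two-stage regression is not a mixed model; its test statistics are
  not comparable to `glmer` z-values.
- The effort scale is ordinal-by-design (`rank/5`); no claim that perceived
  effort is linear in the addend.
- The generator's feature model is Gaussian/Bernoulli and stationary;
  decoding results on real data will reflect richer structure
  (autocorrelation, difficulty effects) that it does not produce.
- Power-function and two-parameter discounting forms are out of scope.
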