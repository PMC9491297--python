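# Methods

This note documents the models, the task generator's guarantees, the
synthetic-cohort conditions, and the numerical and design choices behind
`grlkit`. It is the package's own account; every empirical number referred
to here is computed by the test suite or `scripts/acceptance.py`.

## Task environment

A session is 4 runs × 3 blocks × 32 trials = 384 trials. Four cues (2
categories × 2 states) appear in randomized quartets — each quartet contains
every cue once, and no cue repeats on consecutive trials (enforced by
constrained shuffling with a bounded retry budget; infeasible configurations
raise a design error). Each block assigns one rewarded action per state,
with opposite rewarded actions for the two states of a category
("metastate" AL/BR or AR/BL).

Reward probabilities are multiples of 1/16 and are realized as *exact
counts* among each state's 8 trials per block:

* unequal-category blocks: the greater category pays 10/16 and 16/16 (counts
  5 and 8), the lesser category pays 7/16 for both states;
* equal-category blocks: both categories pay 7/16 and 13/16.

Odd sixteenths cannot be realized in a single block, so each 7/16 instance
is realized as a 3-and-4 half-split over its block pair (6/16 and 8/16) and
each 13/16 as 6-and-7 (12/16 and 14/16), averaging to the net probability.

Three block conditions form a nearly-factorial 3 × 2 × 4 design: relative
category value (3 levels, one per run), the identity of the higher-valued
state (2 levels, 2:1 within each run), and the state-to-action mapping of
both categories (4 levels, fully crossed with the 3-level condition over the
12 blocks). Between consecutive blocks exactly one category's mapping
reverses, and each category reverses exactly once per run.

**Counterbalancing algorithm.** The assignment is a seeded constrained
sampler. Within a run the three mappings must form a chain under
single-category flips, which forces the third block's mapping to be the
double flip of the first; a simple cyclic rotation of condition-3 levels
across runs is therefore *incompatible* with completing the 3 × 4 cross
(exhaustive search over all rotations and chain combinations finds no
solution). The sampler instead draws per-run condition-3 permutations and
remap chains jointly from the enumerated feasible set. The higher-valued
state and the half-split orientations are then chosen subject to exact
cancellation pairings, which guarantee three properties *exactly* (not just
in expectation): a constant-action chooser earns half of all scheduled
rewards, each category precedes half of each run's rewards, and every run
carries one quarter (here: exactly 60 of 240) of the session's rewards. Any
assignment satisfying the audited invariants is admissible; the audit
(`validate_counterbalancing`) re-derives every property from the trial
table.

Reward positions within a state's trials are uniform without replacement —
the design fixes counts, not positions. Missed trials are a property of
choosers, not the environment. Cue identities are fresh per run in the
`3FH` variant and constant across the session in `7CM`; trial timing (2 s
response window, 3 s ISI, 1 s outcome, 3–7 s ITI drawn without replacement
from a 1/24-s grid per run) is carried as metadata for regressor export and
plays no role in choice modeling.

## Model zoo

All 17 learning models and 3 baselines share one trial loop:

1. **Cue onset.** SVPE δ_V = max_a Q(s,a) − V(s0); V(s0) += α·δ_V. This is
   a convex combination, so no clamp is needed.
2. **Choice.** Softmax with temperature τ over
   w_MB·Q_MB + (1−w_MB)·Q + β(a) + β_R·I_R(a), max-subtracted for overflow
   safety (shift-invariant by contract). The hysteresis bias uses the
   *pre-choice* state and updates after the action:
   β(a) ← λ_β·β(a) + β_0·1[a = a_t], provably equal to the decayed sum over
   the action history (property-tested against the closed form).
3. **Outcome.** AVPE δ_Q = r − Q(s,a), then the five updates listed in the
   README. The clamp f applies only where a relayed error can exit [0, 1]:
   the eligibility-trace update of V and the three generalized Q updates.
   Direct delta updates cannot leave the interval when values start there
   and r ∈ {0, 1}; the code asserts this instead of clamping.
4. **Beliefs** (metastate learners). The hypothesis consistent with
   (s, a, r) follows the 8-case rule (e.g. a rewarded left press in state A
   is consistent with AL/BR). The SPE learner moves P(ĥ|c) toward 1 with
   rate α_SPE and renormalizes the complement exactly. The HMM propagates
   each category's posterior through the reversal rate θ_1 *at that
   category's next observation* and applies Bayes' rule with likelihood θ_0
   / 1−θ_0. Model-based action values read the current propagated prior
   (HMM) or current estimate (SPE) before the trial's outcome.

**Initialization and resets.** V(s0) starts at 0 once per session and
persists across runs (configurable). Q values, hysteresis biases, the
action counter and beliefs re-initialize at each run start, mirroring the
per-run replacement of cues; the same reset is applied in the `7CM` variant
for comparability (configurable switch).

**Missed trials.** No policy likelihood term, no hysteresis increment, no
outcome-driven updates; the SVPE update still applies because the cue was
seen. Learning from the forced nonreward of a missed trial is available as
a documented option, default off.

**Degrees of freedom.** The eligibility trace λ is fixed at 0.5 — with one
step per trial it is not identifiable as a free parameter. The fixed-weight
models (e.g. `A-|S-`) tie the interaction coefficient to g_S·g_A; only the
8-parameter `AX|SY|Z` frees g_SA ∈ [−1, 0]. `AW|SW` shares one weight
(g_A = min(0, g_S)). The hysteresis baseline keeps τ as a degree of freedom
(df = 4) even though only the ratios β/τ are identified without learning;
fits of that model are interpreted through those ratios.

**Numerical guards.** Probability floor 10⁻¹² in HMM normalization and in
per-trial log-likelihoods.

The single-trial operations live in `grlkit.models` as plain Python (the
reference semantics); `grlkit.engine` compiles one numba kernel that replays
or simulates whole sessions for any registry model. The test suite asserts
the kernel's session likelihoods equal the reference replay to 10⁻⁸ across
model families, and that nested parameter settings reproduce nested models
bit-for-bit.

## Simulation

Free-running agents sample choices from their own policy; a reward is
delivered iff the chosen action is the state's rewarded action *and* the
schedule made a reward available on that trial — an agent can never earn
more than the scheduled counts. Yoked simulation pins a reference record's
trial sequence and contingencies while the simulated agent's own choices
determine its outcomes. Synthetic reaction times
(RT = 0.85 − 0.30·|ΔQ|_norm + N(0, 0.15), truncated to [0.2, 2] s) exist
only to exercise the RT regression machinery; no behavioral RT model is
implied.

## Fitting and model comparison

Free parameters map to an unconstrained space by scaled logit over their
bounds; Nelder-Mead (adaptive, xatol 10⁻⁴, fatol 10⁻⁷) runs from a
mid-bounds start, uniform-in-bounds random restarts (default 10; scaled-down
recovery studies use 3–8), and *nested warm starts*: each model is also
initialized at the fitted optima of its nested submodels (for instance
`AX|SY` starts from the fitted `A0|SY`, `AX|S0` and `A-|S-` solutions).
Warm-starting enforces likelihood monotonicity across nesting in practice
and removes the optimizer noise that otherwise handicaps higher-dimensional
models in AICc comparison. Ties between restarts resolve to the solution
reached in fewer iterations; ties in AICc resolve to fewer degrees of
freedom.

AICc = 2k + 2·NLL + 2k(k+1)/(n−k−1) with n the number of non-missed trials.
Goodness of fit is reported as residual deviance relative to the hysteresis
baseline. "Significant improvement over hysteresis" for the Poor/Nonlearner
split is operationalized as AICc(best learning model) < AICc(hysteresis); a
likelihood-ratio alternative exists but is not the default, since the
AICc-based rule matches how nonlearners are characterized (best fitted by
hysteresis after penalization). Learner classification excludes each cue's
first encounter from the accuracy numerator and uses a one-tailed exact
binomial test against 50%. Generalizer classification uses the sign of the
fitted g_S with a tolerance band |g_S| ≤ 10⁻³ (bounded optimization rarely
lands exactly on 0).

## Behavioral analyses

**First-generalization trials.** Each category has two constant-mapping
epochs per run (it is remapped exactly once), so a complete session offers
2 × 2 × 4 = 16 diagnostic opportunities. Within an epoch, after the
category's first rewarded state-action pair, the *next* encounter with the
complementary state is diagnostic; correct means choosing the complementary
action. The strict next presentation is used regardless of intervening
same-state trials; missed diagnostics are dropped, not deferred. (A reading
that takes one diagnostic per block would yield 24, which contradicts the
2 × 2 × 4 accounting; the epoch reading is implemented.)

**Conditional repeat probabilities.** For every responded trial, the most
recent same-state and most recent other-state (same category) trials within
the run are antecedents, binned by whether they were rewarded; the statistic
is the probability of repeating the antecedent's action, and the interaction
(same: reward effect) − (other: reward effect) is the signature of
discriminative state generalization (it inverts the reward effect for the
other state). Antecedents without a response are excluded.

**Psychometric regressions.** Choice: per-subject logistic regression of
repeating the most recent action on the signed value difference (positive
toward the previous action), normalized by the subject's maximum absolute
difference; the hypothesized slope is positive. RT: linear regression on
the normalized absolute difference; hypothesized slope negative. Degenerate
subjects (all-repeat/never-repeat, constant RT) are flagged and excluded
from group tests. All group tests are one-tailed with directions fixed a
priori (discriminative > chance, associative < chance, discriminative >
nongeneralizer > associative, more negative g_S → higher accuracy).

**Posterior predictive checks.** For each subject, agents with the fitted
parameters replay the subject's session yoked; first-generalization accuracy
and the repeat bins are averaged across simulations (default 100 here; the
statistic stabilizes well below that) and compared with the source cohort's
own statistics.

## Synthetic-cohort conditions

Synthetic agents stand in for participants throughout. Conditions were
fixed as follows and are used by both the test suite and the acceptance
script:

* **Default sampler** — uniform over ranges typical of engaged learners
  (α ∈ [0.1, 0.9], τ ∈ [0.2, 1.5], |β| ≤ 0.5, g free over its bounds).
* **Population sampler** — truncated normals with the fitted good-learner
  group statistics (mean α 0.517, g_A −0.355, g_S −0.184, τ 0.698,
  β₀ −0.066, λ_β 0.543, β_R 0.113), for cohorts meant to emulate the fitted
  human population.
* **Recovery cohort** (`COHORT_PRESETS["generalizer"]`) — g_S ≤ −0.3,
  g_A ≤ −0.3, τ ≤ 1.0. Model recovery asks whether the 7-parameter model is
  identifiable *when agents actually use both generalization dimensions*; an
  agent with g ≈ 0 is behaviorally a nested model, so diffuse cohorts
  confound cohort composition with model discriminability. The converse
  cohort (basic RL) uses the default sampler.
* **PPC cohorts** (`discriminative` / `associative`) — |g_S| ≥ 0.4,
  g_A ≤ −0.3, mild biases (|β₀| ≤ 0.2). A single rewarded observation must
  relay a value difference of order g_S·α to the complementary state for the
  16-trial probe to bite against softmax noise, and a strong perseverator
  mechanically fails the complementary-action probe whatever its weights —
  hence unambiguous weights and small biases define these groups.

## What passing tests do and do not show

The generator reproduces the task's combinatorial structure and exact
reward-accounting guarantees, and the synthetic cohorts reproduce the
qualitative machinery: discriminative cohorts above chance at first
generalization, associative below, basic-RL posterior predictions unable to
reach above chance, the repeat-bin crossover, and model/parameter
recoverability at full session length. They do not certify human parameter
values or group-level effect sizes: synthetic agents have no attention
lapses, no RT-accuracy coupling beyond the synthetic RT generator,
independent parameters (real fits show correlated α and τ), and no missed
trials unless injected. Scales (20–40 subjects, 100 PPC simulations, 3–8
restarts) are the package's default desk-scale study sizes; all are
arguments, not constants.

## Known limitations

* The SARSA variant is not implemented (indistinguishable with one action
  step per trial), nor are forgetting/decay of unvisited values,
  reference-dependence or range normalization.
* Hierarchical/Bayesian group-level estimation is deliberately out of scope;
  fits are strictly subject-level.
* The regressor-table export stops at the event/modulator table; no HRF
  convolution or GLM estimation.
* `generate_session` supports the canonical 4 × 3 × 32 geometry (and
  multiples of 32 trials per block); other geometries raise a design error
  rather than silently breaking counterbalancing.
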