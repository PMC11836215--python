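# Methods

## The task

A round presents two matrices of 12 keys each. Every key holds a latent
outcome, drawn independently at the start of the round and fixed until the
round ends:

| matrix  | low outcome | high outcome | p(high) |
|---------|------------:|-------------:|--------:|
| Try     | +1          | +14          | 0.1     |
| Give-Up | +1          | +2           | 0.5     |

A round lasts 12 trials. On each trial the player presses one key in
either matrix. The first press of a key in a round reveals its outcome and
charges an exploration cost (2 points at baseline); re-pressing a revealed
key harvests its fixed value at no cost. The structure creates two "local
maxima" of suboptimal behavior: settling for Give-Up rewards, and settling
on a familiar +1 Try key to avoid further exploration costs.

Four intervention schemes modify the middle block of a three-block
(baseline, treatment, baseline) session. All are encoded as additive
per-level outcome deltas plus a per-matrix exploration-cost override:

- `minus_giveup` — every Give-Up outcome is penalized by 2 points.
- `minus_giveup_minus_trylow` — Give-Up outcomes *and* low Try outcomes
  are penalized by 2 points. The low-Try penalty applies to every press of
  a low key, including a first press that merely reveals it: the scheme is
  defined on outcome values, and a press that produces a low Try outcome
  is penalized regardless of why it was made.
- `plus_try` — every Try outcome is rewarded with 2 points.
- `plus_try_explore` — Try exploration costs are waived (a first-press
  reward exactly offsetting the cost). The waiver is scoped to the Try
  matrix only; Give-Up keys keep their cost. The scheme's point is to
  reward *Try exploration*, and extending the waiver to Give-Up keys would
  subsidize the behavior the intervention exists to displace.

Scheme deltas apply on every press, because they modify outcome values and
outcome values are earned on every press; only the exploration-cost waiver
is inherently first-press-scoped. Removing a scheme's deltas and restoring
the baseline cost recovers the baseline payoff of any trial exactly —
this identity is what makes incentive stripping (below) exact rather than
approximate.

Key identity carries no information (keys are i.i.d. within a matrix), so
on-screen layout and shuffling are not modeled; keys are indices, and
agents that explore always take the lowest-index fresh key.

## Optimal benchmark

Because keys are i.i.d., a planner never updates beliefs about the outcome
probabilities; the only state that matters is, per matrix, the best outcome
level already secured and the number of unexplored keys, plus the number of
trials remaining. `solve_dp` runs exact backward induction over this
5-tuple belief space (≈20k states at the shipped sizes, milliseconds to
solve). Exact ties are broken by a fixed action order so solved policies
are reproducible. The abstraction requires that scheme deltas not invert
the low/high ordering within a matrix (true of all shipped schemes;
enforced with a validation error otherwise, since an inverted ordering
would make "exploit the best level" ill-defined).

`brute_force_value` certifies the abstraction: it solves tiny instances
(≤4 trials, ≤3 keys per matrix) by exhaustive recursion over every
concrete key press with full per-key histories and no abstraction. The
test suite checks agreement to 1e−9 on 50 randomized instances, including
randomized schemes.

### The threshold family and the switch point

The threshold strategy S_m explores fresh Try keys until a +14 is found
(then exploits it to the round's end) or until m explorations have failed,
after which it searches the Give-Up matrix for a +2 and exploits that.
`threshold_value_exact` evaluates each S_m in closed recursion;
`benchmark_strategy_comparison` tabulates the family and, separately, asks
after each failure count whether switching to Give-Up search is the
optimal continuation.

At the shipped parameters the answer is clear-cut and worth stating
because it contradicts a natural intuition: **expected payoff is strictly
increasing in m**. E[S_0] = 19.00, E[S_9] = 68.43, E[S_12] = 69.69, and the
unrestricted DP root is 69.91. Switching to Give-Up search never improves
the expected continuation — even on the last trial, exploring a fresh Try
key (EV 0.3) beats exploring Give-Up (EV −0.5), and the only deviation the
unrestricted DP ever makes from pure Try search is exploiting an
already-known +1 Try key on the final trial (1.0 > 0.3). A
switch-after-nine-failures rule is therefore an approximation that gives
up about 1.26 points per round, not the family optimum. The comparison
report surfaces this explicitly (table, per-failure-count continuation
values, and notes) rather than asserting any fixed switch convention.

### The per-trial optimality classifier

The dependent-variable classifier deliberately uses the simple
search-then-exploit rule, not the full DP policy: a choice is
benchmark-consistent iff no high Try key is known and the choice explores
a fresh Try key, or a high Try key is known and the choice exploits a
known-high key. Within the analysis window (trials 1–9) this rule and the
unrestricted DP agree at baseline; they can diverge only at the very end
of a round, which is exactly why the analysis window exists. The four
categories (Give-Up, Try exploration, Try-low exploitation, Try-high
exploitation) partition all possible choices, so category shares sum to 1
by construction, and this is property-tested.

## Agents

Fixed strategies: `giveup_searcher` (search Give-Up for a +2, exploit),
`trylow_settler` (explore one Try key, exploit it regardless),
`threshold_try(m)` (the S_m family; cross-checked by Monte Carlo against
the exact evaluator), and `dp_optimal` (follows the solved policy table;
its 100k-round mean matches the DP root within 3 SE). Agents see only a
`RoundView` of revealed levels and counters — latent values are not
reachable through the interface.

`adaptive_learner` operates over round-level meta-strategies rather than
trial-level values: each round it picks one of {Give-Up search, Try-low
settle, Try search} by softmax (temperature τ) over propensities, then
moves the chosen propensity toward the realized round payoff by step α.
When the scheme changes between blocks, propensities decay toward their
initial values by fraction ρ (0 = full persistence, 1 = full reset), the
retention knob. The phenomena of interest — settling into local maxima,
treatment-block shifts, partial retention — live at the strategy level;
a trial-level learner is a documented extension point, not shipped.

Why this produces the qualitative pattern: Try search has by far the best
expected round payoff (≈70 at baseline) but a bimodal realization — with
probability 0.9¹² ≈ 0.28 a round yields twelve failed explorations and
−12 points — so learners updating from experienced payoffs often abandon
it for the steady ≈19 of Give-Up search or the ≈10–26 lottery of settling.
Each intervention then shifts the realized-payoff landscape exactly as
designed: punishing Give-Up collapses its propensity; rewarding any Try
choice makes settling on a +1 key pay ≈34 per round, inflating Try-low
exploitation; waiving exploration costs removes the −12 failure tail
(twelve free explorations yield +12), making Try search robustly
attractive without subsidizing settling.

## Synthetic cohort

The default `CohortDesign` is the study design the analysis pipeline
assumes: four between-subject conditions with 53, 55, 54, 54 participants,
each playing baseline/treatment/baseline blocks of 15 rounds × 12 trials —
116,640 trials in all. Every participant is an adaptive learner with
parameters drawn once from truncated normals: α ~ TN(0.25, 0.10) on
[0.02, 0.80], τ ~ TN(5, 2) on [1, 15], ρ ~ TN(0.5, 0.2) on [0.05, 0.95],
initial propensities (14, 10, 8) for (Give-Up search, settle, Try search).
The initial propensities start most participants on Give-Up search, as
observed early behavior warrants; the τ range keeps round-1 choice
stochastic; the α range spans sluggish to jumpy learners. These are
calibration knobs chosen so the cohort reproduces the qualitative
treatment-effect pattern, not estimates of human parameters. Per-seed
robustness of the pattern (Give-Up decline within block 1, Give-Up
reduction under every treatment, higher Try-low exploitation under
`plus_try` than `plus_try_explore`) was verified across independent master
seeds before freezing the defaults.

What the generator does *not* emulate: within-round sequential positions
of choices beyond what the meta-strategies imply, reaction times, key
layout effects, payment mechanics (a bonus-round sampling utility is
provided but never affects generation), and any quantitative match to
human effect sizes. Passing the cohort tests shows the pipeline detects
the designed qualitative effects in data with realistic structure — it
says nothing about human parameter values.

Reproducibility: the master seed feeds a `SeedSequence` that spawns one
independent stream per participant, so any participant can be regenerated
in isolation and identical (design, seed) pairs produce byte-identical
CSV logs.

## Metrics

`compute_rates` computes, per participant × block over the analysis window
(trials 1–9 of every round; the window is a parameter), the Give-Up rate,
Try-low exploitation rate, benchmark-consistency rate, and mean payoff per
trial. Rates use the windowed trial count as denominator — choices, not
opportunities. Labels are recomputed from any conforming log by replaying
the revealed state per round, so externally produced logs need only the
core columns.

`strip_incentives` recomputes each trial under baseline rules
(raw outcome − baseline cost on first presses). Because raw outcomes are
latent-value-determined and a fixed choice sequence reveals the same keys
in the same order under any scheme, this equals a literal baseline replay
of the same choices, exactly; the identity is tested on randomized rounds
of every scheme.

`difference_scores` forms per-participant treatment (block 2 − block 1)
and retention (block 3 − block 1) contrasts, with rates scaled to
percentage points, and reports per-condition means with 95% CIs. CIs are
normal-approximation (mean ± 1.96 SE) across participants by default — the
conventional choice for n ≥ 50 per condition — with a percentile bootstrap
behind a flag. `anova_oneway` is the plain between/within decomposition
(cross-checked against an independent implementation in the tests), with
the degenerate zero-within-variance case reported as an infinite F with a
warning, and groups of fewer than two participants refused.
`dv_correlation` computes per-condition Pearson r between two DVs across
participant-block rows and averages via Fisher z, with |r| clamped below
1 − 1e−12 so perfect correlations stay finite. Multivariate inference
(MANOVA) is deliberately not implemented: the pipeline emits the per-DV
difference table that any stats package can consume.

## Numerical and design notes

- All payoff arithmetic at the shipped parameters is exact in binary
  floating point (values are small integers and halves), which is why the
  stripping and round-trip identities are asserted with equality, not
  tolerances.
- Degenerate configurations: `low_value == high_value` makes levels
  indistinguishable from outcomes (level recovery reports high);
  single-trial rounds and p ∈ {0, 1} are exercised in tests.
- Problem sizes in the shipped checks — 50 random oracle instances,
  100,000 Monte-Carlo rounds, 1,000 stripping rounds, the full 216
  participant cohort — were chosen so each check resolves its question
  decisively (e.g. 3-SE bands at 100k rounds are ±0.5 points on a
  70-point value) while the whole suite stays interactive.

## Known limitations

- The learner's meta-strategy set is a superset of the behaviors the
  metrics distinguish, but it is still a discrete set of three; human
  strategy blends within a round are not representable.
- The benchmark family S_m never exploits known low Try keys before the
  switch; the unrestricted DP shows this costs at most ~0.22 points at the
  shipped parameters (69.91 − 69.69).
- `plus_try_explore`'s cost waiver is Try-scoped by design (see above);
  a variant waiving both matrices can be expressed as a custom scheme in
  the config's scheme table if wanted.
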