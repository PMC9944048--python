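# Methods

## Model

Each fish is modeled as an ε-greedy learner on a k = 4 armed bandit with a
single rewarding arm and binary payoff. Per trial the agent explores a
uniformly random arm (including the current greedy arm) with probability ε,
otherwise exploits an arm maximizing the action value Q. Q is the running
sample mean of each arm's rewards, maintained incrementally as
Q(A) ← Q(A) + [R − Q(A)]/N(A) with the visit count N(A) incremented before
the update, so a first visit sets Q = R. Action values and visit counts are
zero-initialized (no optimistic initialization).

The biological mapping is: ε = the fish's basal whole-body cortisol after
min-max normalization over the valid cohort, so the cohort's least-stressed
fish plays ε = 0 (pure exploitation) and its most-stressed plays ε = 1
(pure exploration). This mapping is the modeling assumption under study, not
a fitted quantity.

Conventions chosen where the behavior was underdetermined:

- **Greedy tie-breaking** defaults to the lowest-index maximal arm. With
  zero-initialized Q this is the only convention consistent with the
  reference group-level simulation means (it gives an expected average
  reward ≈ 0.30 at ε = 0.0289, versus ≈ 0.86 under uniform-random
  tie-breaking). Uniform-random tie-breaking remains available everywhere as
  a configuration option.
- **The rewarding arm is drawn uniformly once per episode** and held fixed
  for its trials. A per-trial redraw would make every policy score 1/k in
  expectation, erasing the ε-dependence the group tables clearly show. (The
  live maze re-randomized the baited arm per trial but kept a visual cue on
  it; the fixed-arm bandit stands in for "the thing to be learned".)
- **Exploration does not exclude the greedy arm** (standard ε-greedy).
- Arms are labeled 1..k in all public interfaces.

## Exact oracle

With binary rewards on a single arm, every non-rewarding arm keeps Q = 0
forever and the rewarding arm holds Q = 1 from its first visit on. An
episode therefore occupies one of two regimes — rewarding arm undiscovered
(all Q tied at 0, greedy falls back to the tie-break rule) or discovered
(rewarding arm is the unique maximizer) — each with a constant per-trial
success probability: p_d = (1 − ε) + ε/k once discovered, and before
discovery either ε/k, (1 − ε) + ε/k, or 1/k depending on the tie-break and
on whether the rewarding arm is the tie-break's default. Forward dynamic
programming over this two-state chain (`forage_bandit.oracle`) yields exact
per-trial success probabilities and expected average rewards; a uniform
reward-arm draw is the k-component mixture. Closed-form checks: ε = 1 gives
exactly 1/4 per trial; ε = 0 with first-index ties gives exactly 1/4
(success iff the drawn arm is arm 1); ε = 0 with uniform-random ties gives
1 − (3/T)(1 − 0.75^T) at T trials. The Monte Carlo simulator is required, in
tests, to agree with the oracle within 3 Monte Carlo standard errors; the
oracle supports only the binary single-arm payoff and rejects anything else.

At the five reference group ε values (0.0289, 0.1413, 0.4103, 0.8137,
0.9251) the oracle's T = 21 expectations are (0.3003, 0.4338, 0.5081,
0.3573, 0.2947): an inverted U peaking at group 3. At T = 400 the peak moves
to group 2 — the long-run advantage of exploiters.

## Cohort pipeline

Input is one CSV row per fish: id, cortisol (ng/mL, possibly empty),
a validity flag (`valid` / `assay_failed` / `outlier`), and 21 binary trial
outcomes. Flags are taken as given — no outlier detection is performed,
since the original exclusion criterion is not recoverable. Processing order:
drop non-valid records (error if fewer than two remain), min-max normalize
cortisol over the valid subset only, then label groups by ascending
normalized cortisol in contiguous blocks whose sizes default to
(16, 17, 16, 16, 17). The sort is stable, so a tie at a block boundary is
resolved by input row order. Group summaries report mean ± SE with
SE = sd(n−1 denominator)/√n throughout; a singleton group's SE is reported
as missing rather than zero. Spreadsheet (ODS) input is not supported; the
CSV schema is the interface.

## Synthetic cohorts

The generator emulates the reference study design: 82 valid fish in five
groups spanning the measured per-group cortisol ranges (1.68–10.69,
12.78–28.55, 32.18–87.35, 90.50–117.33, 117.44–135.40 ng/mL), plus 3
failed-assay records (missing cortisol) and 1 outlier, 21 trials each.
Within a group, cortisol is sampled **uniformly** over the group's range —
the least-informative choice consistent with knowing only ranges; group
means of normalized cortisol therefore approximate rather than equal the
reference means, and checks that need the exact means use them directly.
Outcomes come from the bandit model itself (each fish one episode at its
own normalized cortisol), or from i.i.d. Bernoulli draws at stated per-group
rates as a structureless control. Flagged fish also complete trials (with an
arbitrary ε), as real excluded fish did; their outcomes never reach the
analysis. Record order is shuffled so group membership is not encoded in row
position. What the generator does **not** emulate: the cortisol
distribution's within-group shape, any trial-to-trial nonstationarity in
fish behavior, within-fish correlation beyond the bandit's learning
dynamics, and body-size covariates. Tests passing on synthetic cohorts
validate the pipeline's bookkeeping and the model's internal consistency,
not the biological claim.

## Simulation and comparison

`simulate_cohort` runs one episode per (agent, replicate), redrawing the
rewarding arm per episode. Randomness flows from a single integer seed via
`numpy.random.SeedSequence`, one spawned child stream per agent, making runs
bit-reproducible and independent of execution order. Replicates default to 1
— one digital twin per fish, the reference design — but large-replicate runs
are first-class and used wherever an expectation, rather than a draw, is the
target: the headline recomputation uses 20 000 agents per group (Monte Carlo
SE ≈ 0.003, negligible against the published SEs of 0.027–0.103) and the
parameter-recovery check averages 20 replicates per fish. At one episode per
fish, single-episode noise dominates group rankings: the interior group
attains the top mean average reward in only about two-thirds of synthetic
cohorts, whereas with replicate-averaged simulation it essentially always
does — an instability worth remembering when reading 16-fish group means.

Fish-vs-simulation agreement is the Pearson product-moment correlation over
the five group mean average rewards, over all groups and with each group
left out in turn (computing it on the published group means reproduces the
reference values 0.62 and 0.81 with group 4 excluded, insensitive to whether
the printed 4-decimal means or unrounded values are used). Correlations are
displayed rounded half-up to 2 decimals. With only five group pairs no
significance test is attached. A zero-reward census (individuals whose 21
trials earned nothing, per group) accompanies the comparison, since a
cluster of such fish in one group is what drove the largest fish-model
discrepancy in the reference data.

## Numerical and testing choices

- Stochastic tests fix their seeds and use 3-standard-error bands when five
  group-level comparisons are asserted simultaneously (a 2-SE band per
  group would fail by chance in roughly one run in four).
- Monte Carlo vs oracle agreement is always stated in Monte Carlo SEs
  estimated from the sample itself.
- Trial counts: comparisons with the fish use T = 21; long-horizon behavior
  uses T = 400, both via the exact oracle where possible. Problem sizes in
  the test suite (≥ 5000 agents per group for group means, 10^4 episodes per
  ε for oracle agreement, 20 seeds for parameter recovery) were chosen so
  that Monte Carlo error is small against every tolerance asserted.
- Degenerate inputs fail loudly with typed errors: constant cortisol
  (normalization undefined), < 2 valid fish, non-binary outcomes, group-size
  vectors that do not sum to the cohort, correlations on < 3 points or
  zero-variance vectors.

## Limitations

- The ε = normalized-cortisol mapping is an assumption carried over from the
  study design; the package quantifies its consequences, it does not test it
  against alternatives (no model comparison, no fitting of ε).
- The bandit is stationary within an episode; habituation, satiation, or
  cue learning across the 11 experimental days are out of scope.
- Group-level Pearson r over five points is descriptive only.
- The measured fish column (group means and SEs) is data, not something the
  package can recompute; it ships as a built-in fixture for comparisons.
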