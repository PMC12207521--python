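# Methods

`egtlab` studies how the *choice of strategy space* changes what
evolutionary game dynamics predict about cooperation.  Three case
studies share one dynamics layer; each case study contrasts a small,
hand-picked strategy set with a systematically constructed one.

## Dynamics layer

**Replicator dynamics.**  For strategy frequencies `x` and a pairwise
payoff matrix `A`, the deterministic dynamics is
`dx_i/dt = x_i ((Ax)_i − xᵀAx)`.  Integration is fixed-step classical
Runge–Kutta (default `dt = 0.01`) with renormalization onto the simplex
after every step; we prefer a fixed step over adaptive stepping so that
trajectories are bit-reproducible across platforms.  Non-finite states
abort with a diagnostic rather than being silently clipped.

**Imitation process.**  A population of `N` individuals evolves by
elementary updates: a uniformly random focal individual either adopts a
uniformly random strategy from the full configured set (probability
`mu`, the exploration rate) or imitates a role model drawn from the
other `N − 1` individuals with probability proportional to fitness
`exp(beta_sel · payoff)`.  Payoffs exclude self-interaction (divide by
`N − 1`), which keeps `N = 2` well defined.  Because imitation
probabilities depend only on payoff differences, a common offset (the
maximum available payoff) is subtracted before exponentiating — an
exact transformation, so arbitrarily strong selection cannot overflow.
Long-run output is the *time average* of abundances and of the
cooperation index after a burn-in, matching the notion of average
long-term cooperation rather than the modal state.

**Fixation and the small-mutation limit.**  The fixation probability of
a single mutant uses the standard product formula with transition-ratio
`exp(−beta (π_mut(j) − π_res(j)))`, evaluated in log space
(`logsumexp`), and reduces exactly to `1/N` at `beta = 0`.  In the
rare-exploration regime the population is almost always monomorphic, so
the long run reduces to an `m × m` embedded Markov chain over
monomorphic states with off-diagonal entries `ρ(invader ← resident)/(m−1)`;
its stationary distribution is the left null vector of the transition
matrix.  The product formula corresponds to a Moran-style birth–death
chain whose role model is drawn fitness-proportionally from the whole
population; the imitation micro-step excludes the focal individual,
an `O(1/N)` difference in transition probabilities.  The test suite
compares the two routes statistically (3 standard errors over
replicates) rather than pretending they are identical.

Both simulation kernels (matrix-game imitation, reputation dynamics)
are compiled with numba and seeded explicitly; identical seeds give
bit-identical reports.  Pure-Python reference implementations of the
micro-steps (`imitation_step`, `interaction_round`) define the
semantics and are cross-checked against the kernels in the tests.

## Case study 1: repeated prisoner's dilemma

One-shot payoffs `(R, S, T, P) = (3, 0, 4, 1)` with continuation
probability `delta`; payoffs of the repeated game are normalized by
`(1 − delta)`.  Deterministic reactive strategies (first move, reply to
opponent's C, reply to opponent's D) make joint play eventually periodic
over at most four joint states, so discounted payoffs and discounted
cooperation rates are evaluated *in closed form* from the prefix/cycle
decomposition — no truncation error.  The three spaces compared are
`pair` = {AllC, AllD}, `triple` = {AllC, TFT, AllD} and `full8` = all
2³ reactive strategies.  The cooperation index of a population state is
the expected discounted cooperation rate of a random individual against
a random opponent (self excluded); small-mutation reports weight each
strategy by its self-play rate, since that limit spends almost all time
monomorphic.  We use the discounted (not Cesàro) cooperation fraction
so the cooperation measure matches the payoff normalization.

An optional per-strategy *complexity cost* is subtracted from the
bearer's payoff in every interaction — the simplest reading of a
bookkeeping cost for conditional strategies — and supports the
weak-selection variant in which costly reciprocity cycles with
unconditional cooperation and defection.

## Case study 2: optional public goods game with punishment

Groups of `n = 5` are drawn without replacement from a population of
`N = 100`.  Participation classes are cooperate (contribute `c = 1`),
defect, or abstain (loner payoff `sigma = 1`); the pot is multiplied by
`r = 3` and divided among the `S` participants (the `others_only`
sharing rule, where each contribution is divided among the other
participants, is available via config).  If `S ≤ 1` the game is
cancelled and everyone receives `sigma`; punishment then does not occur
either, since nothing was observable.  Otherwise a punishment stage
runs over all group members: a strategy's three punishment bits target
participation classes; each punisher pays `cost_pun = 1` per target and
each target loses `fine = 1` per punisher, self excluded, own class
included.  In the unrestricted 24-strategy space loners present in a
group may punish and be punished.

Expected payoffs in a two-strategy population are exact hypergeometric
expectations over the focal player's `n − 1` co-players, which makes the
small-mutation chain at `N = 100`, `beta = 1` deterministic (no
sampling).  Monte-Carlo group sampling backs the mixed-composition
payoffs used by direct simulation and is cross-checked against the
exact expectation in the tests.

## Case study 3: indirect reciprocity

A donation game (`benefit = 5`, `cost = 1`) among `N = 50` agents with
binary reputations.  Each agent holds a *private* opinion (G/B) of
every agent — including a self-image on the matrix diagonal — and a
strategy combining one of 4 action rules (ALLC, DISC, antiDISC, ALLD,
acting on the agent's own opinion of the recipient) with one of 16
second-order social norms mapping (donor action, observer's opinion of
the recipient) to a reputation.  After every interaction each agent,
the donor's self-assessment included, updates its opinion of the donor
through its own norm.  The donor's self-assessment matters: without it
the recipient would judge donors against a frozen self-image and
same-norm observers would permanently disagree even without noise.

Two error processes: an intended cooperation fails with probability
`exec_error = 0.01` (and is observed as defection), and an interaction
is misperceived with probability `assess_error = 0.01`.  The perception
error is a *synchronized* draw — one per interaction, shared by all
observers — so observers applying the same norm to the same information
never diverge by noise alone, recovering the public-information
behaviour for monomorphic norms.  With independent per-observer errors,
stern judging is known to desynchronize private opinions and cooperation
collapses for reasons unrelated to the strategy-space question this
package studies; the synchronized choice isolates that question.  These
parameter values, and `rounds_per_gen = 100·N` donation interactions
per payoff evaluation, are package defaults chosen once as conventional
values for this literature.

Payoffs are accumulated per agent and divided by the expected number of
game participations (`2·rounds/N`), so the fitness scale is the
per-game surplus regardless of horizon.

Two long-run routes are exposed:

* `evolve` — direct simulation: payoff-evaluation epochs followed by
  `N` imitation micro-steps (one revision opportunity per individual);
  the opinion matrix persists across epochs and an agent that switches
  strategy resets its own opinions to G while others' opinions of it
  are retained.
* `evolve_small_mu` — the embedded small-mutation chain, with invasion
  payoff profiles `π(j)` for `j = 1..N−1` estimated from short
  simulations of the two-strategy mixtures.  Profiles are cached under
  keys that drop payoff-irrelevant norms — an agent's norm affects
  payoffs only if its action rule discriminates — which cuts the
  64-strategy space to ~1.1k distinct profiles and makes the chain
  tractable.  ALLD/ALLC norm variants get *exactly* equal payoff
  profiles, so their neutrality is structural, not statistical.

The figure-style comparison (exogenous stern judging, 4 strategies, vs
endogenous norms, 64 strategies) uses the small-mutation route: under
stern judging, discriminators and defectors form a strongly bistable
pair at `beta = 1`, so a direct imitation chain effectively never
leaves the state it first reaches at any feasible horizon, whereas the
embedded chain computes the stationary average the comparison is about.
Replicate seeds give independent payoff-profile estimates and hence a
standard error for the comparison.

## Problem sizes and numerical choices

Defaults were chosen once as study conditions: repeated-PD imitation
runs use `N = 20`, `beta = 1`, `mu = 1e−3` with 1–2 million updates
after a 10% burn-in; the PGG chain uses the exact expectations at
`N = 100`; indirect-reciprocity profile estimates use 3000 measured
interactions after 500 burn-in interactions per mixture, with 10
replicate seeds for stochastic comparisons in the tests and 3 in the
acceptance script.  Ties in the pure-equilibrium check are admitted at
tolerance `1e−12` (weak inequality).  The embedded-chain solve clips
negative round-off to zero before renormalizing.

## Known limitations

* Deterministic reactive strategies only; stochastic or longer-memory
  repeated-game strategies are out of scope.
* The payoff-irrelevance caching in `IRSimOracle` is specific to
  rules whose actions ignore opinions; richer action rules would need
  a different cache key.
* Direct imitation simulation of the indirect-reciprocity case is
  faithful but slow-mixing at strong selection (see above); its tests
  therefore check invariants (determinism, simplex, coupling), not
  stationary averages.
* The synthetic fixture games are generic 2–4 strategy matrices; they
  exercise the dynamics engine, not any particular biological payoff
  structure.
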