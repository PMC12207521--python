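# egtlab

Evolutionary game dynamics over *systematically constructed* strategy
spaces, for researchers studying the evolution of cooperation.

In evolutionary game theory the modeller usually hand-picks a few
strategies, and with noise and multiple equilibria that choice can
drive the outcome: a small, biased strategy set can overstate how easily
cooperation evolves.  `egtlab` makes the strategy space itself the
experimental variable.  It ships three classic case studies, each
contrasting a hand-picked set with the full computationally equivalent
space:

1. **Repeated prisoner's dilemma** — one-shot payoffs `(R,S,T,P)` with
   continuation probability `δ`; normalized discounted payoffs
   `(1−δ) Σ_i δ^i π_i` for reactive strategies, computed in closed form.
   Sets: `{AllC, AllD}`, `{AllC, TFT, AllD}`, and all 2³ = 8 reactive
   strategies.
2. **Optional public goods game with punishment** — participation class
   (cooperate / defect / loner with assured payoff `σ`,
   `0 < σ < (r−1)c`) crossed with punishment bits per target class:
   24 strategies, with the 4-, 9- and 12-strategy microeconomic
   restrictions.  Exact hypergeometric group-sampling payoffs.
3. **Indirect reciprocity** — donation game with binary private
   reputations; 4 action rules × 16 second-order social norms.
   Exogenous (everyone judges by stern judging; 4 strategies) vs
   endogenous norms (64 strategies).

A shared dynamics layer drives all three: replicator ODE
`ẋ_i = x_i((Ax)_i − xᵀAx)`, a finite-population imitation process with
exponential payoff-to-fitness mapping `f = exp(βπ)` and exploration
rate `μ`, fixation probabilities
`ρ = 1/(1 + Σ_k Π_j exp(−β(π_A(j)−π_B(j))))`, and the small-mutation
embedded Markov chain over monomorphic states.

## Worked example

```python
import egtlab as eg

params = eg.PDParams(R=3, S=0, T=4, P=1, delta=0.9)
for label in ("triple", "full8"):
    game = eg.payoff_matrix(eg.named_sets()[label], params)
    rep = eg.run_imitation(
        game.to_oracle(),
        eg.EvoParams(N=20, beta_sel=1.0, mu=1e-3,
                     steps=2_000_000, burn_in=200_000, seed=1),
    )
    print(label, round(rep.cooperation_index, 3))
```

prints

```
triple 0.719
full8 0.605
```

the long-run fraction of (discount-weighted) cooperative play under the
imitation process: with only `{AllC, TFT, AllD}` available, 72% of play
is cooperative, but opening the full 8-strategy reactive space drops
this to 60% — the three-strategy model overestimates cooperation.  The
same one-liner pattern runs the other case studies
(`eg.PGGOracle` + `eg.small_mu_stationary`, and
`egtlab.indirect_recip.evolve_small_mu`).

Command line:

```bash
egtlab repeated-pd --set full8 --delta 0.9 --N 20 --out results/pd
egtlab pgg --restriction full24 --dynamics smallmu --N 100 --out results/pgg
egtlab indirect --space endogenous --out results/ir
```

Each command writes `<prefix>.csv` (per-strategy long-run abundances)
and `<prefix>.json` (parameters, seed, cooperation index).  YAML sweep
configs (`egtlab run config.yml --out results/sweep`) produce tidy
replicate tables over `δ`, `N` or group-size grids.

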