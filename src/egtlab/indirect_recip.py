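"""Indirect reciprocity with binary reputations and private assessment.

Agents play a donation game: a donor may pay ``cost`` to give the
recipient ``benefit``.  The donor's decision is an action rule mapping
the donor's *own* opinion of the recipient (good G or bad B) to C or D —
four rules: ALLC, DISC (cooperate with the good), antiDISC, ALLD.  After
each interaction every other agent updates its private opinion of the
donor through its social norm, a second-order map
(donor action, observer's opinion of the recipient) -> reputation; there
are 2^4 = 16 such norms.

Two strategy spaces are compared: *exogenous* — everyone shares one
fixed norm (stern judging by default) and only the 4 action rules
evolve — and *endogenous* — the norm is part of the strategy, giving
4 x 16 = 64 strategies.  Opinions are private (one opinion matrix entry
per ordered agent pair), which makes norms of unconditional players
(ALLC/ALLD) payoff-irrelevant: neutral drift among their norms is exact,
not approximate.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import ir_evolve_kernel, ir_payoff_kernel
from .dynamics import EvoParams, PayoffOracle, StationaryReport, small_mu_stationary

__all__ = [
    "IRParams",
    "ActionRule",
    "SocialNorm",
    "NormStrategy",
    "ACTION_RULES",
    "stern_judging",
    "exogenous_space",
    "endogenous_space",
    "IRState",
    "interaction_round",
    "estimate_payoffs",
    "IRSimOracle",
    "evolve",
    "evolve_small_mu",
]

G, B = "G", "B"


@dataclass(frozen=True)
class IRParams:
    """Donation-game and reputation parameters.

    ``assess_error``: probability that an interaction is misperceived;
    the perception error is synchronized — one draw per interaction,
    shared by all observers — so observers applying the same norm to the
    same information never diverge by noise alone.  ``exec_error``:
    probability an intended cooperation fails and is executed (and
    observed) as defection.
    ``rounds_per_gen``: donation interactions per payoff evaluation
    (default 100 * N).
    """

    benefit: float = 5.0
    cost: float = 1.0
    N: int = 50
    rounds_per_gen: int | None = None
    assess_error: float = 0.01
    exec_error: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.benefit > self.cost > 0:
            raise ValueError("need benefit > cost > 0")
        for e in (self.assess_error, self.exec_error):
            if not 0.0 <= e < 0.5:
                raise ValueError("error probabilities must lie in [0, 0.5)")
        if self.N < 2:
            raise ValueError("N must be >= 2")

    @property
    def rounds(self) -> int:
        return 100 * self.N if self.rounds_per_gen is None else self.rounds_per_gen


@dataclass(frozen=True)
class ActionRule:
    act_on_G: str
    act_on_B: str

    def act(self, opinion: str) -> str:
        return self.act_on_G if opinion == G else self.act_on_B

    @property
    def label(self) -> str:
        return {
            ("C", "C"): "ALLC",
            ("C", "D"): "DISC",
            ("D", "C"): "antiDISC",
            ("D", "D"): "ALLD",
        }[(self.act_on_G, self.act_on_B)]


ACTION_RULES = [
    ActionRule("C", "C"),
    ActionRule("C", "D"),
    ActionRule("D", "C"),
    ActionRule("D", "D"),
]


@dataclass(frozen=True)
class SocialNorm:
    """Second-order norm: (donor action, opinion of recipient) -> reputation.

    ``index`` encodes the truth table as 4 bits (G=1) in the entry order
    (C,G), (C,B), (D,G), (D,B), most significant first.
    """

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < 16:
            raise ValueError("norm index must lie in 0..15")

    def assess(self, action: str, recipient_rep: str) -> str:
        pos = {("C", G): 3, ("C", B): 2, ("D", G): 1, ("D", B): 0}[
            (action, recipient_rep)
        ]
        return G if (self.index >> pos) & 1 else B

    @property
    def table(self) -> dict[tuple[str, str], str]:
        return {
            (a, rep): self.assess(a, rep)
            for a in ("C", "D")
            for rep in (G, B)
        }

    @property
    def label(self) -> str:
        named = {stern_judging().index: "SternJudging"}
        return named.get(self.index, f"norm{self.index:02d}")


def stern_judging() -> SocialNorm:
    """The norm that approves cooperating with the good and defecting
    against the bad, and condemns the opposite: (C,G)->G, (D,G)->B,
    (C,B)->B, (D,B)->G."""
    # bits: (C,G)=1, (C,B)=0, (D,G)=0, (D,B)=1
    return SocialNorm(0b1001)


@dataclass(frozen=True)
class NormStrategy:
    rule: ActionRule
    norm: SocialNorm

    @property
    def label(self) -> str:
        return f"{self.rule.label}|{self.norm.label}"


def exogenous_space(norm: SocialNorm | None = None) -> list[NormStrategy]:
    """The 4 action rules, all carrying one fixed social norm."""
    norm = stern_judging() if norm is None else norm
    return [NormStrategy(r, norm) for r in ACTION_RULES]


def endogenous_space() -> list[NormStrategy]:
    """All 4 x 16 = 64 combinations of action rule and social norm."""
    return [
        NormStrategy(r, SocialNorm(i)) for r in ACTION_RULES for i in range(16)
    ]


# ---------------------------------------------------------------------------
# reference (pure-Python) protocol
# ---------------------------------------------------------------------------

@dataclass
class IRState:
    """Agents plus the private opinion matrix (G/B per ordered pair).

    The diagonal holds each agent's self-image, updated by its own norm
    whenever it donates; this keeps same-norm observers unanimous in the
    error-free limit (the recipient assesses the donor against its own
    standing the way everyone else assesses it against theirs)."""

    strategies: list[NormStrategy]
    opinions: np.ndarray = field(default=None)  # type: ignore[assignment]
    payoffs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.strategies)
        if self.opinions is None:
            self.opinions = np.full((n, n), G, dtype="<U1")
        if self.payoffs is None:
            self.payoffs = np.zeros(n)


def interaction_round(
    state: IRState, params: IRParams, rng: np.random.Generator
) -> str:
    """One donation interaction, updating opinions and payoffs in place.

    Draw order (donor, recipient, execution error, one synchronized
    assessment draw) is fixed and independent of opinion values, so runs
    differing only in payoff-irrelevant norms stay coupled.  Every agent
    — the donor's self-assessment included — updates its opinion of the
    donor.  Returns the realized action.
    """
    n = len(state.strategies)
    donor = int(rng.integers(n))
    recipient = int(rng.integers(n - 1))
    if recipient >= donor:
        recipient += 1
    action = state.strategies[donor].rule.act(state.opinions[donor, recipient])
    if action == "C" and rng.random() < params.exec_error:
        action = "D"
    if action == "C":
        state.payoffs[donor] -= params.cost
        state.payoffs[recipient] += params.benefit
    flip = rng.random() < params.assess_error
    for k in range(n):
        rep = state.strategies[k].norm.assess(action, state.opinions[k, recipient])
        if flip:
            rep = B if rep == G else G
        state.opinions[k, donor] = rep
    return action


# ---------------------------------------------------------------------------
# compiled simulation wrappers
# ---------------------------------------------------------------------------

_ACT_TAB = np.array(
    [[1 if r.act_on_B == "C" else 0, 1 if r.act_on_G == "C" else 0] for r in ACTION_RULES],
    dtype=np.int8,
)  # act_tab[rule, opinion(0=B,1=G)] -> 1 if cooperate


def _norm_tab() -> np.ndarray:
    tab = np.empty((16, 2, 2), dtype=np.int8)  # [norm, action(0=D,1=C), rep(0=B,1=G)]
    for i in range(16):
        norm = SocialNorm(i)
        for a_idx, a in ((0, "D"), (1, "C")):
            for r_idx, rep in ((0, B), (1, G)):
                tab[i, a_idx, r_idx] = 1 if norm.assess(a, rep) == G else 0
    return tab


_NORM_TAB = _norm_tab()


def _encode(population: Sequence[NormStrategy]):
    rule_idx = {r: i for i, r in enumerate(ACTION_RULES)}
    rules = np.array([rule_idx[s.rule] for s in population], dtype=np.int64)
    norms = np.array([s.norm.index for s in population], dtype=np.int64)
    return rules, norms


def _kernel_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF)


def estimate_payoffs(
    population: Sequence[NormStrategy],
    params: IRParams,
    seed: int | None = None,
    burn_rounds: int | None = None,
    return_actions: bool = False,
):
    """Per-agent mean payoff (per game participation) and realized
    cooperation rate for a fixed population.

    Opinions start all-G and equilibrate for ``burn_rounds`` (default
    10 * N) interactions before measurement over ``params.rounds``
    interactions.
    """
    rules, norms = _encode(population)
    if len(population) != params.N:
        raise ValueError("population size must equal params.N")
    if burn_rounds is None:
        burn_rounds = 10 * params.N
    pay, coop, actions = ir_payoff_kernel(
        _ACT_TAB,
        _NORM_TAB,
        rules,
        norms,
        float(params.benefit),
        float(params.cost),
        float(params.assess_error),
        float(params.exec_error),
        np.int64(burn_rounds),
        np.int64(params.rounds),
        np.int64(_kernel_seed(params.seed if seed is None else seed)),
    )
    if return_actions:
        return pay, float(coop), actions
    return pay, float(coop)


class IRSimOracle(PayoffOracle):
    """Payoff oracle for reputation strategies, estimated by simulation.

    Invasion payoff profiles pi_mutant(j), pi_resident(j) for j = 1..N-1
    are measured from short donation-game simulations of the two-type
    population at every mixture.  Payoffs depend on an agent's norm only
    if its action rule discriminates (DISC/antiDISC) — the opinions an
    ALLC or ALLD agent forms never feed a decision — so profiles are
    cached under keys that drop payoff-irrelevant norms, which makes the
    64-strategy space tractable.
    """

    def __init__(
        self,
        strategies: Sequence[NormStrategy],
        params: IRParams,
        rounds: int = 3000,
        burn_rounds: int = 500,
        seed: int = 0,
    ):
        self.strategies = list(strategies)
        self.strategy_labels = [s.label for s in self.strategies]
        self.params = params
        self.rounds = rounds
        self.burn_rounds = burn_rounds
        self.seed = seed
        self._profiles: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
        self._coop: np.ndarray | None = None

    @staticmethod
    def _key_part(s: NormStrategy) -> tuple:
        discriminating = s.rule.act_on_G != s.rule.act_on_B
        return (s.rule.act_on_G, s.rule.act_on_B,
                s.norm.index if discriminating else -1)

    def _simulate_pair(self, a: NormStrategy, b: NormStrategy):
        """pi_a(j), pi_b(j) for j = 1..N-1 copies of a."""
        N = self.params.N
        key = (self._key_part(a), self._key_part(b))
        if key in self._profiles:
            return self._profiles[key]
        rev = (key[1], key[0])
        if rev in self._profiles:
            pb, pa = self._profiles[rev]
            prof = (pa[::-1].copy(), pb[::-1].copy())
            self._profiles[key] = prof
            return prof
        pi_a = np.empty(N - 1)
        pi_b = np.empty(N - 1)
        base = np.random.SeedSequence([self.seed, zlib.crc32(repr(key).encode())])
        seeds = base.generate_state(N - 1)
        for idx, j in enumerate(range(1, N)):
            pop = [a] * j + [b] * (N - j)
            pay, _ = estimate_payoffs(
                pop,
                dataclasses.replace(self.params, rounds_per_gen=self.rounds),
                seed=int(seeds[idx] & 0x7FFFFFFF),
                burn_rounds=self.burn_rounds,
            )
            pi_a[idx] = pay[:j].mean()
            pi_b[idx] = pay[j:].mean()
        self._profiles[key] = (pi_a, pi_b)
        return self._profiles[key]

    def invasion_payoffs(self, mutant: int, resident: int, N: int):
        if N != self.params.N:
            raise ValueError(f"oracle built for N={self.params.N}")
        return self._simulate_pair(self.strategies[mutant], self.strategies[resident])

    def monomorphic_coop(self) -> np.ndarray:
        """Realized cooperation rate of each monomorphic population,
        cached by the same payoff-relevance key."""
        if self._coop is None:
            cache: dict[tuple, float] = {}
            out = np.empty(len(self.strategies))
            base = np.random.SeedSequence([self.seed, 2**20])
            seeds = base.generate_state(len(self.strategies))
            for i, s in enumerate(self.strategies):
                key = self._key_part(s)
                if key not in cache:
                    pop = [s] * self.params.N
                    _, coop = estimate_payoffs(
                        pop,
                        dataclasses.replace(self.params, rounds_per_gen=self.rounds),
                        seed=int(seeds[i] & 0x7FFFFFFF),
                        burn_rounds=self.burn_rounds,
                    )
                    cache[key] = coop
                out[i] = cache[key]
            self._coop = out
        return self._coop

    def state_payoffs(self, counts: np.ndarray, rng=None) -> np.ndarray:
        raise NotImplementedError(
            "use evolve() for direct simulation of reputation dynamics"
        )


def evolve_small_mu(
    space: str | Sequence[NormStrategy],
    params: IRParams,
    beta_sel: float = 1.0,
    seed: int = 0,
    rounds: int = 3000,
) -> StationaryReport:
    """Small-mutation-limit stationary distribution over monomorphic
    reputation-strategy states, with invasion payoffs estimated by
    simulation.  The cooperation index weights each strategy by the
    realized cooperation rate of its monomorphic population."""
    if isinstance(space, str):
        strategies = {"exogenous": exogenous_space(),
                      "endogenous": endogenous_space()}.get(space)
        if strategies is None:
            raise ValueError(
                f"unknown space {space!r}; valid: 'exogenous', 'endogenous'"
            )
    else:
        strategies = list(space)
    oracle = IRSimOracle(strategies, params, rounds=rounds, seed=seed)
    report = small_mu_stationary(
        oracle, params.N, beta_sel, coop=oracle.monomorphic_coop()
    )
    report.metadata.update({"ir_params": params, "seed": seed, "rounds": rounds})
    return report


def evolve(
    space: str | Sequence[NormStrategy],
    params: IRParams,
    evo: EvoParams,
    updates_per_generation: int | None = None,
) -> StationaryReport:
    """Imitation dynamics over a reputation-strategy space.

    ``space`` is ``"exogenous"`` (4 action rules, stern judging fixed),
    ``"endogenous"`` (64 rule-norm combinations), or an explicit strategy
    list.  ``evo.steps``/``evo.burn_in`` count payoff-evaluation epochs
    (generations); each epoch runs ``params.rounds`` donation
    interactions and then ``updates_per_generation`` imitation
    micro-steps (default N: one revision opportunity per individual).
    The cooperation index is the long-run mean realized-cooperation rate.
    """
    if isinstance(space, str):
        if space == "exogenous":
            strategies = exogenous_space()
        elif space == "endogenous":
            strategies = endogenous_space()
        else:
            raise ValueError(
                f"unknown space {space!r}; valid: 'exogenous', 'endogenous'"
            )
    else:
        strategies = list(space)
    if evo.N != params.N:
        raise ValueError("evo.N must equal params.N")
    space_rule, space_norm = _encode(strategies)
    upg = params.N if updates_per_generation is None else updates_per_generation
    abund, coop = ir_evolve_kernel(
        _ACT_TAB,
        _NORM_TAB,
        space_rule,
        space_norm,
        np.int64(params.N),
        float(params.benefit),
        float(params.cost),
        float(params.assess_error),
        float(params.exec_error),
        float(evo.beta_sel),
        float(evo.mu),
        np.int64(params.rounds),
        np.int64(upg),
        np.int64(evo.steps),
        np.int64(evo.burn_in),
        np.int64(_kernel_seed(evo.seed)),
    )
    return StationaryReport(
        strategy_labels=[s.label for s in strategies],
        abundances=abund,
        cooperation_index=float(np.clip(coop, 0.0, 1.0)),
        method="simulation",
        metadata={"ir_params": params, "evo_params": evo,
                  "updates_per_generation": upg},
    )
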