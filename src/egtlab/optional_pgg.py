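"""Optional public goods game with peer punishment.

Strategies are a participation class — cooperate (C), defect (D), or
abstain as a loner (L) — combined with three punishment bits saying
whether the strategy punishes members of class C, D, or L after the
contribution stage.  The full space has 3 * 2^3 = 24 strategies;
microeconomic restrictions give the classic 4-strategy set (only
cooperators punish, only defectors are punished), the 9-strategy set
(loners neither punish nor are punished), and a 12-strategy set (loners
may punish but cannot be punished).

Group payoffs: with fewer than two participants the game is not played
and every group member receives the loner payoff sigma.  Otherwise the
pot r*c*n_C is divided among the S participants (default; an
``others_only`` sharing rule divides each contribution among the other
participants), contributors pay c, loners take sigma, and the punishment
stage runs: each member with the punish_X bit pays cost_pun per group
member of class X (self excluded), and each target loses fine per
punisher.

Expected payoffs in a two-strategy population are exact hypergeometric
expectations over the composition of the focal player's n-1 co-players.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .dynamics import PayoffOracle

__all__ = [
    "PGGParams",
    "PGGStrategy",
    "full_space",
    "strategy_space",
    "group_payoffs",
    "expected_payoffs_two_types",
    "coop_fraction",
    "PGGOracle",
]

_CLASSES = "CDL"


@dataclass(frozen=True)
class PGGParams:
    """Parameters of the optional public goods game with punishment.

    ``fine`` is the amount each punished individual loses per punisher;
    ``cost_pun`` is what a punisher pays per target.  ``sharing`` selects
    how the multiplied pot is divided: among the S participants
    (``participants``, default) or, per contribution, among the other
    participants only (``others_only``).
    """

    r: float = 3.0
    c: float = 1.0
    sigma: float = 1.0
    fine: float = 1.0
    cost_pun: float = 1.0
    n: int = 5
    N: int = 100
    sharing: str = "participants"

    def __post_init__(self) -> None:
        if self.sharing not in ("participants", "others_only"):
            raise ValueError("sharing must be 'participants' or 'others_only'")
        if not 2 <= self.n <= self.N:
            raise ValueError(f"need 2 <= n <= N, got n={self.n}, N={self.N}")
        if not 0 < self.sigma < (self.r - 1) * self.c:
            warnings.warn(
                f"loner payoff outside 0 < sigma < (r-1)c: sigma={self.sigma}, "
                f"(r-1)c={(self.r - 1) * self.c}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PGGStrategy:
    participation: str  # 'C', 'D' or 'L'
    punish_C: bool = False
    punish_D: bool = False
    punish_L: bool = False

    def __post_init__(self) -> None:
        if self.participation not in _CLASSES:
            raise ValueError("participation must be 'C', 'D' or 'L'")

    def punishes(self, cls: str) -> bool:
        return {"C": self.punish_C, "D": self.punish_D, "L": self.punish_L}[cls]

    @property
    def label(self) -> str:
        bits = "".join(c for c in _CLASSES if self.punishes(c))
        return self.participation + (f"+p{bits}" if bits else "")


def full_space() -> list[PGGStrategy]:
    """All 24 strategies, participation-major, punishment bits in the
    order (punish_C, punish_D, punish_L)."""
    return [
        PGGStrategy(p, *bits)
        for p in _CLASSES
        for bits in itertools.product((False, True), repeat=3)
    ]


def strategy_space(restriction: str) -> list[PGGStrategy]:
    """Strategy subsets induced by microeconomic assumptions.

    ``four``: plain C, D, L plus the cooperator that punishes defectors.
    ``nine``: participants (C or D) with free (punish_C, punish_D) bits,
    plus the plain loner — loners neither punish nor are punished.
    ``twelve``: all participation classes with free (punish_C, punish_D)
    bits — loners may punish but cannot be punished.
    ``full24``: everyone can punish and be punished.
    """
    if restriction == "four":
        return [
            PGGStrategy("C"),
            PGGStrategy("D"),
            PGGStrategy("L"),
            PGGStrategy("C", punish_D=True),
        ]
    if restriction == "nine":
        return [
            PGGStrategy(p, punish_C=pc, punish_D=pd)
            for p in "CD"
            for pc, pd in itertools.product((False, True), repeat=2)
        ] + [PGGStrategy("L")]
    if restriction == "twelve":
        return [
            PGGStrategy(p, punish_C=pc, punish_D=pd)
            for p in _CLASSES
            for pc, pd in itertools.product((False, True), repeat=2)
        ]
    if restriction == "full24":
        return full_space()
    raise ValueError(
        f"unknown restriction {restriction!r}; "
        "valid: 'four', 'nine', 'twelve', 'full24'"
    )


def coop_fraction(s: PGGStrategy) -> float:
    """1 for contributors (any punishment bits), else 0."""
    return 1.0 if s.participation == "C" else 0.0


def group_payoffs(
    group: Sequence[PGGStrategy], params: PGGParams
) -> np.ndarray:
    """Exact payoffs of the members of one group of size n.

    With at most one participant the game is cancelled: everyone gets
    sigma and no punishment occurs (nothing is observable)."""
    if len(group) != params.n:
        raise ValueError(f"group size must be n={params.n}, got {len(group)}")
    n_cls = {c: sum(1 for s in group if s.participation == c) for c in _CLASSES}
    S = n_cls["C"] + n_cls["D"]
    if S <= 1:
        return np.full(len(group), params.sigma)
    pay = np.empty(len(group))
    pot = params.r * params.c * n_cls["C"]
    for i, s in enumerate(group):
        if s.participation == "L":
            pay[i] = params.sigma
        else:
            contrib = params.c if s.participation == "C" else 0.0
            if params.sharing == "participants":
                pay[i] = pot / S - contrib
            else:  # each contribution split among the other S-1 participants
                others = params.r * params.c * (n_cls["C"] - (1 if s.participation == "C" else 0))
                pay[i] = others / (S - 1) - contrib
    # punishment stage over all n members, targeting by participation class
    punishers = {c: sum(1 for s in group if s.punishes(c)) for c in _CLASSES}
    for i, s in enumerate(group):
        cls = s.participation
        pay[i] -= params.fine * (punishers[cls] - (1 if s.punishes(cls) else 0))
        pay[i] -= params.cost_pun * sum(
            n_cls[c] - (1 if cls == c else 0) for c in _CLASSES if s.punishes(c)
        )
    return pay


def _pair_tables(
    sA: PGGStrategy, sB: PGGStrategy, params: PGGParams
) -> tuple[np.ndarray, np.ndarray]:
    """fA[k] (fB[k]) = payoff of a focal A (B) player whose n-1 co-players
    include exactly k A-players."""
    n = params.n
    fA = np.empty(n)
    fB = np.empty(n)
    for k in range(n):
        gA = [sA] * (k + 1) + [sB] * (n - 1 - k)
        fA[k] = group_payoffs(gA, params)[0]
        gB = [sB] + [sA] * k + [sB] * (n - 1 - k)
        fB[k] = group_payoffs(gB, params)[0]
    return fA, fB


def expected_payoffs_two_types(
    sA: PGGStrategy, sB: PGGStrategy, j: int, params: PGGParams
) -> tuple[float, float]:
    """Exact expected payoffs (to an A-player, to a B-player) when the
    population holds j A-players and N-j B-players.

    The focal player's n-1 co-players are drawn without replacement from
    the other N-1 individuals; the expectation over the hypergeometric
    co-player composition is evaluated exactly.
    """
    N = params.N
    if not 0 < j < N:
        raise ValueError(f"need 0 < j < N, got j={j}")
    fA, fB = _pair_tables(sA, sB, params)
    k = np.arange(params.n)
    pmf_A = hypergeom.pmf(k, N - 1, j - 1, params.n - 1)
    pmf_B = hypergeom.pmf(k, N - 1, j, params.n - 1)
    return float(pmf_A @ fA), float(pmf_B @ fB)


class PGGOracle(PayoffOracle):
    """Payoff oracle over a PGG strategy list for the dynamics module.

    Invasion payoffs (used by fixation probabilities and the small-mu
    embedded chain) are exact hypergeometric expectations.  State payoffs
    for arbitrary mixed compositions are Monte-Carlo estimates over
    sampled group compositions (used only by direct simulation at
    mu > 0).
    """

    def __init__(
        self,
        strategies: Sequence[PGGStrategy],
        params: PGGParams,
        mc_groups: int = 200,
    ):
        self.strategies = list(strategies)
        self.strategy_labels = [s.label for s in self.strategies]
        self.params = params
        self.mc_groups = mc_groups
        self._tables: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self.coop = np.array([coop_fraction(s) for s in self.strategies])

    def _pair(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        key = (i, j)
        if key not in self._tables:
            self._tables[key] = _pair_tables(
                self.strategies[i], self.strategies[j], self.params
            )
        return self._tables[key]

    def invasion_payoffs(self, mutant: int, resident: int, N: int):
        if N != self.params.N:
            raise ValueError(
                f"oracle built for N={self.params.N}, dynamics asked for N={N}"
            )
        n = self.params.n
        fA, fB = self._pair(mutant, resident)
        j = np.arange(1, N)
        k = np.arange(n)
        pmf_A = hypergeom.pmf(k[None, :], N - 1, j[:, None] - 1, n - 1)
        pmf_B = hypergeom.pmf(k[None, :], N - 1, j[:, None], n - 1)
        return pmf_A @ fA, pmf_B @ fB

    def state_payoffs(self, counts: np.ndarray, rng=None) -> np.ndarray:
        counts = np.asarray(counts, dtype=np.int64)
        if rng is None:
            rng = np.random.default_rng()
        n = self.params.n
        m = len(self.strategies)
        pay = np.zeros(m)
        for s in range(m):
            if counts[s] == 0:
                continue
            others = counts.copy()
            others[s] -= 1
            draws = rng.multivariate_hypergeometric(
                others, n - 1, size=self.mc_groups
            )
            total = 0.0
            for row in draws:
                group = [self.strategies[s]]
                for t in range(m):
                    group.extend([self.strategies[t]] * int(row[t]))
                total += group_payoffs(group, self.params)[0]
            pay[s] = total / self.mc_groups
        return pay
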