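"""Reactive strategy spaces and exact discounted payoffs for the
repeated prisoner's dilemma.

A reactive (memory-1, opponent-conditioned) strategy is a triple
(first move, reply to opponent's C, reply to opponent's D); there are
exactly 2^3 = 8 such deterministic strategies.  Play between two
deterministic strategies eventually cycles over at most 4 joint states,
so the normalized discounted payoff (1-delta) * sum_i delta^i * pi_i is
evaluated in closed form from the prefix/cycle decomposition — no series
truncation.

An optional per-strategy complexity cost (subtracted from the payoff of
every interaction) supports the Imhof-et-al variant in which reciprocal
cooperation carries a bookkeeping cost.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dynamics import MatrixOracle

__all__ = [
    "PDParams",
    "ReactiveStrategy",
    "all_reactive",
    "named_sets",
    "strategy_set",
    "play_sequence",
    "discounted_payoff",
    "coop_rate",
    "payoff_matrix",
    "PDMatrixGame",
    "pure_nash",
    "with_complexity_cost",
]

_ALIASES = {"CCC": "AllC", "CCD": "TFT", "DDD": "AllD", "DCD": "STFT"}


@dataclass(frozen=True)
class PDParams:
    """One-shot payoffs (R, S, T, P) and continuation probability delta.

    The prisoner's dilemma ordering T > R > P > S with R > (T+P)/2 is
    checked and produces a warning (not an error) when violated, so that
    degenerate games remain usable in property tests.
    """

    R: float = 3.0
    S: float = 0.0
    T: float = 4.0
    P: float = 1.0
    delta: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ValueError(f"delta must lie in [0, 1), got {self.delta}")
        if not (self.T > self.R > self.P > self.S):
            warnings.warn(
                f"payoffs do not satisfy T > R > P > S: "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}",
                stacklevel=2,
            )
        elif not self.R > (self.T + self.P) / 2:
            warnings.warn(
                "R <= (T+P)/2: alternating exploitation beats mutual cooperation",
                stacklevel=2,
            )

    def one_shot(self, my: str, opp: str) -> float:
        if my == "C":
            return self.R if opp == "C" else self.S
        return self.T if opp == "C" else self.P


@dataclass(frozen=True)
class ReactiveStrategy:
    """Deterministic reactive strategy of the repeated PD."""

    first_move: str
    reply_to_C: str
    reply_to_D: str
    complexity_cost: float = 0.0

    def __post_init__(self) -> None:
        for mv in (self.first_move, self.reply_to_C, self.reply_to_D):
            if mv not in ("C", "D"):
                raise ValueError(f"moves must be 'C' or 'D', got {mv!r}")
        if self.complexity_cost < 0:
            raise ValueError("complexity_cost must be >= 0")

    def reply(self, opp_last: str) -> str:
        return self.reply_to_C if opp_last == "C" else self.reply_to_D

    @property
    def code(self) -> str:
        return self.first_move + self.reply_to_C + self.reply_to_D

    @property
    def label(self) -> str:
        base = _ALIASES.get(self.code, self.code)
        if self.complexity_cost:
            return f"{base}(cost={self.complexity_cost:g})"
        return base


ALLC = ReactiveStrategy("C", "C", "C")
TFT = ReactiveStrategy("C", "C", "D")
ALLD = ReactiveStrategy("D", "D", "D")


def all_reactive() -> list[ReactiveStrategy]:
    """All 8 deterministic reactive strategies, in lexicographic order
    of (first move, reply to C, reply to D) with C before D."""
    return [
        ReactiveStrategy(a, b, c)
        for a, b, c in itertools.product("CD", repeat=3)
    ]


def named_sets() -> dict[str, list[ReactiveStrategy]]:
    """The three strategy-space choices studied for the repeated PD:
    ``pair`` = {AllC, AllD}; ``triple`` = {AllC, TFT, AllD};
    ``full8`` = all 8 reactive strategies."""
    return {
        "pair": [ALLC, ALLD],
        "triple": [ALLC, TFT, ALLD],
        "full8": all_reactive(),
    }


def strategy_set(label: str) -> list[ReactiveStrategy]:
    sets = named_sets()
    if label not in sets:
        raise ValueError(
            f"unknown strategy set {label!r}; valid labels: {sorted(sets)}"
        )
    return sets[label]


def with_complexity_cost(
    strategies: Sequence[ReactiveStrategy], which: str, cost: float
) -> list[ReactiveStrategy]:
    """Copy of ``strategies`` with ``cost`` attached to the strategy whose
    label (or code) equals ``which``."""
    out = []
    hit = False
    for s in strategies:
        if s.label == which or s.code == which:
            out.append(replace(s, complexity_cost=cost))
            hit = True
        else:
            out.append(s)
    if not hit:
        raise ValueError(f"no strategy labelled {which!r} in the set")
    return out


def play_sequence(
    a: ReactiveStrategy, b: ReactiveStrategy
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Decompose deterministic play into a finite prefix and a repeating
    cycle of joint moves (a's move, b's move).

    The joint state is the current move pair, of which there are at most
    4, so prefix length + cycle length <= 5.
    """
    state = (a.first_move, b.first_move)
    seen: dict[tuple[str, str], int] = {}
    path: list[tuple[str, str]] = []
    while state not in seen:
        seen[state] = len(path)
        path.append(state)
        state = (a.reply(state[1]), b.reply(state[0]))
    start = seen[state]
    return path[:start], path[start:]


def _stream_value(prefix_vals, cycle_vals, delta: float) -> float:
    """Normalized discounted sum of a stream that plays ``prefix_vals``
    once and then repeats ``cycle_vals`` forever."""
    p = len(prefix_vals)
    total = 0.0
    for i, v in enumerate(prefix_vals):
        total += (delta ** i) * v
    cyc = 0.0
    for j, v in enumerate(cycle_vals):
        cyc += (delta ** j) * v
    total += (delta ** p) * cyc / (1.0 - delta ** len(cycle_vals))
    return (1.0 - delta) * total


def discounted_payoff(
    a: ReactiveStrategy, b: ReactiveStrategy, params: PDParams
) -> tuple[float, float]:
    """Normalized discounted payoffs (payoff to a, payoff to b) for the
    infinitely repeated game, in closed form.  Each strategy's complexity
    cost is subtracted from its own payoff."""
    if params.delta >= 1.0:
        raise ValueError("delta must be < 1 for the normalized payoff")
    prefix, cycle = play_sequence(a, b)
    pa = _stream_value(
        [params.one_shot(x, y) for x, y in prefix],
        [params.one_shot(x, y) for x, y in cycle],
        params.delta,
    )
    pb = _stream_value(
        [params.one_shot(y, x) for x, y in prefix],
        [params.one_shot(y, x) for x, y in cycle],
        params.delta,
    )
    return pa - a.complexity_cost, pb - b.complexity_cost


def coop_rate(a: ReactiveStrategy, b: ReactiveStrategy, params: PDParams) -> float:
    """Discounted fraction of rounds in which ``a`` cooperates against
    ``b``: (1-delta) * sum_i delta^i [a's move at round i == C]."""
    prefix, cycle = play_sequence(a, b)
    return _stream_value(
        [1.0 if x == "C" else 0.0 for x, _ in prefix],
        [1.0 if x == "C" else 0.0 for x, _ in cycle],
        params.delta,
    )


@dataclass
class PDMatrixGame:
    """Pairwise payoff matrix plus cooperation rates for a strategy list."""

    strategies: list[ReactiveStrategy]
    params: PDParams
    payoffs: np.ndarray  # payoffs[i, j] = payoff to an i-player vs a j-player
    coop: np.ndarray     # coop[i, j] = i's cooperation rate against j

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strategies]

    @property
    def self_play_coop(self) -> np.ndarray:
        return np.diag(self.coop).copy()

    def to_oracle(self) -> MatrixOracle:
        return MatrixOracle(self.labels, self.payoffs, coop=self.coop)


def payoff_matrix(
    strategies: Sequence[ReactiveStrategy], params: PDParams
) -> PDMatrixGame:
    """Full pairwise payoff matrix (row player) and cooperation-rate
    matrix for ``strategies``."""
    m = len(strategies)
    A = np.empty((m, m))
    C = np.empty((m, m))
    for i, si in enumerate(strategies):
        for j, sj in enumerate(strategies):
            A[i, j], _ = discounted_payoff(si, sj, params)
            C[i, j] = coop_rate(si, sj, params)
    return PDMatrixGame(list(strategies), params, A, C)


def pure_nash(A: np.ndarray, tol: float = 1e-12) -> list[int]:
    """Indices i that are pure symmetric Nash equilibria of the symmetric
    game with row-player matrix A: A[i, i] >= A[j, i] for all j (weak
    inequality, so ties admit the equilibrium)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    return [i for i in range(A.shape[0]) if A[i, i] >= A[:, i].max() - tol]
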