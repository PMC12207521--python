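"""Game-agnostic evolutionary dynamics over a finite strategy set.

Deterministic replicator dynamics and stochastic finite-population
imitation dynamics with an exponential payoff-to-fitness mapping
``f = exp(beta * pi)``.  Payoffs are supplied by a :class:`PayoffOracle`
(for pairwise matrix games, :class:`MatrixOracle`; group games provide
their own oracle).  Three routes to long-run behaviour are exposed:

* :func:`integrate_replicator` — deterministic, infinite population;
* :func:`run_imitation` — direct simulation of the imitation process at
  exploration rate ``mu > 0``;
* :func:`small_mu_stationary` — the small-mutation-limit embedded Markov
  chain over monomorphic states, built from fixation probabilities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from ._kernels import imitation_matrix_kernel

__all__ = [
    "EvoParams",
    "PayoffOracle",
    "MatrixOracle",
    "StationaryReport",
    "replicator_rhs",
    "integrate_replicator",
    "fitness",
    "imitation_step",
    "run_imitation",
    "fixation_probability",
    "small_mu_stationary",
]


# ---------------------------------------------------------------------------
# parameter / report containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvoParams:
    """Parameters of the stochastic imitation process.

    Parameters
    ----------
    N : int
        Population size (>= 2).
    beta_sel : float
        Intensity of selection in ``f = exp(beta_sel * pi)``; 0 is
        neutral drift.
    mu : float
        Exploration (mutation) probability per update: the focal
        individual adopts a uniformly random strategy from the full
        configured set instead of imitating.
    steps : int
        Number of elementary updates to simulate.
    burn_in : int
        Updates discarded before time-averaging (must be < steps).
    seed : int
        RNG seed; identical seeds give bit-identical reports.
    """

    N: int
    beta_sel: float = 1.0
    mu: float = 1e-3
    steps: int = 1_000_000
    burn_in: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"population size N must be >= 2, got {self.N}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if self.beta_sel < 0:
            raise ValueError("beta_sel must be >= 0")
        if self.burn_in >= self.steps:
            raise ValueError("burn_in must be smaller than steps")


@dataclass
class StationaryReport:
    """Long-run abundances plus a scalar cooperation index."""

    strategy_labels: list[str]
    abundances: np.ndarray
    cooperation_index: float
    method: str  # {"replicator" | "simulation" | "small_mu"}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if not -1e-12 <= self.cooperation_index <= 1 + 1e-12:
            raise ValueError("cooperation_index must lie in [0, 1]")

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.csv`` (strategy_label, abundance) and a JSON
        sidecar ``<prefix>.json`` with parameters and the cooperation index."""
        import pandas as pd

        pd.DataFrame(
            {"strategy_label": self.strategy_labels, "abundance": self.abundances}
        ).to_csv(f"{prefix}.csv", index=False)
        side = {
            "method": self.method,
            "cooperation_index": self.cooperation_index,
            **{k: _jsonable(v) for k, v in self.metadata.items()},
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(side, fh, indent=2)


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return {k: _jsonable(x) for k, x in dataclasses.asdict(v).items()}
    return v


# ---------------------------------------------------------------------------
# payoff oracles
# ---------------------------------------------------------------------------

class PayoffOracle:
    """Interface between a game module and the dynamics.

    Subclasses must provide ``strategy_labels`` and implement
    :meth:`state_payoffs` (expected payoff of each strategy given the
    population composition, self-interaction excluded) and
    :meth:`invasion_payoffs` (two-type payoff profiles used by fixation
    probabilities).
    """

    strategy_labels: list[str]

    @property
    def n_strategies(self) -> int:
        return len(self.strategy_labels)

    def state_payoffs(self, counts: np.ndarray, rng=None) -> np.ndarray:
        raise NotImplementedError

    def invasion_payoffs(self, mutant: int, resident: int, N: int):
        """Payoffs (pi_mutant[j], pi_resident[j]) for j = 1..N-1 mutants."""
        raise NotImplementedError

    def payoff_matrix_or_none(self) -> np.ndarray | None:
        """Pairwise payoff matrix if the game is pairwise, else None."""
        return None


class MatrixOracle(PayoffOracle):
    """Pairwise game given by a payoff matrix ``A`` (row = focal player).

    ``coop`` optionally carries per-pair cooperation rates, either as a
    vector (per-strategy) or an (m, m) matrix ``C[s, t]`` = cooperation
    rate of an s-player against a t-player; it is used by
    :func:`run_imitation` / :func:`small_mu_stationary` to build the
    cooperation index.
    """

    def __init__(self, labels: Sequence[str], A: np.ndarray, coop=None):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("payoff matrix must be square")
        if len(labels) != A.shape[0]:
            raise ValueError("labels and matrix dimension mismatch")
        if not np.all(np.isfinite(A)):
            raise ValueError("payoff matrix must be finite")
        self.strategy_labels = list(labels)
        self.A = A
        self.coop = None if coop is None else np.asarray(coop, dtype=float)

    def coop_matrix(self) -> np.ndarray | None:
        if self.coop is None:
            return None
        if self.coop.ndim == 1:
            return np.tile(self.coop[:, None], (1, len(self.coop)))
        return self.coop

    def state_payoffs(self, counts: np.ndarray, rng=None) -> np.ndarray:
        counts = np.asarray(counts)
        N = counts.sum()
        return (self.A @ counts - np.diag(self.A)) / (N - 1)

    def invasion_payoffs(self, mutant: int, resident: int, N: int):
        j = np.arange(1, N)
        a, b = mutant, resident
        pi_m = ((j - 1) * self.A[a, a] + (N - j) * self.A[a, b]) / (N - 1)
        pi_r = (j * self.A[b, a] + (N - j - 1) * self.A[b, b]) / (N - 1)
        return pi_m, pi_r

    def payoff_matrix_or_none(self) -> np.ndarray | None:
        return self.A


# ---------------------------------------------------------------------------
# deterministic dynamics
# ---------------------------------------------------------------------------

def replicator_rhs(x: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Right-hand side ``dx_i/dt = x_i ((Ax)_i - x.Ax)`` of the replicator
    equation; the components sum to zero on the simplex."""
    x = np.asarray(x, dtype=float)
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] != x.shape[0]:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[0]} entries, A is {A.shape}"
        )
    f = A @ x
    return x * (f - x @ f)


def integrate_replicator(
    x0: np.ndarray, A: np.ndarray, t_end: float, dt: float = 0.01
) -> np.ndarray:
    """Integrate the replicator equation with fixed-step classical
    Runge-Kutta, renormalizing onto the simplex after every step.

    Returns the trajectory as an array of shape (n_steps + 1, m).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x0, dtype=float).copy()
    if abs(x.sum() - 1.0) > 1e-9 or np.any(x < -1e-12):
        raise ValueError("x0 must lie on the probability simplex")
    n_steps = int(round(t_end / dt))
    traj = np.empty((n_steps + 1, x.shape[0]))
    traj[0] = x
    for i in range(n_steps):
        k1 = replicator_rhs(x, A)
        k2 = replicator_rhs(x + 0.5 * dt * k1, A)
        k3 = replicator_rhs(x + 0.5 * dt * k2, A)
        k4 = replicator_rhs(x + dt * k3, A)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite state at step {i}: x={x!r}"
            )
        x = np.clip(x, 0.0, None)
        x /= x.sum()
        traj[i + 1] = x
    return traj


# ---------------------------------------------------------------------------
# stochastic dynamics
# ---------------------------------------------------------------------------

def fitness(payoff, beta_sel: float):
    """Exponential payoff-to-fitness map ``exp(beta_sel * payoff)``.

    Imitation probabilities depend only on payoff differences, so callers
    subtract a common offset before exponentiating to avoid overflow.
    """
    return np.exp(beta_sel * np.asarray(payoff, dtype=float))


def imitation_step(
    counts: np.ndarray, oracle: PayoffOracle, params: EvoParams, rng: np.random.Generator
) -> np.ndarray:
    """One elementary update of the imitation process.

    A uniformly random focal individual either (with probability ``mu``)
    adopts a uniformly random strategy from the full set, or imitates a
    role model drawn from the other N-1 individuals with probability
    proportional to ``exp(beta_sel * payoff)``.  Returns the new counts;
    total population size is conserved.
    """
    counts = np.asarray(counts, dtype=np.int64)
    m = oracle.n_strategies
    N = params.N
    if counts.sum() != N or np.any(counts < 0):
        raise ValueError("counts must be non-negative and sum to N")
    new = counts.copy()
    # focal individual -> focal strategy, proportional to counts
    sf = rng.choice(m, p=counts / N)
    if rng.random() < params.mu:
        s_new = rng.integers(m)
    else:
        pay = oracle.state_payoffs(counts, rng=rng)
        avail = counts.astype(float)
        avail[sf] -= 1.0
        w = np.where(avail > 0, avail, 0.0)
        if w.sum() == 0:  # N == 1 cannot happen (N >= 2); defensive
            return new
        w = w * np.exp(params.beta_sel * (pay - pay[w > 0].max()))
        s_new = rng.choice(m, p=w / w.sum())
    new[sf] -= 1
    new[s_new] += 1
    return new


def _coop_matrix_for(oracle: PayoffOracle, coop) -> np.ndarray:
    m = oracle.n_strategies
    if coop is None:
        if isinstance(oracle, MatrixOracle) and oracle.coop is not None:
            return oracle.coop_matrix()
        return np.zeros((m, m))
    coop = np.asarray(coop, dtype=float)
    if coop.ndim == 1:
        return np.tile(coop[:, None], (1, m))
    return coop


def run_imitation(
    oracle: PayoffOracle,
    params: EvoParams,
    coop=None,
    init_counts=None,
) -> StationaryReport:
    """Simulate the imitation process and time-average after burn-in.

    ``coop`` gives per-strategy (vector) or per-pair (matrix) cooperation
    rates; the cooperation index is the time-average of the expected
    cooperation rate of a random individual against a random opponent
    (self excluded).  ``init_counts`` fixes the initial composition
    (default: each individual starts with a uniform random strategy).
    Pairwise matrix games run in a compiled kernel; other oracles fall
    back to the pure-Python :func:`imitation_step`.
    """
    m = oracle.n_strategies
    C = _coop_matrix_for(oracle, coop)
    A = oracle.payoff_matrix_or_none()
    seed = int(np.random.SeedSequence(params.seed).generate_state(1)[0] & 0x7FFFFFFF)
    if init_counts is not None:
        init_counts = np.asarray(init_counts, dtype=np.int64)
        if init_counts.sum() != params.N or np.any(init_counts < 0):
            raise ValueError("init_counts must be non-negative and sum to N")
    if A is not None:
        abund, coop_idx = imitation_matrix_kernel(
            np.ascontiguousarray(A, dtype=np.float64),
            np.ascontiguousarray(C, dtype=np.float64),
            np.int64(params.N),
            float(params.beta_sel),
            float(params.mu),
            np.int64(params.steps),
            np.int64(params.burn_in),
            np.int64(seed),
            np.empty(0, dtype=np.int64) if init_counts is None else init_counts,
        )
    else:
        rng = np.random.default_rng(params.seed)
        if init_counts is None:
            counts = np.bincount(rng.integers(m, size=params.N), minlength=m)
        else:
            counts = init_counts.copy()
        abund = np.zeros(m)
        coop_idx = 0.0
        n_acc = 0
        N = params.N
        for step in range(params.steps):
            counts = imitation_step(counts, oracle, params, rng)
            if step >= params.burn_in:
                n_acc += 1
                abund += counts
                num = counts @ C @ counts - counts @ np.diag(C)
                coop_idx += num / (N * (N - 1))
        abund /= n_acc * N
        coop_idx /= n_acc
    return StationaryReport(
        strategy_labels=list(oracle.strategy_labels),
        abundances=abund,
        cooperation_index=float(min(max(coop_idx, 0.0), 1.0)),
        method="simulation",
        metadata={"params": params},
    )


def fixation_probability(
    oracle: PayoffOracle, mutant: int, resident: int, N: int, beta_sel: float
) -> float:
    """Probability that a single ``mutant`` takes over a ``resident``
    population of size N under the exponential fitness mapping.

    Uses the standard product formula with transition-probability ratio
    ``exp(-beta (pi_mutant(j) - pi_resident(j)))``; evaluated in log
    space, so it is stable for strong selection.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if beta_sel == 0.0:  # neutral drift: exactly 1/N
        return 1.0 / N
    pi_m, pi_r = oracle.invasion_payoffs(mutant, resident, N)
    log_terms = np.concatenate(
        [[0.0], np.cumsum(-beta_sel * (np.asarray(pi_m) - np.asarray(pi_r)))]
    )
    return float(np.exp(-logsumexp(log_terms)))


def small_mu_stationary(
    oracle: PayoffOracle,
    N: int,
    beta_sel: float,
    coop=None,
) -> StationaryReport:
    """Stationary distribution of the small-mutation-limit embedded chain.

    In the rare-mutation regime the population is almost always
    monomorphic; transitions between monomorphic states occur at rate
    ``rho(invader <- resident) / (m - 1)``.  The cooperation index weights
    each strategy's abundance by its monomorphic (self-play) cooperation
    rate.
    """
    m = oracle.n_strategies
    if m < 2:
        raise ValueError("need at least 2 strategies")
    P = np.zeros((m, m))
    for r in range(m):
        for q in range(m):
            if q == r:
                continue
            P[r, q] = fixation_probability(oracle, q, r, N, beta_sel) / (m - 1)
        P[r, r] = 1.0 - P[r].sum()
    # left stationary vector: v P = v, sum v = 1
    M = P.T - np.eye(m)
    M[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    try:
        v = np.linalg.solve(M, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rho>0 => ergodic
        raise np.linalg.LinAlgError(
            f"singular embedded chain (should not happen for rho > 0): {exc}"
        )
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    C = _coop_matrix_for(oracle, coop)
    coop_self = np.diag(C)
    return StationaryReport(
        strategy_labels=list(oracle.strategy_labels),
        abundances=v,
        cooperation_index=float(np.clip(v @ coop_self, 0.0, 1.0)),
        method="small_mu",
        metadata={"N": N, "beta_sel": beta_sel},
    )
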