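"""Reproducible sweep orchestration for the three case studies.

A plain-YAML :class:`ExperimentConfig` names a case study, a sweep
variable with its grid, the strategy sets to compare, and replicate
count; :func:`run_experiment` executes every (grid point, set,
replicate) cell with a deterministic per-cell seed derived from the
master seed and returns a tidy table (one row per cell).  Re-running a
config reproduces the table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import indirect_recip, optional_pgg, repeated_pd
from .dynamics import EvoParams, run_imitation, small_mu_stationary

__all__ = ["ExperimentConfig", "run_experiment", "fixture_games", "cell_seed",
           "plot_sweep"]

_CASES = ("repeated_pd", "pgg", "indirect")


@dataclass
class ExperimentConfig:
    """Declarative description of one figure-style sweep.

    ``game`` holds the case study's model parameters (anything omitted
    falls back to the module defaults); ``evo`` holds N, beta_sel, mu,
    steps, burn_in for the stochastic dynamics.  ``dynamics`` selects
    ``imitation`` (direct simulation), ``smallmu`` (embedded chain) or —
    for the repeated PD — ``replicator``.
    """

    case_study: str
    sets: list[str]
    sweep_var: str | None = None
    grid: list = field(default_factory=lambda: [None])
    replicates: int = 10
    seed: int = 0
    dynamics: str = "imitation"
    game: dict = field(default_factory=dict)
    evo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.case_study not in _CASES:
            raise ValueError(
                f"unknown case_study {self.case_study!r}; valid: {_CASES}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.grid:
            raise ValueError("grid must not be empty")

    # -- lossless round-trip through YAML ---------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls(**yaml.safe_load(text))


def cell_seed(master_seed: int, sweep_value, set_label: str, replicate: int) -> int:
    """Stable per-cell seed: CRC32 of the cell coordinates, below 2^31."""
    key = f"{master_seed}|{sweep_value!r}|{set_label}|{replicate}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _evo(cfg: ExperimentConfig, seed: int, **overrides) -> EvoParams:
    kw = dict(N=20, beta_sel=1.0, mu=1e-3, steps=1_000_000, burn_in=100_000)
    kw.update(cfg.evo)
    kw.update(overrides)
    return EvoParams(seed=seed, **kw)


def _run_pd_cell(cfg, set_label, value, seed):
    game_kw = dict(cfg.game)
    evo_over = {}
    if cfg.sweep_var == "delta":
        game_kw["delta"] = value
    elif cfg.sweep_var == "N":
        evo_over["N"] = int(value)
    elif cfg.sweep_var is not None:
        raise ValueError(f"repeated_pd sweeps over 'delta' or 'N', not {cfg.sweep_var!r}")
    params = repeated_pd.PDParams(**game_kw)
    game = repeated_pd.payoff_matrix(repeated_pd.strategy_set(set_label), params)
    oracle = game.to_oracle()
    evo = _evo(cfg, seed, **evo_over)
    if cfg.dynamics == "imitation":
        return run_imitation(oracle, evo)
    if cfg.dynamics == "smallmu":
        return small_mu_stationary(oracle, evo.N, evo.beta_sel)
    raise ValueError(f"unsupported dynamics {cfg.dynamics!r} for repeated_pd")


def _run_pgg_cell(cfg, set_label, value, seed):
    game_kw = dict(cfg.game)
    if cfg.sweep_var in ("N", "n"):
        game_kw[cfg.sweep_var] = int(value)
    elif cfg.sweep_var is not None:
        raise ValueError(f"pgg sweeps over 'N' or 'n', not {cfg.sweep_var!r}")
    params = optional_pgg.PGGParams(**game_kw)
    strategies = optional_pgg.strategy_space(set_label)
    oracle = optional_pgg.PGGOracle(strategies, params)
    evo = _evo(cfg, seed, N=params.N)
    if cfg.dynamics == "smallmu":
        return small_mu_stationary(oracle, params.N, evo.beta_sel, coop=oracle.coop)
    if cfg.dynamics == "imitation":
        return run_imitation(oracle, evo, coop=oracle.coop)
    raise ValueError(f"unsupported dynamics {cfg.dynamics!r} for pgg")


def _run_ir_cell(cfg, set_label, value, seed):
    game_kw = dict(cfg.game)
    if cfg.sweep_var == "N":
        game_kw["N"] = int(value)
    elif cfg.sweep_var is not None:
        raise ValueError(f"indirect sweeps over 'N', not {cfg.sweep_var!r}")
    params = indirect_recip.IRParams(**game_kw)
    evo_kw = dict(beta_sel=1.0, mu=0.01, steps=1500, burn_in=300)
    evo_kw.update(cfg.evo)
    evo_kw["N"] = params.N
    evo = EvoParams(seed=seed, **evo_kw)
    return indirect_recip.evolve(set_label, params, evo)


_RUNNERS = {"repeated_pd": _run_pd_cell, "pgg": _run_pgg_cell, "indirect": _run_ir_cell}


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Execute the configured sweep; one row per (grid point, set,
    replicate) with the cooperation index and the abundance vector
    (JSON).  Any cell failure aborts with the cell's full parameters."""
    runner = _RUNNERS[cfg.case_study]
    rows = []
    for value in cfg.grid:
        for set_label in cfg.sets:
            for rep in range(cfg.replicates):
                seed = cell_seed(cfg.seed, value, set_label, rep)
                try:
                    report = runner(cfg, set_label, value, seed)
                except Exception as exc:
                    raise RuntimeError(
                        f"experiment cell failed: case={cfg.case_study} "
                        f"{cfg.sweep_var}={value!r} set={set_label} "
                        f"replicate={rep} seed={seed} game={cfg.game} "
                        f"evo={cfg.evo}: {exc}"
                    ) from exc
                rows.append(
                    {
                        "case_study": cfg.case_study,
                        "sweep_var": cfg.sweep_var,
                        "sweep_value": value,
                        "set_label": set_label,
                        "replicate": rep,
                        "seed": seed,
                        "cooperation_index": report.cooperation_index,
                        "abundances": json.dumps(
                            dict(
                                zip(
                                    report.strategy_labels,
                                    np.round(report.abundances, 10).tolist(),
                                )
                            )
                        ),
                    }
                )
    return pd.DataFrame(rows)


def fixture_games(seed: int, n_games: int = 20) -> list[tuple[list[str], np.ndarray]]:
    """Reproducible random small matrix games for property tests.

    Payoffs are uniform in [-5, 5] over 2-4 strategies.  The batch always
    contains at least one 2x2 dominance game and one 2x2 coexistence
    (hawk-dove-like) game, obtained by rejection sampling with explicit
    classification.
    """
    rng = np.random.default_rng(seed)

    def random_game():
        m = int(rng.integers(2, 5))
        A = rng.uniform(-5, 5, size=(m, m))
        labels = [f"s{i}" for i in range(m)]
        return labels, A

    def classify2(A):
        # invasion fitnesses at the two monomorphic corners
        adv1 = A[1, 0] - A[0, 0]  # strategy 1 invading 0
        adv0 = A[0, 1] - A[1, 1]  # strategy 0 invading 1
        if adv1 > 0 and adv0 < 0:
            return "dominance"
        if adv1 < 0 and adv0 > 0:
            return "dominance"
        if adv1 > 0 and adv0 > 0:
            return "coexistence"
        return "bistable"

    games = [random_game() for _ in range(n_games - 2)]
    for wanted in ("dominance", "coexistence"):
        while True:
            A = rng.uniform(-5, 5, size=(2, 2))
            if classify2(A) == wanted:
                games.append((["s0", "s1"], A))
                break
    return games


def plot_sweep(table: pd.DataFrame, out_path: str) -> None:
    """Render cooperation index vs sweep value, one line per strategy
    set (mean over replicates).  Cosmetic; the CSV is canonical."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, sub in table.groupby("set_label"):
        agg = sub.groupby("sweep_value")["cooperation_index"].agg(["mean", "sem"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=label, marker="o")
    ax.set_xlabel(table["sweep_var"].iloc[0] or "")
    ax.set_ylabel("cooperation index")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
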