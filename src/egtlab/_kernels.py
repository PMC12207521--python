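"""Compiled inner loops (numba) for the stochastic simulations.

The kernels use the numba-supported legacy numpy RNG seeded explicitly,
so identical seeds give bit-identical trajectories.  Semantics of the
imitation micro-step mirror :func:`egtlab.dynamics.imitation_step`
exactly; the correspondence is exercised in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["imitation_matrix_kernel", "ir_payoff_kernel", "ir_evolve_kernel"]


@njit(cache=True)
def imitation_matrix_kernel(A, C, N, beta, mu, steps, burn_in, seed, init_counts):
    """Imitation process for a pairwise matrix game.

    Returns (time-averaged abundances, time-averaged cooperation index).
    ``C[s, t]`` is the cooperation rate of an s-player against a t-player.
    ``init_counts`` of length m fixes the initial composition; an empty
    array means each individual starts with a uniform random strategy.
    """
    m = A.shape[0]
    np.random.seed(seed)
    counts = np.zeros(m, np.int64)
    if init_counts.shape[0] == m:
        for t in range(m):
            counts[t] = init_counts[t]
    else:
        for _ in range(N):
            counts[int(np.random.random() * m)] += 1
    abund = np.zeros(m)
    pay = np.empty(m)
    w = np.empty(m)
    coop_acc = 0.0
    n_acc = 0
    for step in range(steps):
        # focal individual -> its strategy, proportional to counts
        r = np.random.random() * N
        sf = 0
        acc = counts[0]
        while r >= acc and sf < m - 1:
            sf += 1
            acc += counts[sf]
        if np.random.random() < mu:
            s_new = int(np.random.random() * m)
        else:
            pmax = -1.0e300
            for t in range(m):
                s = 0.0
                for u in range(m):
                    s += counts[u] * A[t, u]
                pay[t] = (s - A[t, t]) / (N - 1)
                avail = counts[t] - (1 if t == sf else 0)
                if avail > 0 and pay[t] > pmax:
                    pmax = pay[t]
            wsum = 0.0
            for t in range(m):
                avail = counts[t] - (1 if t == sf else 0)
                if avail > 0:
                    w[t] = avail * np.exp(beta * (pay[t] - pmax))
                else:
                    w[t] = 0.0
                wsum += w[t]
            r2 = np.random.random() * wsum
            s_new = 0
            acc2 = w[0]
            while r2 >= acc2 and s_new < m - 1:
                s_new += 1
                acc2 += w[s_new]
        counts[sf] -= 1
        counts[s_new] += 1
        if step >= burn_in:
            n_acc += 1
            num = 0.0
            for s in range(m):
                cs = counts[s]
                if cs == 0:
                    continue
                abund[s] += cs
                row = 0.0
                for t in range(m):
                    ct = counts[t] - (1 if t == s else 0)
                    row += ct * C[s, t]
                num += cs * row
            coop_acc += num / (N * (N - 1.0))
    return abund / (n_acc * N), coop_acc / n_acc


@njit(cache=True)
def ir_payoff_kernel(
    act_tab, norm_tab, agent_rule, agent_norm,
    benefit, cost, assess_error, exec_error,
    burn_rounds, rounds, seed,
):
    """Donation-game rounds with private reputations for a fixed population.

    Opinions start all-G (1), the diagonal holding each agent's
    self-image; ``burn_rounds`` rounds equilibrate opinions before
    payoffs and realized actions are recorded.  Returns
    (per-agent payoff per game participation, cooperation rate,
    realized action per measured round).

    RNG draws never depend on opinion or norm values, so two runs with
    the same seed that differ only in the norm of an agent whose action
    rule ignores reputations are coupled bit-exactly.
    """
    N = agent_rule.shape[0]
    np.random.seed(seed)
    op = np.ones((N, N), np.int8)
    pay = np.zeros(N)
    actions = np.empty(rounds, np.int8)
    coop = 0
    total = burn_rounds + rounds
    for t in range(total):
        d = int(np.random.random() * N)
        rcp = int(np.random.random() * (N - 1))
        if rcp >= d:
            rcp += 1
        action = act_tab[agent_rule[d], op[d, rcp]]
        if action == 1 and np.random.random() < exec_error:
            action = 0
        if t >= burn_rounds:
            actions[t - burn_rounds] = action
            if action == 1:
                pay[d] -= cost
                pay[rcp] += benefit
                coop += 1
        # every agent (donor's self-assessment included) updates its view
        # of the donor; the flip is one synchronized draw per interaction
        flip = np.random.random() < assess_error
        for k in range(N):
            rep = norm_tab[agent_norm[k], action, op[k, rcp]]
            if flip:
                rep = 1 - rep
            op[k, d] = rep
    games_per_agent = 2.0 * rounds / N
    return pay / games_per_agent, coop / rounds, actions


@njit(cache=True)
def ir_evolve_kernel(
    act_tab, norm_tab, space_rule, space_norm,
    N, benefit, cost, assess_error, exec_error,
    beta, mu, rounds, updates_per_gen, gens, burn_in_gens, seed,
):
    """Evolution of reputation strategies: payoff-evaluation epochs of
    ``rounds`` donation interactions, each followed by ``updates_per_gen``
    imitation micro-steps.  Opinions persist across epochs; an agent that
    switches strategy resets its own opinions of everyone to G.

    Returns (time-averaged strategy abundances, cooperation index).
    """
    S = space_rule.shape[0]
    np.random.seed(seed)
    strat = np.empty(N, np.int64)
    for i in range(N):
        strat[i] = int(np.random.random() * S)
    op = np.ones((N, N), np.int8)
    pay = np.zeros(N)
    w = np.empty(N)
    abund = np.zeros(S)
    coop_acc = 0.0
    n_acc = 0
    games_per_agent = 2.0 * rounds / N
    for g in range(gens):
        for i in range(N):
            pay[i] = 0.0
        coop = 0
        for t in range(rounds):
            d = int(np.random.random() * N)
            rcp = int(np.random.random() * (N - 1))
            if rcp >= d:
                rcp += 1
            action = act_tab[space_rule[strat[d]], op[d, rcp]]
            if action == 1 and np.random.random() < exec_error:
                action = 0
            if action == 1:
                pay[d] -= cost
                pay[rcp] += benefit
                coop += 1
            flip = np.random.random() < assess_error
            for k in range(N):
                rep = norm_tab[space_norm[strat[k]], action, op[k, rcp]]
                if flip:
                    rep = 1 - rep
                op[k, d] = rep
        # imitation micro-steps at frozen payoff estimates
        for _ in range(updates_per_gen):
            focal = int(np.random.random() * N)
            if np.random.random() < mu:
                s_new = int(np.random.random() * S)
            else:
                pmax = -1.0e300
                for k in range(N):
                    if k != focal and pay[k] > pmax:
                        pmax = pay[k]
                wsum = 0.0
                for k in range(N):
                    if k == focal:
                        w[k] = 0.0
                    else:
                        w[k] = np.exp(beta * (pay[k] - pmax) / games_per_agent)
                    wsum += w[k]
                r2 = np.random.random() * wsum
                rm = 0
                acc = w[0]
                while r2 >= acc and rm < N - 1:
                    rm += 1
                    acc += w[rm]
                s_new = strat[rm]
            if s_new != strat[focal]:
                strat[focal] = s_new
                for j in range(N):
                    op[focal, j] = 1
        if g >= burn_in_gens:
            n_acc += 1
            for i in range(N):
                abund[strat[i]] += 1.0
            coop_acc += coop / rounds
    return abund / (n_acc * N), coop_acc / n_acc
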