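"""Dynamics layer: replicator equation, imitation process, fixation,
small-mutation embedded chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import egtlab.repeated_pd as rpd
from egtlab.dynamics import (
    EvoParams,
    MatrixOracle,
    StationaryReport,
    fitness,
    fixation_probability,
    imitation_step,
    integrate_replicator,
    replicator_rhs,
    run_imitation,
    small_mu_stationary,
)


def chain_solve_fixation(A, N, beta):
    """Independent oracle: fixation probability of one mutant (strategy 0)
    in a resident (strategy 1) population via the absorbing tridiagonal
    birth-death chain.  The hitting-probability system
    -Tm phi_{j-1} + (Tm+Tp) phi_j - Tp phi_{j+1} = 0 is eliminated with
    exact rational arithmetic (Thomas algorithm on Fractions), because a
    float dense solve loses all accuracy for strong selection."""
    from fractions import Fraction

    j = np.arange(1, N)
    pi_m = ((j - 1) * A[0, 0] + (N - j) * A[0, 1]) / (N - 1)
    pi_r = (j * A[1, 0] + (N - j - 1) * A[1, 1]) / (N - 1)
    fm, fr = np.exp(beta * pi_m), np.exp(beta * pi_r)
    Tp = [
        Fraction(int(N - jj), int(N))
        * Fraction(float(jj * m)) / Fraction(float(jj * m + (N - jj) * r))
        for jj, m, r in zip(j.tolist(), fm.tolist(), fr.tolist())
    ]
    Tm = [
        Fraction(int(jj), int(N))
        * Fraction(float((N - jj) * r)) / Fraction(float(jj * m + (N - jj) * r))
        for jj, m, r in zip(j.tolist(), fm.tolist(), fr.tolist())
    ]
    # Thomas elimination on the (N-1) unknowns phi_1..phi_{N-1}
    diag = [Tp[i] + Tm[i] for i in range(N - 1)]
    rhs = [Fraction(0)] * (N - 1)
    rhs[-1] = Tp[-1]  # phi_N = 1
    for i in range(1, N - 1):
        w = Tm[i] / diag[i - 1]  # sub-diagonal is -Tm[i], super is -Tp[i-1]
        diag[i] = diag[i] - w * Tp[i - 1]
        rhs[i] = rhs[i] + w * rhs[i - 1]
    phi = [Fraction(0)] * (N - 1)
    phi[-1] = rhs[-1] / diag[-1]
    for i in range(N - 3, -1, -1):
        phi[i] = (rhs[i] + Tp[i] * phi[i + 1]) / diag[i]
    return float(phi[0])


class TestReplicator:
    def test_monomorphic_state_is_fixed_point(self, rng):
        A = rng.uniform(-5, 5, size=(3, 3))
        assert np.allclose(replicator_rhs(np.array([1.0, 0, 0]), A), 0.0)

    def test_equal_payoffs_are_neutral(self):
        A = np.full((2, 2), 1.7)
        assert np.allclose(replicator_rhs(np.array([0.5, 0.5]), A), 0.0)

    def test_defection_grows_in_one_shot_pd(self):
        A = np.array([[3.0, 0.0], [4.0, 1.0]])  # rows: C, D
        dx = replicator_rhs(np.array([0.5, 0.5]), A)
        assert dx[1] > 0 and dx[0] < 0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            replicator_rhs(np.array([0.5, 0.5]), np.zeros((3, 3)))

    @given(
        x=arrays(float, 4, elements=st.floats(0.01, 1.0)),
        A=arrays(float, (4, 4), elements=st.floats(-5, 5)),
    )
    def test_simplex_conservation(self, x, A):
        x = x / x.sum()
        assert abs(replicator_rhs(x, A).sum()) < 1e-12

    def test_dominated_strategy_decay_matches_logistic(self):
        """One-shot PD: the cooperator share follows the closed-form
        logistic solution x(t) = x0 e^-t / (1 - x0 + x0 e^-t)."""
        A = np.array([[3.0, 0.0], [4.0, 1.0]])  # pi_C - pi_D = -1 everywhere
        x0 = 0.9
        t = 8.0
        traj = integrate_replicator(np.array([x0, 1 - x0]), A, t_end=t, dt=0.005)
        expected = x0 * np.exp(-t) / (1 - x0 + x0 * np.exp(-t))
        assert traj[-1][0] == pytest.approx(expected, abs=1e-6)
        assert traj[-1][1] > 0.99  # defection takes over

    def test_monomorphic_start_stays_constant(self, pd_params):
        game = rpd.payoff_matrix(rpd.strategy_set("triple"), pd_params)
        traj = integrate_replicator(np.array([0.0, 1.0, 0.0]), game.payoffs, 10.0)
        assert np.allclose(traj, traj[0])

    def test_alld_basin_attracts(self, pd_params):
        """Defector-heavy initial conditions converge to pure AllD; AllD is
        locally stable alongside TFT in the three-strategy repeated PD."""
        game = rpd.payoff_matrix(rpd.strategy_set("triple"), pd_params)
        traj = integrate_replicator(np.array([0.05, 0.05, 0.9]), game.payoffs, 200.0)
        assert traj[-1][2] > 0.999

    def test_trajectory_stays_on_simplex(self, pd_params):
        game = rpd.payoff_matrix(rpd.strategy_set("full8"), pd_params)
        x0 = np.full(8, 1 / 8)
        traj = integrate_replicator(x0, game.payoffs, 50.0)
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-9)
        assert traj.min() >= 0


class TestFitness:
    def test_identities(self):
        assert fitness(0.0, 1.0) == 1.0
        assert fitness(2.0, 0.0) == 1.0
        p1, p2, beta = 1.3, -0.4, 2.0
        assert fitness(p1, beta) / fitness(p2, beta) == pytest.approx(
            np.exp(beta * (p1 - p2))
        )


class TestImitationStep:
    def test_count_conservation_and_mutation(self, rng):
        o = MatrixOracle(["a", "b", "c"], rng.uniform(-1, 1, (3, 3)))
        params = EvoParams(N=12, beta_sel=1.0, mu=1.0, steps=10)
        counts = np.array([4, 4, 4])
        hits = np.zeros(3)
        for _ in range(600):
            new = imitation_step(counts, o, params, rng)
            assert new.sum() == 12
            diff = new - counts
            if diff.any():
                hits[np.argmax(diff)] += 1
        # mu=1: adopted strategy uniform over the full set
        assert hits.sum() > 0
        assert (hits / hits.sum()).max() < 0.5

    def test_neutral_drift_role_model_uniform_over_others(self, rng):
        """beta=0, mu=0: adoption probabilities equal the composition of
        the other N-1 individuals."""
        o = MatrixOracle(["a", "b"], np.array([[5.0, 5.0], [0.0, 0.0]]))
        params = EvoParams(N=10, beta_sel=0.0, mu=0.0, steps=10)
        counts = np.array([1, 9])
        grew = 0
        trials = 4000
        for _ in range(trials):
            new = imitation_step(counts, o, params, rng)
            if new[0] == 2:
                grew += 1
        # P(focal=b) * P(model=a) = (9/10) * (1/9) = 0.1
        assert grew / trials == pytest.approx(0.1, abs=0.02)


class TestRunImitation:
    def test_absorbing_without_mutation(self, pd_params):
        game = rpd.payoff_matrix(rpd.strategy_set("triple"), pd_params)
        rep = run_imitation(
            game.to_oracle(),
            EvoParams(N=10, beta_sel=1.0, mu=0.0, steps=20_000, burn_in=0, seed=3),
            init_counts=[0, 0, 10],
        )
        assert np.allclose(rep.abundances, [0, 0, 1])
        assert rep.cooperation_index == 0.0

    def test_symmetric_game_near_uniform(self):
        o = MatrixOracle(["a", "b", "c"], np.ones((3, 3)))
        rep = run_imitation(
            o, EvoParams(N=12, beta_sel=1.0, mu=0.05, steps=400_000, burn_in=40_000, seed=5)
        )
        assert np.allclose(rep.abundances, 1 / 3, atol=0.05)

    def test_ergodicity_all_strategies_recur(self, pd_params):
        game = rpd.payoff_matrix(rpd.strategy_set("triple"), pd_params)
        rep = run_imitation(
            game.to_oracle(),
            EvoParams(N=20, beta_sel=1.0, mu=1e-3, steps=1_000_000,
                      burn_in=100_000, seed=11),
        )
        assert (rep.abundances > 0).all()

    def test_seed_determinism(self, pd_params):
        game = rpd.payoff_matrix(rpd.strategy_set("full8"), pd_params)
        params = EvoParams(N=20, beta_sel=1.0, mu=1e-3, steps=100_000,
                           burn_in=10_000, seed=42)
        a = run_imitation(game.to_oracle(), params)
        b = run_imitation(game.to_oracle(), params)
        assert np.array_equal(a.abundances, b.abundances)
        assert a.cooperation_index == b.cooperation_index

    def test_step_transition_probabilities_match_closed_form(self, rng):
        """Empirical one-step up/down transition frequencies of the
        Python micro-step agree with the closed-form probabilities of the
        imitation chain at every two-strategy composition."""
        A = np.array([[2.0, 0.5], [1.0, 1.5]])
        N, beta, mu = 8, 0.6, 0.02
        o = MatrixOracle(["a", "b"], A)
        params = EvoParams(N=N, beta_sel=beta, mu=mu, steps=10)
        T = 4000
        for j in range(1, N):
            counts = np.array([j, N - j])
            pa = ((j - 1) * A[0, 0] + (N - j) * A[0, 1]) / (N - 1)
            pb = (j * A[1, 0] + (N - j - 1) * A[1, 1]) / (N - 1)
            wa, wb = j * np.exp(beta * pa), (N - j - 1) * np.exp(beta * pb)
            up = ((N - j) / N) * (mu * 0.5 + (1 - mu) * wa / (wa + wb))
            wa2, wb2 = (j - 1) * np.exp(beta * pa), (N - j) * np.exp(beta * pb)
            down = (j / N) * (mu * 0.5 + (1 - mu) * wb2 / (wa2 + wb2))
            grew = shrank = 0
            for _ in range(T):
                new = imitation_step(counts, o, params, rng)
                if new[0] > j:
                    grew += 1
                elif new[0] < j:
                    shrank += 1
            for expected, got in ((up, grew / T), (down, shrank / T)):
                tol = 4 * np.sqrt(expected * (1 - expected) / T)
                assert abs(got - expected) < tol

    def test_kernel_long_run_matches_exact_chain_stationary(self):
        """Compiled-kernel time averages agree with the exact stationary
        distribution of the two-strategy imitation chain."""
        A = np.array([[2.0, 0.5], [1.0, 1.5]])
        N, beta, mu = 8, 0.6, 0.02
        P = np.zeros((N + 1, N + 1))
        for j in range(N + 1):
            pa = ((j - 1) * A[0, 0] + (N - j) * A[0, 1]) / (N - 1) if j > 0 else 0.0
            pb = (j * A[1, 0] + (N - j - 1) * A[1, 1]) / (N - 1) if j < N else 0.0
            up = down = 0.0
            if j < N:
                wa, wb = j * np.exp(beta * pa), (N - j - 1) * np.exp(beta * pb)
                up = ((N - j) / N) * (mu * 0.5 + (1 - mu) * (wa / (wa + wb) if wa + wb > 0 else 0.0))
            if j > 0:
                wa, wb = (j - 1) * np.exp(beta * pa), (N - j) * np.exp(beta * pb)
                down = (j / N) * (mu * 0.5 + (1 - mu) * (wb / (wa + wb) if wa + wb > 0 else 0.0))
            P[j, min(j + 1, N)] += up
            P[j, max(j - 1, 0)] += down
            P[j, j] += 1 - up - down
        M = P.T - np.eye(N + 1)
        M[-1, :] = 1.0
        b = np.zeros(N + 1)
        b[-1] = 1.0
        pi = np.linalg.solve(M, b)
        exact = float(pi @ np.arange(N + 1)) / N
        sim = run_imitation(
            MatrixOracle(["a", "b"], A),
            EvoParams(N=N, beta_sel=beta, mu=mu, steps=4_000_000,
                      burn_in=100_000, seed=2),
        )
        assert abs(sim.abundances[0] - exact) < 0.03


class TestFixation:
    def test_neutral_is_exactly_one_over_N(self, rng):
        for N in (2, 5, 12, 50):
            o = MatrixOracle(["a", "b"], rng.uniform(-5, 5, (2, 2)))
            assert fixation_probability(o, 0, 1, N, 0.0) == 1.0 / N

    def test_N2_closed_form(self):
        A = np.array([[0.0, 2.0], [1.0, 0.0]])
        o = MatrixOracle(["a", "b"], A)
        beta = 0.7
        # single mutant in N=2: pi_A = A[0,1], pi_B = A[1,0]
        expected = 1.0 / (1.0 + np.exp(-beta * (A[0, 1] - A[1, 0])))
        assert fixation_probability(o, 0, 1, 2, beta) == pytest.approx(expected, abs=1e-12)

    def test_product_formula_equals_chain_solve(self, rng):
        for _ in range(30):
            A = rng.uniform(-5, 5, (2, 2))
            N = int(rng.integers(2, 13))
            beta = rng.uniform(0, 5)
            o = MatrixOracle(["a", "b"], A)
            assert fixation_probability(o, 0, 1, N, beta) == pytest.approx(
                chain_solve_fixation(A, N, beta), abs=1e-9
            )

    def test_small_N_rejected(self, rng):
        o = MatrixOracle(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            fixation_probability(o, 0, 1, 1, 1.0)


class TestSmallMuStationary:
    def test_symmetric_two_strategies(self):
        o = MatrixOracle(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        rep = small_mu_stationary(o, 10, 2.0)
        assert np.allclose(rep.abundances, 0.5, atol=1e-12)

    def test_equal_payoffs_uniform(self):
        for m in (2, 5, 8):
            o = MatrixOracle([f"s{i}" for i in range(m)], np.ones((m, m)))
            rep = small_mu_stationary(o, 20, 3.0)
            assert np.allclose(rep.abundances, 1 / m, atol=1e-9)

    def test_strong_selection_top_strategies(self, pd_params):
        """TFT and AllD, the two pure equilibria, dominate the stationary
        distribution of the three-strategy repeated PD."""
        game = rpd.payoff_matrix(rpd.strategy_set("triple"), pd_params)
        rep = small_mu_stationary(game.to_oracle(), 20, 5.0)
        order = np.argsort(rep.abundances)[::-1]
        top2 = {rep.strategy_labels[i] for i in order[:2]}
        assert top2 == {"TFT", "AllD"}

    def test_ergodic_consistency_with_simulation(self):
        """Direct simulation at mu=1e-3 reproduces the embedded-chain
        abundances within 3 standard errors (2-strategy game)."""
        A = np.array([[2.0, 0.5], [1.0, 1.5]])
        o = MatrixOracle(["a", "b"], A)
        sm = small_mu_stationary(o, 8, 0.6)
        vals = np.array(
            [
                run_imitation(
                    o,
                    EvoParams(N=8, beta_sel=0.6, mu=1e-3, steps=2_000_000,
                              burn_in=200_000, seed=seed),
                ).abundances[0]
                for seed in range(8)
            ]
        )
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - sm.abundances[0]) < 3 * se


class TestStationaryReport:
    def test_validation(self):
        with pytest.raises(ValueError):
            StationaryReport(["a"], np.array([0.5]), 0.0, "simulation")
        with pytest.raises(ValueError):
            StationaryReport(["a", "b"], np.array([0.5, 0.5]), 1.5, "simulation")

    def test_save_roundtrip(self, tmp_path):
        import json

        import pandas as pd

        rep = StationaryReport(
            ["x", "y"], np.array([0.25, 0.75]), 0.4, "small_mu", {"N": 10}
        )
        prefix = str(tmp_path / "out")
        rep.save(prefix)
        table = pd.read_csv(prefix + ".csv")
        assert list(table["strategy_label"]) == ["x", "y"]
        assert np.allclose(table["abundance"], [0.25, 0.75])
        side = json.load(open(prefix + ".json"))
        assert side["cooperation_index"] == 0.4
        assert side["N"] == 10
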