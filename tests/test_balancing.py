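"""Empirical Gramians against Lyapunov oracles, balancing, truncation,
importance indices."""

import numpy as np
import pytest
import sympy as sp

import crnreduce as cr
from crnreduce.errors import RankError, UndefinedIndexError

from conftest import linear_system


def _design(seed=0, horizon=40.0, n=8, points=401):
    return cr.PerturbationDesign.sample(
        seed=seed, n_input=n, n_state=n, horizon=horizon, n_timepoints=points
    )


class TestControllabilityGramian:
    def test_scalar_system_matches_lyapunov_half(self):
        system = linear_system([[-1.0]], B=[[1.0]], C=[[1.0]])
        P = cr.empirical_controllability_gramian(system, _design(), x_star=np.zeros(1))
        assert P[0, 0] == pytest.approx(0.5, rel=0.05)

    def test_disconnected_input_gives_zero(self):
        system = linear_system([[-1.0]], B=[[0.0]], C=[[1.0]])
        P = cr.empirical_controllability_gramian(system, _design(), x_star=np.zeros(1))
        assert np.allclose(P, 0.0)

    def test_decoupled_systems_give_diagonal_gramian(self):
        A = np.diag([-1.0, -3.0])
        system = linear_system(A, B=np.array([[1.0], [0.5]]), C=np.array([[1.0, 1.0]]))
        # two scalar systems driven by independent channels stay uncorrelated
        system2 = linear_system(
            A, B=np.array([[1.0, 0.0], [0.0, 0.5]]), C=np.array([[1.0, 1.0]])
        )
        P = cr.empirical_controllability_gramian(system2, _design(), x_star=np.zeros(2))
        assert abs(P[0, 1]) < 1e-8 * np.trace(P)

    def test_design_counts_runs(self):
        system = linear_system([[-1.0]], B=[[1.0]], C=[[1.0]])
        design = _design(n=6)
        cr.empirical_controllability_gramian(system, design, x_star=np.zeros(1))
        assert design.n_sims == 6


class TestObservabilityGramian:
    def test_scalar_system_matches_lyapunov_half(self):
        system = linear_system([[-1.0]], B=[[1.0]], C=[[1.0]])
        Q = cr.empirical_observability_gramian(system, _design(), x_star=np.zeros(1))
        assert Q[0, 0] == pytest.approx(0.5, rel=0.05)

    def test_blind_output_gives_zero(self):
        system = linear_system([[-1.0]], B=[[1.0]], C=[[0.0]])
        Q = cr.empirical_observability_gramian(system, _design(), x_star=np.zeros(1))
        assert np.allclose(Q, 0.0)

    def test_conservation_is_respected_in_perturbed_runs(self, phosphorelay_reduced):
        """Initial-condition perturbations recompute conserved totals, so
        every perturbed trajectory stays exactly on its own conservation
        manifold."""
        full, reduced, cons, _ = phosphorelay_reduced
        x_star_r = cr.find_steady_state(reduced)
        full_star = reduced.lift(x_star_r)
        pert = reduced.pert_map()
        gamma = cons.gamma
        for i in range(reduced.n):
            full0 = full_star + 0.4 * pert[:, i]
            sys_i, z0 = reduced.rebuild(full0)
            traj = cr.simulate(sys_i, x0=z0, t_end=2.0, rtol=1e-9, atol=1e-12)
            rebuilt = np.array([sys_i.lift(x) for x in traj.states])
            totals = rebuilt @ gamma.T
            assert np.allclose(totals, gamma @ full0, rtol=1e-7, atol=1e-9)

    def test_empirical_gramians_proportional_to_lyapunov_on_lti(self):
        """On random stable LTI fixtures the empirical Gramians match the
        Lyapunov solutions after trace normalisation."""
        for seed in range(3):
            fx = cr.make_lti(seed, 4)
            system = fx.to_system()
            design = _design(seed=seed)
            P = cr.empirical_controllability_gramian(system, design, x_star=np.zeros(4))
            Q = cr.empirical_observability_gramian(system, design, x_star=np.zeros(4))
            for emp, ana in ((P, fx.analytic_P), (Q, fx.analytic_Q)):
                a = emp / np.trace(emp)
                b = ana / np.trace(ana)
                assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 0.05


class TestBalancing:
    def test_scalar_hankel_value_is_sqrt_pq(self):
        tf = cr.balancing_transform(np.array([[0.5]]), np.array([[0.32]]), 1)
        assert tf.hankel[0] == pytest.approx(np.sqrt(0.5 * 0.32), rel=1e-10)

    def test_already_balanced_diagonal_pair_gives_signed_identity(self):
        S = np.diag([4.0, 2.0, 1.0])
        tf = cr.balancing_transform(S, S, 3)
        assert np.allclose(np.abs(tf.T1), np.eye(3), atol=1e-8)
        assert np.allclose(tf.T1 @ tf.S1, np.eye(3), atol=1e-10)

    def test_random_spd_pair_is_balanced_and_diagonal(self):
        rng = np.random.default_rng(3)
        M1 = rng.standard_normal((4, 4))
        M2 = rng.standard_normal((4, 4))
        P = M1 @ M1.T + 0.1 * np.eye(4)
        Q = M2 @ M2.T + 0.1 * np.eye(4)
        tf = cr.balancing_transform(P, Q, 4)
        D = np.diag(tf.hankel)
        assert np.allclose(tf.T1 @ P @ tf.T1.T, D, rtol=1e-6, atol=1e-8 * tf.hankel[0])
        assert np.allclose(tf.S1.T @ Q @ tf.S1, D, rtol=1e-6, atol=1e-8 * tf.hankel[0])
        assert np.all(np.diff(tf.hankel) <= 1e-12)

    def test_rank_error_reports_feasible_dimension(self):
        P = np.diag([1.0, 0.5, 0.0])
        Q = np.diag([1.0, 1.0, 0.0])
        with pytest.raises(RankError) as err:
            cr.balancing_transform(P, Q, 3)
        assert err.value.max_feasible == 2
        # the suggested dimension is feasible
        tf = cr.balancing_transform(P, Q, err.value.max_feasible)
        assert tf.T1.shape == (2, 3)

    def test_hankel_invariant_under_diagonal_state_rescaling(self):
        fx = cr.make_lti(11, 4)
        d = np.array([0.5, 2.0, 1.5, 0.8])
        D = np.diag(d)
        A2 = D @ fx.A @ np.linalg.inv(D)
        B2 = D @ fx.B
        C2 = fx.C @ np.linalg.inv(D)
        import scipy.linalg

        P2 = scipy.linalg.solve_continuous_lyapunov(A2, -B2 @ B2.T)
        Q2 = scipy.linalg.solve_continuous_lyapunov(A2.T, -C2.T @ C2)
        tf1 = cr.balancing_transform(fx.analytic_P, fx.analytic_Q, 4)
        tf2 = cr.balancing_transform(P2, Q2, 4)
        assert np.allclose(tf1.hankel, tf2.hankel, rtol=1e-8)


class TestTruncate:
    def test_full_dimension_truncation_preserves_io(self):
        fx = cr.make_lti(5, 4)
        system = fx.to_system()
        tf = cr.balancing_transform(fx.analytic_P, fx.analytic_Q, 4)
        red = cr.truncate(system, tf)
        u = np.array([0.7])
        ref = cr.simulate(system, u=u, t_end=10.0, rtol=1e-10, atol=1e-13)
        cand = cr.simulate(red, u=u, t_end=10.0, rtol=1e-10, atol=1e-13)
        assert np.max(np.abs(ref.outputs - cand.outputs)) < 1e-8

    def test_l2_error_bounded_by_twice_truncated_hankel_sum(self):
        """Classical balanced-truncation bound with a unit-energy pulse:
        ||y - y_red||_2 <= 2 sum(truncated Hankel) * ||u||_2."""
        for seed in (0, 1):
            fx = cr.make_lti(seed, 5)
            system = fx.to_system()
            for n_red in (1, 3):
                tf = cr.balancing_transform(fx.analytic_P, fx.analytic_Q, n_red)
                red = cr.truncate(system, tf)
                bound = 2.0 * float(np.sum(tf.hankel_full[n_red:]))
                pulse = lambda t: np.array([1.0 if t < 1.0 else 0.0])
                t_eval = np.linspace(0.0, 40.0, 2001)
                y = cr.simulate(system, u=pulse, t_end=40.0, t_eval=t_eval).outputs
                yr = cr.simulate(red, u=pulse, t_end=40.0, t_eval=t_eval).outputs
                err_l2 = np.sqrt(np.trapezoid(((y - yr) ** 2).sum(axis=1), t_eval))
                assert err_l2 <= bound * (1 + 1e-6)


class TestImportanceIndices:
    def test_observability_index_from_sqrt_diagonal(self):
        out = cr.importance_indices(np.eye(2), np.diag([4.0, 1.0]))
        assert np.allclose(out.nu_o, [1.0, 0.5])

    def test_each_index_attains_one(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((3, 3))
        P = M @ M.T
        Q = np.diag([2.0, 1.0, 0.5])
        out = cr.importance_indices(P, Q)
        for vec in (out.nu_c, out.nu_o, out.nu):
            assert np.max(vec) == pytest.approx(1.0)
            assert np.all((vec >= 0) & (vec <= 1))

    def test_dead_state_scores_zero_everywhere(self):
        P = np.diag([1.0, 0.0])
        Q = np.diag([1.0, 0.0])
        out = cr.importance_indices(P, Q)
        assert out.nu_c[1] == out.nu_o[1] == out.nu[1] == 0.0

    def test_zero_gramian_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            cr.importance_indices(np.zeros((2, 2)), np.eye(2))

    def test_lumped_kinase_block_carries_the_input_signal(
        self, phosphorelay_reduced, step_protocol
    ):
        """The lumped variable containing the phosphorylated kinase is the
        most controllable state and tops the combined input-output index."""
        _, reduced, _, _ = phosphorelay_reduced
        scheme = cr.forward_selection_lump(
            reduced, cr.LumpConfig(max_error=0.05, chi_c=250.0, protocol=step_protocol)
        )
        lumped = cr.galerkin_reduce(reduced, scheme.L, scheme.L_bar)
        design = cr.PerturbationDesign.sample(seed=0, horizon=8.0)
        x_star = cr.find_steady_state(lumped)
        P = cr.empirical_controllability_gramian(lumped, design, x_star=x_star)
        Q = cr.empirical_observability_gramian(lumped, design, x_star=x_star)
        out = cr.importance_indices(P, Q, labels=lumped.names)
        top = int(np.argmax(out.nu))
        assert "A_P" in out.labels[top] and "+" in out.labels[top]
        assert out.nu[top] == 1.0 and out.nu_c[top] == 1.0
        for vec in (out.nu_c, out.nu_o, out.nu):
            assert np.max(vec) == pytest.approx(1.0)
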