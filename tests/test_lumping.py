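"""Lumping matrices, generalised inverses and forward selection."""

import math

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import crnreduce as cr
from crnreduce.errors import DegeneratePairError, SingularityError

from conftest import linear_system, make_ab_network


class TestInverses:
    def test_moore_penrose_pair_weights(self):
        L = np.array([[1.0, 1.0]])
        assert np.allclose(cr.moore_penrose_inverse(L), [[0.5], [0.5]])

    def test_moore_penrose_identity(self):
        assert np.allclose(cr.moore_penrose_inverse(np.eye(3)), np.eye(3))

    def test_moore_penrose_block_of_four_is_uniform(self):
        L = np.ones((1, 4))
        assert np.allclose(cr.moore_penrose_inverse(L), 0.25)

    def test_steady_state_weights_proportional_to_x_star(self):
        L = np.array([[1.0, 1.0]])
        Lbar = cr.steady_state_inverse(L, np.array([1.0, 3.0]))
        assert np.allclose(Lbar, [[0.25], [0.75]])
        # reconstructs the steady state exactly
        assert np.allclose(Lbar @ (L @ np.array([1.0, 3.0])), [1.0, 3.0])

    def test_unlumped_species_gets_weight_one(self):
        L = cr.pair_lumping_matrix(3, 0, 1)
        Lbar = cr.steady_state_inverse(L, np.array([1.0, 3.0, 5.0]))
        assert Lbar[2, 1] == pytest.approx(1.0)

    def test_zero_steady_state_block_is_singular(self):
        L = np.array([[1.0, 1.0]])
        with pytest.raises(SingularityError):
            cr.steady_state_inverse(L, np.zeros(2))

    def test_averaged_weights_for_constant_ratio(self):
        t = np.linspace(0, 10, 500)
        xk = np.exp(-0.3 * t) + 0.5
        xh = 2.0 * xk
        traj = cr.Trajectory(times=t, states=np.column_stack([xh, xk]),
                             outputs=xh[:, None])
        Lbar = cr.averaged_inverse(cr.pair_lumping_matrix(2, 0, 1), traj, 10.0)
        assert np.allclose(Lbar.ravel(), [2 / 3, 1 / 3], atol=1e-9)

    def test_averaged_weights_for_symmetric_pair(self):
        t = np.linspace(0, 5, 200)
        x = np.exp(-t)[:, None] * np.ones((1, 2))
        traj = cr.Trajectory(times=t, states=x, outputs=x[:, :1])
        Lbar = cr.averaged_inverse(cr.pair_lumping_matrix(2, 0, 1), traj, 5.0)
        assert np.allclose(Lbar.ravel(), [0.5, 0.5])

    def test_averaged_tends_to_steady_state_inverse(self):
        net = make_ab_network(k1=1.0, k2=3.0, a0=2.0, b0=0.0)
        system = cr.build_state_space(net, cr.InputOutputSpec([], "A+B"))
        x_star = cr.find_steady_state(system)
        L = cr.pair_lumping_matrix(2, 0, 1)
        ss = cr.steady_state_inverse(L, x_star)
        gaps = []
        for T in (5.0, 50.0, 500.0):
            traj = cr.simulate(system, t_end=T, t_eval=np.linspace(0, T, 4001),
                               rtol=1e-10, atol=1e-13)
            avg = cr.averaged_inverse(L, traj, T)
            gaps.append(np.max(np.abs(avg - ss)))
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 1e-3

    def test_degenerate_pair_raises(self):
        t = np.linspace(0, 1, 50)
        states = np.zeros((50, 2))
        traj = cr.Trajectory(times=t, states=states, outputs=np.ones((50, 1)))
        with pytest.raises(DegeneratePairError):
            cr.averaged_inverse(cr.pair_lumping_matrix(2, 0, 1), traj, 1.0)


class TestCompose:
    def test_three_into_one_via_two_pairwise_lumps(self):
        inner = cr.LumpingScheme(
            L=np.array([[1, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]]),
            L_bar=cr.moore_penrose_inverse(
                np.array([[1, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
            ),
        )
        outer = cr.LumpingScheme(
            L=np.array([[1, 1, 0], [0, 0, 1.0]]),
            L_bar=cr.moore_penrose_inverse(np.array([[1, 1, 0], [0, 0, 1.0]])),
        )
        total = cr.compose_lumpings(outer, inner)
        assert total.L.tolist() == [[1, 1, 1, 0], [0, 0, 0, 1]]
        assert np.allclose(total.L @ total.L_bar, np.eye(2))

    def test_composition_with_identity_is_unchanged(self):
        scheme = cr.LumpingScheme(
            L=cr.pair_lumping_matrix(3, 0, 2),
            L_bar=cr.moore_penrose_inverse(cr.pair_lumping_matrix(3, 0, 2)),
        )
        total = cr.compose_lumpings(scheme, cr.LumpingScheme.identity(3))
        assert np.array_equal(total.L, scheme.L)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 8))
    def test_random_pairwise_chains_stay_proper_with_right_inverse(self, seed, n):
        rng = np.random.default_rng(seed)
        scheme = cr.LumpingScheme.identity(n)
        dim = n
        while dim > 2:
            h = int(rng.integers(dim - 1))
            k = int(rng.integers(h + 1, dim))
            L = cr.pair_lumping_matrix(dim, h, k)
            step = cr.LumpingScheme(L=L, L_bar=cr.moore_penrose_inverse(L))
            scheme = cr.compose_lumpings(step, scheme)
            dim -= 1
        scheme.validate()  # 0/1, column-orthogonal, L Lbar = I
        assert np.allclose(scheme.L.sum(axis=0), 1.0)


class TestGalerkin:
    def test_identity_projection_preserves_dynamics(self, phosphorelay):
        _, _, system = phosphorelay
        ident = cr.galerkin_reduce(system, np.eye(system.n), np.eye(system.n))
        t1 = cr.simulate(system, t_end=3.0, rtol=1e-10, atol=1e-13)
        t2 = cr.simulate(ident, t_end=3.0, rtol=1e-10, atol=1e-13)
        assert np.max(np.abs(t1.states - t2.states)) < 1e-10

    def test_left_eigenvector_lump_of_linear_system_is_exact(self):
        # (1,1) is a left eigenvector of the exchange-symmetric block, so
        # the lumped total evolves autonomously and the output error is zero
        A = np.array([[-2.0, 1.0, 0.3], [1.0, -2.0, 0.3], [0.0, 0.0, -1.0]])
        system = linear_system(A, C=np.array([[1.0, 1.0, 0.0]]),
                               x0=np.array([2.0, 0.5, 1.0]))
        L = cr.pair_lumping_matrix(3, 0, 1)
        lumped = cr.galerkin_reduce(system, L, cr.moore_penrose_inverse(L))
        ref = cr.simulate(system, t_end=4.0, rtol=1e-10, atol=1e-13)
        cand = cr.simulate(lumped, t_end=4.0, rtol=1e-10, atol=1e-13)
        assert cr.max_relative_error(ref, cand).E < 1e-8

    def test_lumped_state_names_record_membership(self, phosphorelay):
        _, _, system = phosphorelay
        L = cr.pair_lumping_matrix(system.n, 1, 3)
        lumped = cr.galerkin_reduce(system, L, cr.moore_penrose_inverse(L))
        assert f"{system.names[1]}+{system.names[3]}" in lumped.names


class TestForwardSelection:
    def test_zero_budget_returns_identity(self, phosphorelay_reduced, step_protocol):
        _, reduced, _, _ = phosphorelay_reduced
        scheme = cr.forward_selection_lump(
            reduced, cr.LumpConfig(max_error=0.0, protocol=step_protocol)
        )
        assert scheme.ntilde == reduced.n
        assert not scheme.history

    def test_fast_pair_is_lumped_first_on_three_state_chain(self):
        # A -> B <-> C with the B/C exchange 100x faster: (B, C) is the
        # fast-equilibrating pair and must be the first choice
        A = np.array(
            [[-1.0, 0.0, 0.0], [1.0, -100.0, 100.0], [0.0, 100.0, -100.0 - 0.5]]
        )
        system = linear_system(
            A, B=np.array([[1.0], [0.0], [0.0]]),
            C=np.array([[0.0, 1.0, 1.0]]),
            x0=np.array([1.0, 0.4, 0.4]),
        )
        proto = cr.Protocol(u=np.array([1.0]), t_end=10.0)
        scheme = cr.forward_selection_lump(
            system, cr.LumpConfig(max_error=0.05, chi_c=1.5, protocol=proto)
        )
        assert scheme.history[0].pair == (1, 2)

    def test_greedy_step_matches_brute_force_minimiser(
        self, phosphorelay_reduced, step_protocol
    ):
        """The chosen (pair, inverse) equals an independent exhaustive
        search over all candidates at the first step."""
        _, reduced, _, x_star = phosphorelay_reduced
        x_star_r = cr.find_steady_state(reduced)
        ref = cr.simulate(
            reduced, u=step_protocol.u_fn(reduced), t_end=step_protocol.t_end,
            t_eval=step_protocol.times(),
        )
        T = 8.0
        unpert = cr.simulate(reduced, t_end=T, t_eval=np.linspace(0, T, 201))
        best = (math.inf, None)
        for h in range(reduced.n - 1):
            for k in range(h + 1, reduced.n):
                L = cr.pair_lumping_matrix(reduced.n, h, k)
                for label, Lbar in (
                    ("steady-state", cr.steady_state_inverse(L, x_star_r)),
                    ("averaged", cr.averaged_inverse(L, unpert, T)),
                ):
                    cand = cr.galerkin_reduce(reduced, L, Lbar)
                    try:
                        traj = cr.simulate(
                            cand, u=step_protocol.u_fn(cand),
                            t_end=step_protocol.t_end, t_eval=step_protocol.times(),
                        )
                        E = cr.max_relative_error(ref, traj).E
                    except cr.errors.BlowUpError:
                        E = math.inf
                    if E < best[0]:
                        best = (E, (h, k))
        scheme = cr.forward_selection_lump(
            reduced,
            cr.LumpConfig(max_error=0.05, chi_c=250.0, protocol=step_protocol, T_avg=T),
        )
        assert scheme.history[0].pair == best[1]
        assert scheme.history[0].error <= best[0] * (1 + 1e-6) + 1e-12

    def test_stiffness_nonincreasing_and_stop_below_chi_c(
        self, phosphorelay_reduced, step_protocol
    ):
        _, reduced, _, _ = phosphorelay_reduced
        chi0 = cr.stiffness_coefficient(reduced)
        scheme = cr.forward_selection_lump(
            reduced, cr.LumpConfig(max_error=0.05, chi_c=250.0, protocol=step_protocol)
        )
        chis = [chi0] + list(scheme.per_step_chi)
        assert all(b <= a * (1 + 1e-9) for a, b in zip(chis, chis[1:]))
        assert scheme.per_step_chi[-1] < 250.0
        assert all(E <= 0.05 for E in scheme.per_step_error)

    def test_moore_penrose_never_beats_best_of_ss_and_averaged(
        self, phosphorelay_reduced, step_protocol
    ):
        _, reduced, _, _ = phosphorelay_reduced
        x_star_r = cr.find_steady_state(reduced)
        ref = cr.simulate(
            reduced, u=step_protocol.u_fn(reduced), t_end=step_protocol.t_end,
            t_eval=step_protocol.times(),
        )
        T = 8.0
        unpert = cr.simulate(reduced, t_end=T, t_eval=np.linspace(0, T, 201))

        def err(L, Lbar):
            cand = cr.galerkin_reduce(reduced, L, Lbar)
            try:
                traj = cr.simulate(
                    cand, u=step_protocol.u_fn(cand), t_end=step_protocol.t_end,
                    t_eval=step_protocol.times(),
                )
                return cr.max_relative_error(ref, traj).E
            except cr.errors.BlowUpError:
                return math.inf

        for h, k in ((0, 1), (2, 3), (1, 4)):
            L = cr.pair_lumping_matrix(reduced.n, h, k)
            e_mp = err(L, cr.moore_penrose_inverse(L))
            e_ss = err(L, cr.steady_state_inverse(L, x_star_r))
            e_av = err(L, cr.averaged_inverse(L, unpert, T))
            assert min(e_ss, e_av) <= e_mp * (1 + 1e-9)
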