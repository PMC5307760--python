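import numpy as np
import pytest
import sympy as sp

import crnreduce as cr


def make_ab_network(k1=1.0, k2=1.0, a0=2.0, b0=0.0):
    """Reversible isomerisation A <-> B; conserves A + B."""
    A, B = sp.Symbol("A"), sp.Symbol("B")
    return cr.ReactionNetwork(
        [cr.Species("A", a0), cr.Species("B", b0)],
        [cr.Reaction("iso", {"A": 1}, {"B": 1}, sp.Symbol("k1") * A - sp.Symbol("k2") * B)],
        {"k1": k1, "k2": k2},
    )


def make_enzyme_network():
    """Michaelis-Menten mechanism E + S <-> C -> E + P (two net reactions);
    conserves E + C and S + C + P."""
    E, S, C = sp.Symbol("E"), sp.Symbol("S"), sp.Symbol("C")
    return cr.ReactionNetwork(
        [
            cr.Species("E", 1.0),
            cr.Species("S", 2.0),
            cr.Species("C", 0.0),
            cr.Species("P", 0.0),
        ],
        [
            cr.Reaction(
                "bind", {"E": 1, "S": 1}, {"C": 1},
                sp.Symbol("kon") * E * S - sp.Symbol("koff") * C,
            ),
            cr.Reaction("cat", {"C": 1}, {"E": 1, "P": 1}, sp.Symbol("kcat") * C),
        ],
        {"kon": 2.0, "koff": 1.0, "kcat": 1.5},
    )


def make_decay_system(k=1.0, k_in=1.0):
    """dx/dt = -k x + u with h = x: first-order decay driven by an
    additive-rate input on the production parameter."""
    X = sp.Symbol("X")
    net = cr.ReactionNetwork(
        [cr.Species("X", 1.0)],
        [
            cr.Reaction("prod", {}, {"X": 1}, sp.Symbol("k_in")),
            cr.Reaction("deg", {"X": 1}, {}, sp.Symbol("k") * X),
        ],
        {"k": k, "k_in": k_in},
    )
    spec = cr.InputOutputSpec([("k_in", "additive-rate")], "X")
    return net, spec, cr.build_state_space(net, spec)


def linear_system(A, B=None, C=None, x0=None, u0=None):
    """ControlledSystem for xdot = A x + B u, y = C x."""
    A = np.atleast_2d(np.asarray(A, float))
    n = A.shape[0]
    B = np.zeros((n, 0)) if B is None else np.atleast_2d(np.asarray(B, float))
    C = np.eye(n) if C is None else np.atleast_2d(np.asarray(C, float))
    syms = sp.symbols(f"_x0:{n}")
    f = [sp.Add(*[sp.Float(A[i, j]) * syms[j] for j in range(n)]) for i in range(n)]
    g = sp.Matrix([[sp.Float(B[i, j]) for j in range(B.shape[1])] for i in range(n)]) \
        if B.shape[1] else sp.zeros(n, 0)
    h = [sp.Add(*[sp.Float(C[i, j]) * syms[j] for j in range(n)]) for i in range(C.shape[0])]
    return cr.ControlledSystem(
        syms, f, g, h,
        x0=np.zeros(n) if x0 is None else x0,
        u0=np.zeros(B.shape[1]) if u0 is None else u0,
    )


@pytest.fixture(scope="session")
def phosphorelay():
    net, spec = cr.make_phosphorelay(stiff_ratio=1000.0)
    system = cr.build_state_space(net, spec)
    return net, spec, system


@pytest.fixture(scope="session")
def phosphorelay_reduced(phosphorelay):
    """Speed-ranked, conservation-eliminated realisation of the
    phosphorelay (5 states) plus the full system and its steady state."""
    net, spec, system = phosphorelay
    x_star = cr.find_steady_state(system)
    gamma = cr.left_null_space(cr.stoichiometry_matrix(net))
    ranking = cr.speed_rank(system, x_star)
    cons = cr.select_eliminations(gamma, system.x0, ranking)
    reduced = cr.eliminate_states(system, cons, ranking).system
    return system, reduced, cons, x_star


@pytest.fixture(scope="session")
def step_protocol():
    return cr.Protocol(u=np.array([1.0]), t_end=8.0)
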