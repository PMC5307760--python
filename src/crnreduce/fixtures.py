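"""Synthetic model generators with analytic oracles.

Everything a reduction stage needs for testing without downloading a
model:

* random stable LTI systems with exact Lyapunov Gramians and Hankel
  spectra (the oracle for empirical Gramians and balanced truncation);
* closed mass-action networks with a prescribed number of conserved
  moieties (conversion cycles coupled by catalytic reactions);
* a ligand-controlled kinase/phosphotransfer/phosphatase chain whose
  phosphotransfer block runs ``stiff_ratio`` times faster than the rest —
  a miniature of receptor-signalling models: stiff, conserved, with a
  fast-equilibrating pair that proper lumping should absorb first.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import sympy as sp

from .errors import GenerationError
from .model_core import (
    ControlledSystem,
    InputOutputSpec,
    Reaction,
    ReactionNetwork,
    Species,
    stoichiometry_matrix,
)

__all__ = ["LTIFixture", "make_lti", "make_conserved_network", "make_phosphorelay"]


@dataclass
class LTIFixture:
    """Stable LTI triple (A, B, C) with its analytic Gramians.

    ``analytic_P`` and ``analytic_Q`` solve ``A P + P A^T + B B^T = 0`` and
    ``A^T Q + Q A + C^T C = 0``; ``hankel`` is ``sqrt(eig(P Q))`` sorted
    non-increasing.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    analytic_P: np.ndarray
    analytic_Q: np.ndarray
    hankel: np.ndarray

    def to_system(self) -> ControlledSystem:
        """The fixture as a control-affine system with x0 = 0, u0 = 0."""
        n, l = self.B.shape
        p = self.C.shape[0]
        syms = sp.symbols(f"_x0:{n}")
        f = [
            sp.Add(*[sp.Float(self.A[i, j]) * syms[j] for j in range(n)])
            for i in range(n)
        ]
        g = sp.Matrix([[sp.Float(self.B[i, j]) for j in range(l)] for i in range(n)])
        h = [
            sp.Add(*[sp.Float(self.C[i, j]) * syms[j] for j in range(n)])
            for i in range(p)
        ]
        return ControlledSystem(
            syms, f, g, h, x0=np.zeros(n), u0=np.zeros(l),
            names=[f"x{i}" for i in range(n)],
        )


def make_lti(seed: int, n: int, stability_margin: float = 0.5, l: int = 1, p: int = 1) -> LTIFixture:
    """Random stable LTI fixture with eigenvalues left of
    ``-stability_margin`` and exact Lyapunov Gramians attached."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n)) / np.sqrt(n)
    shift = max(np.real(np.linalg.eigvals(A)).max(), 0.0) + stability_margin
    A = A - shift * np.eye(n)
    B = rng.standard_normal((n, l))
    C = rng.standard_normal((p, n))
    P = scipy.linalg.solve_continuous_lyapunov(A, -B @ B.T)
    Q = scipy.linalg.solve_continuous_lyapunov(A.T, -C.T @ C)
    P = 0.5 * (P + P.T)
    Q = 0.5 * (Q + Q.T)
    hank = np.sqrt(np.clip(np.real(np.linalg.eigvals(P @ Q)), 0.0, None))
    hank = np.sort(hank)[::-1]
    return LTIFixture(A=A, B=B, C=C, analytic_P=P, analytic_Q=Q, hankel=hank)


def make_conserved_network(
    seed: int, n_species: int, n_moieties: int, max_tries: int = 20
) -> ReactionNetwork:
    """Closed mass-action network with exactly ``n_moieties`` conserved
    moieties.

    Species are partitioned into ``n_moieties`` conversion cycles (each a
    closed chain ``A1 <-> A2 <-> ... <-> Am``, conserving its group total);
    cycles are coupled by catalytic cross-reactions (a species of one group
    catalyses a conversion in another), which add nonlinearity without
    breaking any conservation.  The left-null dimension is verified and the
    network resampled until it holds.
    """
    if n_moieties < 1 or n_species < 2 * n_moieties:
        raise GenerationError(
            f"need n_species >= 2*n_moieties, got ({n_species}, {n_moieties})"
        )
    rng = np.random.default_rng(seed)
    from .conservation import left_null_space

    for _ in range(max_tries):
        sizes = np.full(n_moieties, 2)
        for _extra in range(n_species - 2 * n_moieties):
            sizes[rng.integers(n_moieties)] += 1
        species, reactions, params = [], [], {}
        groups = []
        idx = 0
        for gnum, size in enumerate(sizes):
            members = []
            for j in range(size):
                sid = f"S{gnum}_{j}"
                species.append(Species(sid, float(rng.uniform(0.5, 2.0))))
                members.append(sid)
            groups.append(members)
            for j in range(size - 1):
                a, b = members[j], members[j + 1]
                kf, kr = f"kf{idx}", f"kr{idx}"
                params[kf] = float(rng.lognormal(0.0, 0.5))
                params[kr] = float(rng.lognormal(0.0, 0.5))
                rate = sp.Symbol(kf) * sp.Symbol(a) - sp.Symbol(kr) * sp.Symbol(b)
                reactions.append(Reaction(f"r{idx}", {a: 1}, {b: 1}, rate))
                idx += 1
        # catalytic couplings between distinct groups
        if n_moieties > 1:
            for gnum in range(n_moieties - 1):
                cat = groups[gnum][0]
                tgt = groups[gnum + 1]
                kc = f"kc{idx}"
                params[kc] = float(rng.lognormal(0.0, 0.5))
                rate = sp.Symbol(kc) * sp.Symbol(cat) * sp.Symbol(tgt[0])
                reactions.append(Reaction(f"r{idx}", {tgt[0]: 1}, {tgt[1]: 1}, rate))
                idx += 1
        net = ReactionNetwork(species, reactions, params)
        gamma = left_null_space(stoichiometry_matrix(net))
        if gamma.shape[0] == n_moieties:
            return net
    raise GenerationError(
        f"could not realise a ({n_species}, {n_moieties}) conserved network"
    )


#: default slow-block rate constants of the phosphorelay (1/time or
#: 1/(conc*time)); the fast phosphotransfer/phosphatase block multiplies
#: the starred entries by ``stiff_ratio``.
PHOSPHORELAY_RATES = {
    "k_auto": 0.6,     # A -> A_P basal autophosphorylation
    "k_in": 0.1,       # input-controlled extra autophosphorylation (baseline u0)
    "k_bind": 0.8,     # * A_P + Y -> A_P_Y
    "k_unbind": 0.4,   # * A_P_Y -> A_P + Y
    "k_trans": 1.2,    # * A_P_Y -> A + Y_P (phosphotransfer)
    "k_zbind": 0.8,    # * Y_P + Z -> Y_P_Z
    "k_zunbind": 0.4,  # * Y_P_Z -> Y_P + Z
    "k_dephos": 1.0,   # * Y_P_Z -> Y + Z
    "k_bact": 0.4,     # A_P + B -> A_P + B_P (slow adaptation branch)
    "k_brev": 0.3,     # B_P -> B
    "k_fb": 0.5,       # B_P + A_P -> B_P + A (feedback dephosphorylation)
}

_FAST = ("k_bind", "k_unbind", "k_trans", "k_zbind", "k_zunbind", "k_dephos")


def make_phosphorelay(rates=None, stiff_ratio: float = 1000.0):
    """Ligand-controlled phosphorelay: kinase A, response regulator Y,
    phosphatase Z and a slow adaptation enzyme B.

    Returns ``(network, spec)`` where the input channel is the
    ligand-modulated autophosphorylation rate (additive-rate mode on the
    parameter ``k_in``, baseline ``u0`` = its nominal value) and the output
    is the total phosphorylated response regulator, free and in complex
    (``Y_P + Y_P_Z``).

    The phosphotransfer and phosphatase reactions run ``stiff_ratio`` times
    faster than the autophosphorylation/adaptation block, so the stiffness
    coefficient at the initial condition grows with ``stiff_ratio`` and the
    phosphorylated kinase and its transfer complex (A_P, A_P_Y) reach
    proportional equilibrium almost immediately — the designated lumpable
    fast pair.  Four moieties are conserved: total A, total Y, total Z,
    total B.
    """
    if stiff_ratio < 1:
        raise ValueError("stiff_ratio must be >= 1")
    base = dict(PHOSPHORELAY_RATES)
    if rates:
        base.update(rates)
    params = {
        k: (v * stiff_ratio if k in _FAST else v) for k, v in base.items()
    }

    S = sp.Symbol
    species = [
        Species("A", 0.8),
        Species("A_P", 0.15),
        Species("A_P_Y", 0.05),
        Species("Y", 1.5),
        Species("Y_P", 0.3),
        Species("Z", 0.45),
        Species("Y_P_Z", 0.05),
        Species("B", 0.35),
        Species("B_P", 0.05),
    ]
    reactions = [
        Reaction("auto", {"A": 1}, {"A_P": 1}, (S("k_auto") + S("k_in")) * S("A")),
        Reaction("bind", {"A_P": 1, "Y": 1}, {"A_P_Y": 1}, S("k_bind") * S("A_P") * S("Y")),
        Reaction("unbind", {"A_P_Y": 1}, {"A_P": 1, "Y": 1}, S("k_unbind") * S("A_P_Y")),
        Reaction("trans", {"A_P_Y": 1}, {"A": 1, "Y_P": 1}, S("k_trans") * S("A_P_Y")),
        Reaction("zbind", {"Y_P": 1, "Z": 1}, {"Y_P_Z": 1}, S("k_zbind") * S("Y_P") * S("Z")),
        Reaction("zunbind", {"Y_P_Z": 1}, {"Y_P": 1, "Z": 1}, S("k_zunbind") * S("Y_P_Z")),
        Reaction("dephos", {"Y_P_Z": 1}, {"Y": 1, "Z": 1}, S("k_dephos") * S("Y_P_Z")),
        Reaction("bact", {"B": 1}, {"B_P": 1}, S("k_bact") * S("A_P") * S("B")),
        Reaction("brev", {"B_P": 1}, {"B": 1}, S("k_brev") * S("B_P")),
        Reaction("fb", {"A_P": 1}, {"A": 1}, S("k_fb") * S("B_P") * S("A_P")),
    ]
    network = ReactionNetwork(species, reactions, params)
    spec = InputOutputSpec(
        inputs=[("k_in", "additive-rate")],
        output_expression="Y_P + Y_P_Z",
    )
    return network, spec
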