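"""Conserved-moiety analysis and speed-ranked state elimination.

A conserved moiety is a weighted sum of species concentrations that is
constant along every trajectory of a closed network — a left-null vector of
the stoichiometry matrix N.  The rank of N is decided by a column-pivoted
Householder QR (the numerically stable route for large models where naive
Gaussian elimination can miss relations or invent spurious ones); the null
basis itself is then computed exactly over the rationals, since N is
integer, and rescaled to smallest-integer form.

Eliminating one species per relation gives a lower-dimensional realisation
with identical dynamics and a non-singular Jacobian.  Which species to
eliminate matters downstream: fast species should stay explicit so that
lumping can absorb them, so species are "speed ranked" by the magnitude of
the Jacobian diagonal at the unperturbed steady state (the outgoing rate of
concentration from each state-variable) and the *slowest* are eliminated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import sympy as sp

from .errors import EliminationInfeasibleError
from .model_core import ConservationLineage, ControlledSystem

__all__ = [
    "ConservationSet",
    "ReducedRealisation",
    "left_null_space",
    "speed_rank",
    "select_eliminations",
    "eliminate_states",
]


def left_null_space(N, rank_tol: float = 1e-9) -> np.ndarray:
    """Integer basis of the left null space of the stoichiometry matrix.

    The rank is decided from the diagonal of the column-pivoted Householder
    QR of ``N^T`` (``|R_kk| > rank_tol * |R_11|``); the basis is then taken
    from the exact rational null space of ``N^T`` and scaled to the smallest
    integer form with a positive leading entry.  Returns a (c x n) integer
    array; c may be zero.
    """
    N = np.asarray(N)
    n = N.shape[0]
    if N.size == 0 or N.shape[1] == 0:
        return np.eye(n, dtype=int)
    _, R, _ = scipy.linalg.qr(N.T.astype(float), mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank_qr = int(np.sum(diag > rank_tol * (diag[0] if diag.size else 1.0)))
    c_expected = n - rank_qr

    basis = sp.Matrix(N.astype(int)).T.nullspace()
    if len(basis) != c_expected:
        warnings.warn(
            f"QR rank estimate gives {c_expected} conservation relations but the "
            f"exact null space has {len(basis)}; using the exact count",
            stacklevel=2,
        )
    rows = []
    for vec in basis:
        lcm = 1
        for v in vec:
            lcm = sp.ilcm(lcm, int(sp.nsimplify(v).q))
        ints = [int(sp.Integer(v * lcm)) for v in vec]
        g = 0
        for v in ints:
            g = sp.igcd(g, abs(v))
        g = int(g) or 1
        ints = [v // g for v in ints]
        lead = next((v for v in ints if v != 0), 1)
        if lead < 0:
            ints = [-v for v in ints]
        rows.append(ints)
    if not rows:
        return np.zeros((0, n), dtype=int)
    gamma = _sparsify_rows(np.array(rows, dtype=int))
    # invariant: gamma spans the left null space
    if N.shape[1] and np.max(np.abs(gamma @ N)) > 0:
        raise AssertionError("computed basis is not a left null space")
    return gamma


def _sparsify_rows(gamma: np.ndarray) -> np.ndarray:
    """Greedy integer row combinations to minimise the support of each
    basis row; recovers natural moiety vectors (sparse, usually
    non-negative) from an arbitrary rational null basis."""

    def canon(row):
        g = 0
        for v in row:
            g = sp.igcd(g, abs(int(v)))
        g = int(g) or 1
        row = row // g
        lead = next((v for v in row if v != 0), 1)
        return -row if lead < 0 else row

    gamma = gamma.copy()
    c = gamma.shape[0]
    changed = True
    iters = 0
    while changed and iters < 10 * max(c, 1):
        changed = False
        iters += 1
        for a in range(c):
            for b in range(c):
                if a == b:
                    continue
                for coeff in (1, -1, 2, -2):
                    cand = gamma[a] + coeff * gamma[b]
                    better = np.count_nonzero(cand) < np.count_nonzero(gamma[a])
                    same_support_nicer = (
                        np.count_nonzero(cand) == np.count_nonzero(gamma[a])
                        and np.all(cand >= 0)
                        and not np.all(gamma[a] >= 0)
                    )
                    if np.any(cand) and (better or same_support_nicer):
                        gamma[a] = canon(cand)
                        changed = True
    return np.array([canon(r) for r in gamma], dtype=int)


def speed_rank(system: ControlledSystem, x_star=None) -> list:
    """Indices of the state variables sorted slow -> fast by ``|J_ii|`` at
    the unperturbed steady state (falls back to the initial condition, with
    a warning, when no steady state is supplied).  Ties keep declaration
    order."""
    if x_star is None:
        warnings.warn(
            "no steady state supplied; speed ranking evaluated at x0", stacklevel=2
        )
        x_star = system.x0
    diag = np.abs(np.diag(system.jac(np.asarray(x_star, float))))
    return list(np.argsort(diag, kind="stable"))


@dataclass
class ConservationSet:
    """Left-null vectors, conserved totals, and the species chosen for
    elimination.

    ``gamma`` is (c x n); ``totals = gamma @ x0``; the c x c sub-matrix of
    gamma on ``eliminated_indices`` must be invertible for the elimination
    to be well posed.
    """

    gamma: np.ndarray
    totals: np.ndarray
    eliminated_indices: list
    retained_indices: list

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, float)
        self.totals = np.asarray(self.totals, float)
        c = self.gamma.shape[0]
        if len(self.eliminated_indices) != c:
            raise ValueError("one eliminated species per relation required")
        sub = self.gamma[:, self.eliminated_indices]
        if c and abs(np.linalg.det(sub)) < 1e-12:
            raise ValueError("eliminated sub-matrix of gamma is singular")

    def to_frame(self, names=None) -> pd.DataFrame:
        """Conservation relations as a table (relation, coefficients, total)."""
        n = self.gamma.shape[1]
        names = names or [f"x{i}" for i in range(n)]
        recs = []
        for k in range(self.gamma.shape[0]):
            terms = " + ".join(
                (f"{int(cf)}*" if cf != 1 else "") + names[i]
                for i, cf in enumerate(self.gamma[k])
                if cf != 0
            )
            recs.append({"relation": k, "members": terms, "total": self.totals[k]})
        return pd.DataFrame(recs)


def select_eliminations(gamma, x0, ranking=None) -> ConservationSet:
    """Assign one species to eliminate per conservation relation.

    Relations are processed most-constrained first (fewest candidate
    species); within a relation the slowest not-yet-chosen species with a
    nonzero coefficient is taken, skipping choices that would make the
    eliminated sub-matrix rank-deficient.
    """
    gamma = np.asarray(gamma, float)
    c, n = gamma.shape
    x0 = np.asarray(x0, float)
    ranking = list(ranking) if ranking is not None else list(range(n))
    priority = {idx: pos for pos, idx in enumerate(ranking)}

    order = sorted(range(c), key=lambda k: int(np.sum(gamma[k] != 0)))
    chosen: dict = {}
    used: set = set()
    picked_cols: list = []
    for k in order:
        candidates = [i for i in range(n) if gamma[k, i] != 0 and i not in used]
        candidates.sort(key=lambda i: priority.get(i, n))
        picked = None
        for i in candidates:
            trial = picked_cols + [i]
            sub = gamma[:, trial]
            if np.linalg.matrix_rank(sub) == len(trial):
                picked = i
                break
        if picked is None:
            raise EliminationInfeasibleError(
                f"no admissible species to eliminate for relation {k} "
                f"(coefficients {gamma[k]})"
            )
        chosen[k] = picked
        used.add(picked)
        picked_cols.append(picked)
    eliminated = [chosen[k] for k in range(c)]
    retained = [i for i in range(n) if i not in used]
    return ConservationSet(
        gamma=gamma,
        totals=gamma @ x0,
        eliminated_indices=eliminated,
        retained_indices=retained,
    )


@dataclass
class ReducedRealisation:
    """Conservation-eliminated system plus the affine reconstruction of the
    full state from retained states and conserved totals."""

    system: ControlledSystem
    conservation: ConservationSet

    def reconstruct(self, states) -> np.ndarray:
        """Full-state trajectory (or single state) from reduced states."""
        states = np.asarray(states, float)
        lineage = self.system.lineage
        totals = self.system.extra_vals[-lineage.c:]
        if states.ndim == 1:
            return lineage.assemble(states, totals)
        return np.array([lineage.assemble(x, totals) for x in states])


def eliminate_states(
    system: ControlledSystem, conservation: ConservationSet, ranking=None
) -> ReducedRealisation:
    """Substitute the conservation relations into f, g and h, removing one
    species per relation.

    If ``conservation`` carries no elimination choice consistent with
    ``ranking``, call :func:`select_eliminations` first.  Conserved totals
    become symbolic values bound at evaluation time, so later perturbations
    of the full initial condition update them automatically.
    """
    gamma = conservation.gamma
    c, n = gamma.shape
    if n != system.n:
        raise ValueError("conservation set does not match system dimension")
    if c == 0:
        return ReducedRealisation(system=system, conservation=conservation)
    elim = conservation.eliminated_indices
    ret = conservation.retained_indices

    ge = sp.Matrix(gamma)[:, elim]
    ge_inv = ge.inv()
    gr = sp.Matrix(gamma)[:, ret]
    total_syms = [sp.Symbol(f"_T{k}") for k in range(c)]
    x_ret = sp.Matrix([system.syms[i] for i in ret])
    x_elim_expr = ge_inv * (sp.Matrix(total_syms) - gr * x_ret)
    subs = {system.syms[e]: sp.expand(x_elim_expr[k]) for k, e in enumerate(elim)}

    f_new = [sp.expand(system.f_exprs[i].xreplace(subs)) for i in ret]
    g_new = sp.Matrix(
        [[sp.expand(system.g_exprs[i, j].xreplace(subs)) for j in range(system.l)] for i in ret]
    ) if system.l else sp.zeros(len(ret), 0)
    h_new = [sp.expand(e.xreplace(subs)) for e in system.h_exprs]

    lineage = ConservationLineage(
        system, gamma, elim, ret, np.asarray(ge_inv, float)
    )
    reduced = ControlledSystem(
        syms=[system.syms[i] for i in ret],
        f_exprs=f_new,
        g_exprs=g_new,
        h_exprs=h_new,
        x0=system.x0[ret],
        u0=system.u0,
        names=[system.names[i] for i in ret],
        extra_syms=tuple(system.extra_syms) + tuple(total_syms),
        extra_vals=np.concatenate([system.extra_vals, gamma @ system.x0]),
        species_names=system.species_names,
        lineage=lineage,
        time_scale=system.time_scale,
    )
    return ReducedRealisation(system=reduced, conservation=conservation)
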