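"""Proper lumping by greedy forward selection under the Galerkin projection.

A proper lumping is a 0/1 projection ``x~ = L x`` in which every original
state contributes to at most one lumped state, so lumped variables remain
sums of species concentrations.  Reduced dynamics follow from the Galerkin
projection

.. math::

    \\dot{\\tilde x} = L f(\\bar L \\tilde x)
        + \\sum_i L g_i(\\bar L \\tilde x) u_i,
    \\qquad \\tilde y = h(\\bar L \\tilde x),

for any generalised right-inverse ``Lbar`` with ``L Lbar = I``.  Three
inverses are provided:

* Moore-Penrose — equal weights within a block;
* steady-state reconstructing — weights proportional to the unperturbed
  steady state (singular when a block's steady state is all zero);
* time-averaged — weights are the average proportion each member carries of
  the pair total over an equilibration window [0, T]; tends to the
  steady-state inverse as T grows when the steady state is nonzero, but
  stays finite when it is zero.

Forward selection lumps one pair per step, trying the steady-state and
averaged inverse for every pair, scoring each candidate by the maximal
relative output error against the unlumped reference under a user-supplied
perturbation protocol, and keeping the best.  The loop exits when the next
lump would exceed the error budget, when the stiffness coefficient drops
below the critical value, or at one state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .errors import (
    BlowUpError,
    DegeneratePairError,
    NonConvergenceError,
    SingularityError,
)
from .model_core import ControlledSystem, ProjectionLineage
from .simulation import (
    Protocol,
    Trajectory,
    find_steady_state,
    max_relative_error,
    simulate,
    stiffness_coefficient,
)

__all__ = [
    "LumpingScheme",
    "LumpStep",
    "LumpConfig",
    "pair_lumping_matrix",
    "galerkin_reduce",
    "moore_penrose_inverse",
    "steady_state_inverse",
    "averaged_inverse",
    "compose_lumpings",
    "forward_selection_lump",
]


@dataclass
class LumpStep:
    """One accepted pairwise lump: the pair (h, k) in the coordinates of the
    step, the inverse variant chosen, and the error/stiffness after it."""

    pair: tuple
    inverse: str
    error: float
    chi: float


@dataclass
class LumpingScheme:
    """Cumulative proper lumping ``L`` (ntilde x n), generalised inverse
    ``L_bar`` (n x ntilde), and the composition history of pairwise lumps."""

    L: np.ndarray
    L_bar: np.ndarray
    history: list = field(default_factory=list)
    per_step_error: list = field(default_factory=list)
    per_step_chi: list = field(default_factory=list)

    def __post_init__(self):
        self.L = np.asarray(self.L, float)
        self.L_bar = np.asarray(self.L_bar, float)
        self.validate()

    @property
    def n(self):
        return self.L.shape[1]

    @property
    def ntilde(self):
        return self.L.shape[0]

    def validate(self):
        L = self.L
        if not np.all((L == 0) | (L == 1)):
            raise ValueError("lumping matrix entries must be 0/1")
        if np.any(L.sum(axis=0) > 1):
            raise ValueError("improper lumping: a state contributes to two lumps")
        if np.any(L.sum(axis=1) < 1):
            raise ValueError("a lumped state has no members")
        resid = np.max(np.abs(L @ self.L_bar - np.eye(self.ntilde)))
        if resid > 1e-8:
            raise ValueError(f"L @ L_bar != I (residual {resid:.2e})")

    @classmethod
    def identity(cls, n):
        return cls(L=np.eye(n), L_bar=np.eye(n))

    def to_json(self) -> str:
        triplets = [
            [int(i), int(j), 1] for i, j in zip(*np.nonzero(self.L))
        ]
        return json.dumps(
            {
                "n": self.n,
                "ntilde": self.ntilde,
                "L_triplets": triplets,
                "L_bar": self.L_bar.tolist(),
                "history": [
                    {"pair": list(s.pair), "inverse": s.inverse, "error": s.error, "chi": s.chi}
                    for s in self.history
                ],
            },
            indent=1,
        )


def pair_lumping_matrix(n: int, h: int, k: int) -> np.ndarray:
    """The (n-1) x n proper lumping summing states h and k (h < k) and
    keeping every other state."""
    if not (0 <= h < k < n):
        raise ValueError(f"need 0 <= h < k < n, got h={h}, k={k}, n={n}")
    L = np.zeros((n - 1, n))
    for i in range(n - 1):
        j = i if i < k else i + 1
        L[i, j] = 1.0
    L[h, k] = 1.0
    return L


def _pair_of(L_pair: np.ndarray):
    """Recover (h, k) from a single-pair lumping matrix."""
    col_sums = L_pair.sum(axis=0)
    row_sums = L_pair.sum(axis=1)
    rows = np.nonzero(row_sums == 2)[0]
    if len(rows) != 1:
        raise ValueError("not a single-pair lumping matrix")
    members = np.nonzero(L_pair[rows[0]])[0]
    return int(members[0]), int(members[1])


def galerkin_reduce(system: ControlledSystem, L, L_bar, names=None) -> ControlledSystem:
    """Reduced dynamics under the projection ``z = L x`` with lift
    ``x ~= L_bar z`` (valid for 0/1 lumpings and for real-valued balancing
    projections alike)."""
    L = np.asarray(L, float)
    L_bar = np.asarray(L_bar, float)
    n, ntilde = system.n, L.shape[0]
    if L.shape[1] != n or L_bar.shape != (n, ntilde):
        raise ValueError(
            f"projection shapes {L.shape}/{L_bar.shape} do not match n={n}"
        )
    z = sp.symbols(f"_z0:{ntilde}")
    lift = [
        sp.Add(*[sp.Float(L_bar[i, k]) * z[k] for k in range(ntilde) if L_bar[i, k] != 0.0])
        if np.any(L_bar[i] != 0.0)
        else sp.Integer(0)
        for i in range(n)
    ]
    subs = dict(zip(system.syms, lift))
    f_lift = [e.xreplace(subs) for e in system.f_exprs]
    f_new = [
        sp.Add(*[sp.Float(L[k, i]) * f_lift[i] for i in range(n) if L[k, i] != 0.0])
        for k in range(ntilde)
    ]
    if system.l:
        g_lift = system.g_exprs.xreplace(subs)
        g_new = sp.Matrix(L) * g_lift
    else:
        g_new = sp.zeros(ntilde, 0)
    h_new = [e.xreplace(subs) for e in system.h_exprs]

    if names is None:
        is_binary = np.all((L == 0) | (L == 1))
        if is_binary:
            names = [
                "+".join(system.names[i] for i in np.nonzero(L[k])[0])
                for k in range(ntilde)
            ]
        else:
            names = [f"z{k}" for k in range(ntilde)]
    return ControlledSystem(
        syms=z,
        f_exprs=f_new,
        g_exprs=g_new,
        h_exprs=h_new,
        x0=L @ system.x0,
        u0=system.u0,
        names=names,
        extra_syms=system.extra_syms,
        extra_vals=system.extra_vals,
        species_names=system.species_names,
        lineage=ProjectionLineage(system, L, L_bar),
        time_scale=system.time_scale,
    )


def moore_penrose_inverse(L) -> np.ndarray:
    """``L^+ = L^T (L L^T)^{-1}``: equal weights 1/(block size) within each
    lumped block."""
    L = np.asarray(L, float)
    block_sizes = L.sum(axis=1)
    return L.T / block_sizes


def steady_state_inverse(L, x_star) -> np.ndarray:
    """``Lbar = X L^T (L X L^T)^{-1}`` with ``X = diag(x*)``: within-block
    weights proportional to the steady state, so the reduced model
    reconstructs ``x*`` exactly.  A block whose steady state sums to zero is
    singular and raises :class:`SingularityError`."""
    L = np.asarray(L, float)
    x_star = np.asarray(x_star, float)
    block_tot = L @ x_star
    if np.any(np.abs(block_tot) < 1e-300):
        bad = int(np.argmin(np.abs(block_tot)))
        raise SingularityError(
            f"lumped block {bad} has zero steady-state total; the steady-state "
            "inverse is singular for a group of species all with a steady-state "
            "value of zero"
        )
    return (x_star[:, None] * L.T) / block_tot


def averaged_inverse(
    L_pair, trajectory: Trajectory, T: float, guard: float = 1e-12
) -> np.ndarray:
    """Time-averaged inverse for a single-pair lumping.

    The weight of member h is ``(1/T) \\int_0^T x_h / (x_h + x_k) dt``,
    evaluated by trapezoidal quadrature on the trajectory grid restricted to
    [0, T]; points where the pair total falls below ``guard`` times its
    maximum are excluded (and the average renormalised to the included
    measure).  Raises :class:`DegeneratePairError` when the pair is
    identically zero on the window.
    """
    L_pair = np.asarray(L_pair, float)
    h, k = _pair_of(L_pair)
    t = trajectory.times
    sel = t <= T + 1e-12 * max(T, 1.0)
    if sel.sum() < 2:
        raise ValueError("averaging window contains fewer than two trajectory points")
    t = t[sel]
    xh = trajectory.states[sel, h]
    xk = trajectory.states[sel, k]
    total = xh + xk
    ok = np.abs(total) > guard * max(np.max(np.abs(total)), 1e-300)
    if ok.sum() < 2:
        raise DegeneratePairError(
            f"states {h} and {k} are identically zero on the averaging window"
        )
    ratio = np.where(ok, np.divide(xh, np.where(ok, total, 1.0)), 0.0)
    measure = np.trapezoid(ok.astype(float), t)
    if measure <= 0:
        raise DegeneratePairError("no usable quadrature points for the averaged inverse")
    w_h = float(np.trapezoid(ratio * ok, t) / measure)
    w_h = min(max(w_h, 0.0), 1.0)

    n = L_pair.shape[1]
    Lbar = np.zeros((n, n - 1))
    for i in range(n):
        if i == h:
            Lbar[i, h] = w_h
        elif i == k:
            Lbar[i, h] = 1.0 - w_h
        else:
            j = i if i < k else i - 1
            Lbar[i, j] = 1.0
    return Lbar


def compose_lumpings(outer: LumpingScheme, inner: LumpingScheme) -> LumpingScheme:
    """Sequential composition: ``L = L_outer L_inner`` and
    ``Lbar = Lbar_inner Lbar_outer``; any lumping is expressible as a chain
    of pairwise lumps this way."""
    if outer.n != inner.ntilde:
        raise ValueError(
            f"dimension mismatch: outer acts on {outer.n}, inner produces {inner.ntilde}"
        )
    return LumpingScheme(
        L=outer.L @ inner.L,
        L_bar=inner.L_bar @ outer.L_bar,
        history=inner.history + outer.history,
        per_step_error=inner.per_step_error + outer.per_step_error,
        per_step_chi=inner.per_step_chi + outer.per_step_chi,
    )


@dataclass
class LumpConfig:
    """Forward-selection settings.

    max_error : error budget E (fraction, default 0.05).
    chi_c : critical stiffness; lumping stops once chi drops below it.
    protocol : the input perturbation under which candidates are scored
        (defaults to holding u0 — callers normally supply a step change).
    T_avg : averaging horizon for the time-averaged inverse; by default the
        time at which the unperturbed relative state deviation from x*
        falls below 1e-3.
    rtol, atol : integration tolerances for candidate scoring.
    """

    max_error: float = 0.05
    chi_c: float = 250.0
    protocol: Protocol = field(default_factory=Protocol)
    T_avg: float = None
    rtol: float = 1e-6
    atol: float = 1e-9


def _equilibration_time(system, x_star, rtol, atol, threshold=1e-3, t_probe=None):
    """Time for ||x(t) - x*|| / ||x0 - x*|| to fall below ``threshold``
    under the unperturbed input."""
    scale = np.linalg.norm(system.x0 - x_star)
    if scale == 0:
        return 1.0 * system.time_scale
    t_end = t_probe if t_probe is not None else 50.0 * system.time_scale
    for _ in range(8):
        traj = simulate(system, u=None, t_end=t_end, rtol=rtol, atol=atol)
        dev = np.linalg.norm(traj.states - x_star[None, :], axis=1) / scale
        below = np.nonzero(dev < threshold)[0]
        if below.size:
            return float(traj.times[below[0]])
        t_end *= 10.0
    return float(traj.times[-1])


def forward_selection_lump(system: ControlledSystem, config: LumpConfig) -> LumpingScheme:
    """Greedy pairwise lumping with best-of-two inverse selection.

    At each step every unordered pair of current states is lumped trially
    with both the steady-state and the averaged inverse; each candidate is
    simulated under the scoring protocol and its maximal relative output
    error against the *unlumped* reference recorded (blow-ups score
    infinity).  The minimum-error candidate is applied; ties prefer the
    lower resulting stiffness, then lexicographic pair order.  Exit when the
    best candidate would exceed ``max_error``, when ``chi < chi_c``, or at
    one state.
    """
    n0 = system.n
    scheme = LumpingScheme.identity(n0)
    if config.max_error <= 0:
        return scheme
    try:
        if stiffness_coefficient(system) < config.chi_c:
            return scheme  # already below the critical stiffness
    except Exception:
        pass

    proto = config.protocol
    reference = simulate(
        system,
        u=proto.u_fn(system),
        t_end=proto.t_end,
        t_eval=proto.times(),
        rtol=config.rtol,
        atol=config.atol,
    )
    current = system
    current_scheme = scheme

    while current.n > 1:
        try:
            x_star = find_steady_state(current, rtol=config.rtol)
        except NonConvergenceError:
            x_star = None
        T_avg = config.T_avg
        avg_traj = None
        if x_star is not None:
            if T_avg is None:
                T_avg = _equilibration_time(current, x_star, config.rtol, config.atol)
            avg_traj = simulate(
                current,
                u=None,
                t_end=T_avg,
                t_eval=np.linspace(0.0, T_avg, 201),
                rtol=config.rtol,
                atol=config.atol,
            )

        candidates = []
        for h in range(current.n - 1):
            for k in range(h + 1, current.n):
                L_pair = pair_lumping_matrix(current.n, h, k)
                inverses = []
                if x_star is not None:
                    try:
                        inverses.append(("steady-state", steady_state_inverse(L_pair, x_star)))
                    except SingularityError:
                        pass
                if avg_traj is not None:
                    try:
                        inverses.append(("averaged", averaged_inverse(L_pair, avg_traj, T_avg)))
                    except DegeneratePairError:
                        pass
                if not inverses:
                    inverses.append(("moore-penrose", moore_penrose_inverse(L_pair)))
                for label, Lbar in inverses:
                    cand = galerkin_reduce(current, L_pair, Lbar)
                    try:
                        traj = simulate(
                            cand,
                            u=proto.u_fn(cand),
                            t_end=proto.t_end,
                            t_eval=proto.times(),
                            rtol=config.rtol,
                            atol=config.atol,
                        )
                        E = max_relative_error(reference, traj).E
                    except BlowUpError:
                        E = math.inf
                    candidates.append((E, (h, k), label, L_pair, Lbar, cand))

        finite = [c for c in candidates if math.isfinite(c[0])]
        if not finite:
            break
        best_E = min(c[0] for c in finite)
        near = [c for c in finite if c[0] <= best_E * (1 + 1e-9) + 1e-15]
        if len(near) > 1:
            scored = []
            for c in near:
                try:
                    chi_c_ = stiffness_coefficient(c[5])
                except Exception:
                    chi_c_ = math.inf
                scored.append((chi_c_, c[1], c))
            scored.sort(key=lambda t: (t[0], t[1]))
            best = scored[0][2]
        else:
            best = near[0]
        E, pair, label, L_pair, Lbar, cand = best
        if E > config.max_error:
            break
        try:
            chi = stiffness_coefficient(cand)
        except Exception:
            chi = math.nan
        step_scheme = LumpingScheme(
            L=L_pair,
            L_bar=Lbar,
            history=[LumpStep(pair=pair, inverse=label, error=E, chi=chi)],
            per_step_error=[E],
            per_step_chi=[chi],
        )
        current_scheme = compose_lumpings(step_scheme, current_scheme)
        current = cand
        if math.isfinite(chi) and chi < config.chi_c:
            break
    return current_scheme
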