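"""Empirical Gramians, Laub balancing, truncation and importance indices.

The empirical controllability Gramian P is assembled from simulations of
the system kicked along each input channel (an impulse of strength c
through channel i displaces the steady state to ``x* + c g_i(x*)``), the
state deviation from the unperturbed steady state integrated as an outer
product and normalised by ``1/c^2``; magnitudes c are derived from
multipliers sampled uniformly on a user interval (0.2-1.8 of the baseline
by default) and the result is averaged over magnitudes.  For linear systems
this construction converges to the Lyapunov controllability Gramian, which
is the correctness oracle used in the tests.

The empirical observability Gramian Q is assembled from output responses to
perturbed initial conditions, one direction per state coordinate.  For a
system whose coordinates descend from a conservation-eliminated realisation
the perturbation is applied to the *full* species state and the conserved
totals are recomputed from it before simulating, so no perturbation can
violate conservation.

Balancing follows the numerically stable square-root (Cholesky + SVD)
route: with ``P = Lc^T Lc`` and ``Q = Ro^T Ro``, the SVD
``Lc Ro^T = U S V^T`` yields the truncated projection

.. math::

    T_1 = S_1^{-1/2} V_1^T R_o, \\qquad S_1 = L_c^T U_1 S_1^{-1/2},

after which both transformed Gramians equal ``diag(S_1)`` — the Hankel
singular values, which rank each balanced direction's contribution to the
input-output map.

Per-state importance indices are read off the Gramian diagonals:
``nu_o = sqrt(diag Q)`` and ``nu_c = sqrt(diag P)`` rescaled to maximum
one, and the input-output index ``nu`` is their elementwise product,
rescaled again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import BlowUpError, GramianFailureError, RankError, UndefinedIndexError
from .lumping import galerkin_reduce
from .simulation import find_steady_state, simulate

__all__ = [
    "PerturbationDesign",
    "GramianPair",
    "BalancingTransform",
    "ImportanceIndices",
    "empirical_controllability_gramian",
    "empirical_observability_gramian",
    "balancing_transform",
    "truncate",
    "importance_indices",
]


@dataclass
class PerturbationDesign:
    """Multipliers applied to the baseline input / initial state, the
    simulation horizon and the quadrature grid.

    ``input_scales`` and ``state_scales`` are positive multipliers m; the
    perturbation amplitude of a run is ``(m - 1)`` times the baseline
    magnitude (multipliers at exactly 1 produce no perturbation and are
    skipped).  ``n_sims`` reports how many distinct perturbed simulations
    were actually run.
    """

    input_scales: np.ndarray
    state_scales: np.ndarray
    horizon: float = 20.0
    n_timepoints: int = 201
    seed: int = 0
    n_sims: int = 0

    def __post_init__(self):
        self.input_scales = np.atleast_1d(np.asarray(self.input_scales, float))
        self.state_scales = np.atleast_1d(np.asarray(self.state_scales, float))
        if np.any(self.input_scales <= 0) or np.any(self.state_scales <= 0):
            raise ValueError("perturbation multipliers must be positive")

    @classmethod
    def sample(
        cls,
        seed: int = 0,
        n_input: int = 8,
        n_state: int = 8,
        low: float = 0.2,
        high: float = 1.8,
        horizon: float = 20.0,
        n_timepoints: int = 201,
    ):
        """Uniformly sampled multipliers on [low, high] (the 0.2-1.8 range
        used for the 100-simulation protocol by default)."""
        rng = np.random.default_rng(seed)
        return cls(
            input_scales=rng.uniform(low, high, n_input),
            state_scales=rng.uniform(low, high, n_state),
            horizon=horizon,
            n_timepoints=n_timepoints,
            seed=seed,
        )

    def grid(self):
        return np.linspace(0.0, self.horizon, self.n_timepoints)


@dataclass
class GramianPair:
    """Empirical controllability (P) and observability (Q) Gramians with the
    design that produced them."""

    P: np.ndarray
    Q: np.ndarray
    design: PerturbationDesign

    def __post_init__(self):
        for name, M in (("P", self.P), ("Q", self.Q)):
            M = np.asarray(M, float)
            if np.max(np.abs(M - M.T)) > 1e-10 * max(1.0, np.max(np.abs(M))):
                raise ValueError(f"{name} is not symmetric")
            w = np.linalg.eigvalsh(M)
            if w.size and w.min() < -1e-10 * max(np.trace(M), 1.0):
                raise ValueError(f"{name} is not PSD up to round-off")


def _quad_outer(t, Z):
    """Trapezoidal quadrature of the outer product integral
    int Z(t) Z(t)^T dt for Z with rows Z(t_k)."""
    w = np.zeros(len(t))
    w[1:] += 0.5 * np.diff(t)
    w[:-1] += 0.5 * np.diff(t)
    return (Z * w[:, None]).T @ Z


def empirical_controllability_gramian(
    system, design: PerturbationDesign, x_star=None, rtol=1e-6, atol=1e-9
) -> np.ndarray:
    """Empirical controllability Gramian from input-channel impulses.

    For each input channel i and multiplier m the steady state is kicked by
    ``c = (m - 1) u_ref_i`` along ``g_i(x*)``; the quadrature-weighted
    covariance of the state deviation, normalised by ``1/c^2``, is averaged
    over magnitudes and summed over channels.  A blown-up run raises
    :class:`GramianFailureError` naming the perturbation.
    """
    if system.l == 0:
        design.n_sims = 0
        return np.zeros((system.n, system.n))
    if x_star is None:
        x_star = find_steady_state(system, rtol=rtol)
    G = system.g(x_star)
    tiny = 1e-9 * max(1.0, float(np.max(np.abs(system.u0))) if system.l else 1.0)
    u_ref = np.where(np.abs(system.u0) > tiny, np.abs(system.u0), 1.0)
    t = design.grid()
    P = np.zeros((system.n, system.n))
    runs = 0
    for i in range(system.l):
        acc = np.zeros_like(P)
        n_mag = 0
        for m in design.input_scales:
            c = (m - 1.0) * u_ref[i]
            if abs(c) < 1e-12:
                continue
            z0 = x_star + c * G[:, i]
            try:
                traj = simulate(
                    system, u=None, x0=z0, t_end=design.horizon,
                    t_eval=t, rtol=rtol, atol=atol,
                )
            except BlowUpError as exc:
                raise GramianFailureError(
                    f"controllability simulation blew up (channel {i}, "
                    f"multiplier {m:.3f}): {exc}",
                    perturbation=(i, m),
                ) from exc
            Z = traj.states - x_star[None, :]
            acc += _quad_outer(traj.times, Z) / c**2
            n_mag += 1
            runs += 1
        if n_mag:
            P += acc / n_mag
    design.n_sims = runs
    return 0.5 * (P + P.T)


def empirical_observability_gramian(
    system, design: PerturbationDesign, x_star=None, rtol=1e-6, atol=1e-9
) -> np.ndarray:
    """Empirical observability Gramian from perturbed initial conditions.

    For each multiplier m, every state coordinate is displaced by
    ``a = (m - 1) s_i`` (``s_i = |x*_i|`` or 1 for zero-steady-state
    coordinates).  The displacement is realised in the full species space
    and the system rebuilt from the perturbed full initial condition, which
    recomputes any conserved totals so conservation is never violated.
    Output deviations, normalised per run, assemble Q as a covariance over
    directions, averaged over magnitudes.
    """
    if x_star is None:
        x_star = find_steady_state(system, rtol=rtol)
    n = system.n
    y_star = system.h(x_star)
    # reference magnitude per coordinate; numerically-zero steady states
    # fall back to unit scale so the direction is still explored
    tiny = 1e-9 * max(1.0, float(np.max(np.abs(x_star))) if n else 1.0)
    s_ref = np.where(np.abs(x_star) > tiny, np.abs(x_star), 1.0)
    t = design.grid()
    full_star = system.lift(x_star)
    pert_map = system.pert_map()
    Q = np.zeros((n, n))
    runs = 0
    n_mag = 0
    for m in design.state_scales:
        a = m - 1.0
        if abs(a) < 1e-12:
            continue
        Y = np.empty((len(t) * system.p, n))
        for i in range(n):
            amp = a * s_ref[i]
            full0 = full_star + amp * pert_map[:, i]
            sys_i, z0 = system.rebuild(full0)
            try:
                traj = simulate(
                    sys_i, u=None, x0=z0, t_end=design.horizon,
                    t_eval=t, rtol=rtol, atol=atol,
                )
            except BlowUpError as exc:
                raise GramianFailureError(
                    f"observability simulation blew up (state {i}, "
                    f"multiplier {m:.3f}): {exc}",
                    perturbation=(i, m),
                ) from exc
            Y[:, i] = ((traj.outputs - y_star[None, :]) / amp).reshape(-1)
            runs += 1
        w = np.zeros(len(t))
        w[1:] += 0.5 * np.diff(t)
        w[:-1] += 0.5 * np.diff(t)
        wfull = np.repeat(w, system.p) if system.p > 1 else w
        Q += (Y * wfull[:, None]).T @ Y
        n_mag += 1
    if n_mag:
        Q /= n_mag
    design.n_sims = runs
    return 0.5 * (Q + Q.T)


@dataclass
class BalancingTransform:
    """Truncated balancing projection (T1, S1), the Hankel singular values
    retained on the diagonal of the balanced Gramians, and the Cholesky
    factors of P and Q (stored as ``chol_P`` / ``chol_Q``; these are the
    square-root factors, not lumping matrices)."""

    T1: np.ndarray
    S1: np.ndarray
    hankel: np.ndarray
    hankel_full: np.ndarray
    chol_P: np.ndarray
    chol_Q: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.hankel) > 1e-12):
            raise ValueError("Hankel values must be non-increasing")
        resid = np.max(np.abs(self.T1 @ self.S1 - np.eye(self.T1.shape[0])))
        if resid > 1e-8:
            raise ValueError(f"T1 @ S1 != I (residual {resid:.2e})")


def balancing_transform(P, Q, n_red: int, ridge: float = 1e-12) -> BalancingTransform:
    """Square-root balancing of a Gramian pair, truncated to ``n_red``.

    Both Gramians get a ridge of ``ridge * trace / n`` before factorisation
    to tolerate semidefiniteness from quadrature round-off.  Requesting more
    states than the numerical rank of ``Lc Ro^T`` raises :class:`RankError`
    carrying the maximal feasible dimension.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = P.shape[0]
    Pr = P + np.eye(n) * (ridge * max(np.trace(P), 1e-300) / n)
    Qr = Q + np.eye(n) * (ridge * max(np.trace(Q), 1e-300) / n)
    Lc = scipy.linalg.cholesky(Pr)   # upper triangular, P = Lc^T Lc
    Ro = scipy.linalg.cholesky(Qr)
    U, s, Vt = scipy.linalg.svd(Lc @ Ro.T)
    rank = int(np.sum(s > max(s[0], 1e-300) * 1e-10)) if s.size else 0
    if n_red > rank:
        raise RankError(
            f"requested n_red={n_red} exceeds numerical rank {rank} of the "
            f"balancing problem; the maximal feasible reduction is {rank}",
            max_feasible=rank,
        )
    s1 = s[:n_red]
    inv_sqrt = np.diag(1.0 / np.sqrt(s1))
    T1 = inv_sqrt @ Vt[:n_red] @ Ro
    S1 = Lc.T @ U[:, :n_red] @ inv_sqrt
    return BalancingTransform(
        T1=T1, S1=S1, hankel=s1, hankel_full=s, chol_P=Lc, chol_Q=Ro
    )


def truncate(system, transform: BalancingTransform):
    """Galerkin projection of the system through the balanced-truncated
    coordinates ``z = T1 x`` with lift ``x ~= S1 z``."""
    return galerkin_reduce(
        system,
        transform.T1,
        transform.S1,
        names=[f"z{k + 1}" for k in range(transform.T1.shape[0])],
    )


@dataclass
class ImportanceIndices:
    """Per-state controllability (nu_c), observability (nu_o) and combined
    input-output (nu) indices, each rescaled to maximum one; zero means the
    state neither responds to the input nor moves the output."""

    nu_c: np.ndarray
    nu_o: np.ndarray
    nu: np.ndarray
    labels: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.labels,
                "controllability": self.nu_c,
                "observability": self.nu_o,
                "input_output": self.nu,
            }
        )


def importance_indices(P, Q, labels=None) -> ImportanceIndices:
    """Indices from the Gramian diagonals: ``nu_ci = sqrt(P_ii)/max`` and
    ``nu_oi = sqrt(Q_ii)/max``; ``nu`` is their elementwise product
    renormalised to maximum one."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    dc = np.sqrt(np.clip(np.diag(P), 0.0, None))
    do = np.sqrt(np.clip(np.diag(Q), 0.0, None))
    if dc.max(initial=0.0) == 0.0 or do.max(initial=0.0) == 0.0:
        raise UndefinedIndexError("a Gramian is identically zero; indices undefined")
    nu_c = dc / dc.max()
    nu_o = do / do.max()
    prod = nu_c * nu_o
    nu = prod / prod.max() if prod.max() > 0 else prod
    labels = labels or [f"x{i}" for i in range(len(nu_c))]
    return ImportanceIndices(nu_c=nu_c, nu_o=nu_o, nu=nu, labels=list(labels))
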