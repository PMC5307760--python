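"""Stiff integration, steady states, the maximal-relative-error metric and
the stiffness coefficient.

The reduction-quality metric used throughout the package is the maximal
relative output error

.. math::

    \\epsilon_i(t) = \\frac{|y_i(t) - \\bar y_i(t)|}{|y_i(t)|},
    \\qquad E = \\sup_{t,i} \\epsilon_i(t),

evaluated on the reference trajectory's time grid with the candidate output
interpolated onto it.  Time points where the reference output magnitude
falls below ``delta * max_t |y_i|`` are masked (the metric has no zero
protection otherwise); the mask is reported.

The stiffness coefficient is

.. math:: \\chi = \\frac{\\max_k |\\lambda_k|}{\\min_k |\\lambda_k|}

over the eigenvalues of the Jacobian at a reference state, excluding
eigenvalues with modulus below ``1e-9`` of the largest — conservation
relations contribute exact zero modes that would otherwise make every
closed network infinitely stiff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import root

from .errors import (
    BlowUpError,
    DegenerateOutputError,
    NonConvergenceError,
    UndefinedStiffnessError,
)

__all__ = [
    "Trajectory",
    "ErrorReport",
    "Protocol",
    "simulate",
    "find_steady_state",
    "max_relative_error",
    "stiffness_coefficient",
]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


@dataclass
class Trajectory:
    """Time points (strictly increasing, original model time units), state
    matrix (time x n) and output matrix (time x p)."""

    times: np.ndarray
    states: np.ndarray
    outputs: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        self.outputs = np.asarray(self.outputs, float)
        if self.outputs.ndim == 1:
            self.outputs = self.outputs[:, None]
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory states must be finite")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, variable, value) table of states and outputs."""
        rows = []
        for j in range(self.states.shape[1]):
            rows.append(
                pd.DataFrame(
                    {"time": self.times, "variable": f"x{j}", "value": self.states[:, j]}
                )
            )
        for j in range(self.outputs.shape[1]):
            rows.append(
                pd.DataFrame(
                    {"time": self.times, "variable": f"y{j}", "value": self.outputs[:, j]}
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class ErrorReport:
    """Pointwise relative errors (time x p), their supremum E over unmasked
    points, and the guard mask marking excluded time points."""

    pointwise: np.ndarray
    E: float
    guard_mask: np.ndarray
    infeasible: bool = False

    def __post_init__(self):
        if self.E < 0:
            raise ValueError("E must be non-negative")


@dataclass
class Protocol:
    """An input perturbation protocol: the signal ``u(t)`` (callable of
    original-model time, constant vector, or None for the baseline input)
    applied over ``[0, t_end]``, evaluated on ``n_points`` grid points."""

    u: object = None
    t_end: float = 10.0
    n_points: int = 200
    grid: str = "linear"

    def times(self) -> np.ndarray:
        if self.grid == "log":
            # log-spaced from 1e-4*t_end, with t=0 prepended
            pts = np.geomspace(self.t_end * 1e-4, self.t_end, self.n_points - 1)
            return np.concatenate([[0.0], pts])
        return np.linspace(0.0, self.t_end, self.n_points)

    def u_fn(self, system):
        if self.u is None:
            const = np.asarray(system.u0, float)
            return lambda t: const
        if callable(self.u):
            return lambda t: np.atleast_1d(np.asarray(self.u(t), float))
        const = np.atleast_1d(np.asarray(self.u, float))
        return lambda t: const


def simulate(
    system,
    u=None,
    x0=None,
    t_end=10.0,
    rtol=DEFAULT_RTOL,
    atol=DEFAULT_ATOL,
    t_eval=None,
    method="LSODA",
) -> Trajectory:
    """Integrate the system with an implicit, stiff-capable solver.

    ``u`` may be None (hold the unperturbed input ``u0``), a constant
    vector, or a callable of time.  Times are in original model units; the
    conversion for nondimensionalised systems (``system.time_scale``) is
    internal.  Integration failure raises :class:`BlowUpError` carrying the
    failure time — a signal, not a crash: the pipeline records it as an
    infeasible reduction.
    """
    x0 = system.x0 if x0 is None else np.asarray(x0, float)
    ts = system.time_scale
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, float)
    tau_eval = t_eval / ts
    if callable(u):
        u_of_t = lambda t: np.atleast_1d(np.asarray(u(t), float))
    elif u is None:
        const = np.asarray(system.u0, float)
        u_of_t = lambda t: const
    else:
        const = np.atleast_1d(np.asarray(u, float))
        u_of_t = lambda t: const

    # divergence guard: once the state leaves any plausible range the solver
    # would otherwise grind towards overflow with ever-shrinking steps
    blow_limit = 1e50

    class _Diverged(Exception):
        def __init__(self, tau):
            self.tau = tau

    def rhs(tau, x):
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > blow_limit:
            raise _Diverged(tau)
        return system.rhs(x, u_of_t(tau * ts))

    def jac(tau, x):
        return system.jac(x, u_of_t(tau * ts))

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(
                rhs,
                (tau_eval[0], tau_eval[-1]),
                x0,
                method=method,
                t_eval=tau_eval,
                rtol=rtol,
                atol=atol,
                jac=jac,
            )
    except _Diverged as exc:
        raise BlowUpError(
            f"state diverged at t={exc.tau * ts:.4g}", time=exc.tau * ts
        ) from None
    if not sol.success or sol.y.shape[1] != len(tau_eval) or not np.all(np.isfinite(sol.y)):
        t_fail = sol.t[-1] * ts if sol.t.size else t_eval[0]
        raise BlowUpError(
            f"integration failed at t={t_fail:.4g}: {sol.message}", time=t_fail
        )
    states = sol.y.T
    outputs = np.array([system.h(x) for x in states])
    return Trajectory(times=t_eval, states=states, outputs=outputs)


def find_steady_state(
    system,
    u0=None,
    x_guess=None,
    atol=1e-9,
    t_max=1e7,
    rtol=DEFAULT_RTOL,
):
    """Steady state ``x*`` under the unperturbed input.

    Long integration over doubling horizons until ``||f(x) + g(x) u0||`` is
    small, then Newton polishing; the polished root is kept only if it
    improves the residual and stays near the integrated point.  Systems that
    never settle (limit cycles, drift) raise :class:`NonConvergenceError`.
    """
    u0 = system.u0 if u0 is None else np.atleast_1d(np.asarray(u0, float))
    x = system.x0 if x_guess is None else np.asarray(x_guess, float)
    ts = system.time_scale

    def res_norm(xv):
        return float(np.max(np.abs(system.rhs(xv, u0))))

    scale = max(res_norm(x), 1.0)
    tol = atol * max(1.0, float(np.max(np.abs(x))))
    horizon = 10.0
    total = 0.0
    converged = res_norm(x) < tol
    while not converged and total < t_max:
        try:
            traj = simulate(
                system, u=u0, x0=x, t_end=horizon * ts, rtol=rtol, atol=atol,
                t_eval=np.linspace(0, horizon * ts, 33),
            )
        except BlowUpError as exc:
            raise NonConvergenceError(
                f"integration towards steady state failed at t={exc.time}"
            ) from exc
        x = traj.states[-1]
        total += horizon
        horizon *= 4.0
        r = res_norm(x)
        if r < tol:
            converged = True
        elif r < 1e-12 * scale:
            converged = True

    r_before = res_norm(x)
    try:
        sol = root(
            lambda xv: system.rhs(xv, u0),
            x,
            jac=lambda xv: system.jac(xv, u0),
            method="hybr",
        )
        if sol.success and res_norm(sol.x) < r_before and (
            np.linalg.norm(sol.x - x) <= 1e-2 * (1.0 + np.linalg.norm(x))
        ):
            x = sol.x
    except Exception:
        pass

    if res_norm(x) >= max(tol, 1e3 * atol):
        raise NonConvergenceError(
            f"no steady state within t_max={t_max:g}: residual {res_norm(x):.3e}"
        )
    return x


def max_relative_error(
    reference: Trajectory, candidate: Trajectory, delta: float = 1e-3
) -> ErrorReport:
    """Maximal relative output error of ``candidate`` against ``reference``.

    The candidate is resampled onto the reference time grid with monotone
    cubic (PCHIP) interpolation per output.  Points where
    ``|y_i(t)| < delta * max_t |y_i|`` are masked out of the supremum; if
    every point of every output is masked the output is degenerate.
    """
    y = np.atleast_2d(reference.outputs)
    if y.shape[1] != np.atleast_2d(candidate.outputs).shape[1]:
        raise ValueError("trajectories have different output dimensions")
    ybar = np.empty_like(y)
    for j in range(y.shape[1]):
        interp = PchipInterpolator(candidate.times, candidate.outputs[:, j], extrapolate=True)
        ybar[:, j] = interp(reference.times)
    denom = np.abs(y)
    col_max = np.max(denom, axis=0, keepdims=True)
    guard = (denom < delta * col_max) | (col_max == 0.0)
    if np.all(guard):
        raise DegenerateOutputError("all output points fall below the relative-error guard")
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = np.abs(y - ybar) / denom
    eps = np.where(guard, np.nan, eps)
    E = float(np.nanmax(eps))
    return ErrorReport(pointwise=eps, E=E, guard_mask=guard)


def stiffness_coefficient(system, x=None, eps_rank: float = 1e-9) -> float:
    """Stiffness coefficient chi = max|lambda| / min|lambda| of the Jacobian
    at ``x`` (default: the initial condition), over eigenvalues with modulus
    above ``eps_rank`` times the largest."""
    x = system.x0 if x is None else np.asarray(x, float)
    J = system.jac(x)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian is not finite at the requested state")
    mags = np.abs(np.linalg.eigvals(J))
    top = float(np.max(mags)) if mags.size else 0.0
    if top <= 0.0:
        raise UndefinedStiffnessError("all Jacobian eigenvalues are zero")
    kept = mags[mags > eps_rank * top]
    return float(top / np.min(kept))
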