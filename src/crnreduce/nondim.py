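"""Nondimensionalisation by sampled scalings scored on parameter spread.

A scaling rescales every concentration by a positive reference value and
time by a reference time scale.  There is no canonical "best" choice; when
the model is fully parameterised, a dimensionless parameter set spanning
few orders of magnitude improves floating-point conditioning.  Candidate
scalings are therefore sampled (50 by default) and scored by

.. math:: \\sigma = \\log_{10}\\left(\\frac{\\max \\tilde p}{\\min \\tilde p}\\right),

the order-of-magnitude spread of the dimensionless parameter set; the
minimiser is applied.  Since a scaling is a similarity transform plus a
time rescale, the output trajectory in original units is invariant under
any valid choice — only numerical conditioning differs.

The dimensionless parameter set of a candidate is the collection of
nonzero monomial coefficients of the scaled polynomial right-hand side
(exact for mass-action kinetics); for non-polynomial rate laws the
fallback is the parameter values multiplied by the time scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import sympy as sp

from .conservation import left_null_space
from .model_core import ControlledSystem, ReactionNetwork, stoichiometry_matrix
from .simulation import Trajectory

__all__ = ["Scaling", "propose_scalings", "score_scaling", "apply_scaling"]


@dataclass
class Scaling:
    """Positive per-species concentration scales, a time scale, and the
    dimensionless parameter set the combination induces."""

    species_order: list
    state_scales: np.ndarray
    time_scale: float
    scaled_parameters: dict

    def __post_init__(self):
        self.state_scales = np.asarray(self.state_scales, float)
        if np.any(self.state_scales <= 0) or self.time_scale <= 0:
            raise ValueError("all scales must be strictly positive")

    def scales_for(self, names) -> np.ndarray:
        """Concentration scales aligned with an arbitrary species subset."""
        index = {s: i for i, s in enumerate(self.species_order)}
        return np.array([self.state_scales[index[n]] for n in names])

    def map_back(self, trajectory: Trajectory, names=None) -> Trajectory:
        """Undo the scaling on a trajectory of the scaled system (states
        multiplied by their scales; times are already reported in original
        units by the simulator)."""
        scales = self.state_scales if names is None else self.scales_for(names)
        return Trajectory(
            times=trajectory.times,
            states=trajectory.states * scales[None, :],
            outputs=trajectory.outputs,
        )


def _dimensionless_groups(network: ReactionNetwork, scales, t_scale):
    """Nonzero monomial coefficients of the scaled RHS, keyed by
    (species, monomial)."""
    odes = network.odes()
    syms = [sp.Symbol(s) for s in network.species_ids]
    sub = {x: sp.Float(s) * x for x, s in zip(syms, scales)}
    groups = {}
    for i, (expr, s_i) in enumerate(zip(odes, scales)):
        scaled = sp.expand(expr.xreplace(sub) * sp.Float(t_scale / s_i))
        try:
            poly = sp.Poly(scaled, *syms)
        except sp.PolynomialError:
            return None
        for mono, coeff in poly.terms():
            val = abs(float(coeff))
            if val > 0:
                groups[f"c_{network.species_ids[i]}_{mono}"] = val
    return groups


def propose_scalings(
    network: ReactionNetwork, n_candidates: int = 50, seed: int = 0
) -> list:
    """Sample candidate nondimensionalisations.

    Each candidate draws its time scale as the reciprocal of one sampled
    rate parameter and each species scale from the species' own initial
    value, its conserved total, or the largest initial value in the model.
    Reproducible under ``seed``; if no positive concentration scale exists
    the candidate falls back to unit scales with a warning.
    """
    rng = np.random.default_rng(seed)
    sids = network.species_ids
    x0 = network.x0
    rates = [v for v in network.parameters.values() if v > 0]
    if not rates:
        rates = [1.0]

    gamma = left_null_space(stoichiometry_matrix(network))
    totals = gamma @ x0 if gamma.size else np.zeros(0)
    per_species_total = {}
    for k in range(gamma.shape[0]):
        for i in np.nonzero(gamma[k])[0]:
            if totals[k] > 0:
                per_species_total.setdefault(i, totals[k])
    global_max = float(np.max(x0)) if np.any(x0 > 0) else None
    if global_max is None:
        warnings.warn(
            "no positive concentration scale available; using unit scales",
            stacklevel=2,
        )

    out = []
    for _ in range(n_candidates):
        t_scale = 1.0 / rates[rng.integers(len(rates))]
        scales = np.empty(len(sids))
        for i in range(len(sids)):
            choices = []
            if x0[i] > 0:
                choices.append(x0[i])
            if i in per_species_total:
                choices.append(per_species_total[i])
            if global_max is not None:
                choices.append(global_max)
            scales[i] = choices[rng.integers(len(choices))] if choices else 1.0
        groups = _dimensionless_groups(network, scales, t_scale)
        if groups is None:
            groups = {
                k: abs(v) * t_scale for k, v in network.parameters.items() if v != 0
            }
        if not groups:
            groups = {"unit": 1.0}
        out.append(
            Scaling(
                species_order=list(sids),
                state_scales=scales,
                time_scale=t_scale,
                scaled_parameters=groups,
            )
        )
    return out


def score_scaling(scaled_parameters) -> float:
    """Order-of-magnitude spread sigma = log10(max p~ / min p~); zero iff
    all dimensionless parameters coincide."""
    vals = np.asarray(
        list(scaled_parameters.values())
        if isinstance(scaled_parameters, dict)
        else list(scaled_parameters),
        float,
    )
    if vals.size == 0:
        raise ValueError("empty dimensionless parameter set")
    if np.any(vals <= 0):
        raise ValueError("dimensionless parameters must be strictly positive")
    return float(np.log10(vals.max() / vals.min()))


def apply_scaling(system: ControlledSystem, scaling: Scaling) -> ControlledSystem:
    """Rescale a system's states and time.

    New states are ``x~ = x / s`` and new time ``tau = t / t_s``; the
    output map is composed with the un-scaling so outputs remain in
    original units, and the system's ``time_scale`` records ``t_s`` so
    simulated trajectories keep original time units.  Mapping a scaled
    trajectory back reproduces the original trajectory exactly (up to
    solver tolerance).
    """
    s = scaling.scales_for(system.names)
    t_s = scaling.time_scale
    sub = {x: sp.Float(si) * x for x, si in zip(system.syms, s)}
    f_new = [sp.expand(e.xreplace(sub) * sp.Float(t_s / si)) for e, si in zip(system.f_exprs, s)]
    if system.l:
        g_new = sp.Matrix(
            [
                [
                    sp.expand(system.g_exprs[i, j].xreplace(sub) * sp.Float(t_s / s[i]))
                    for j in range(system.l)
                ]
                for i in range(system.n)
            ]
        )
    else:
        g_new = sp.zeros(system.n, 0)
    h_new = [e.xreplace(sub) for e in system.h_exprs]

    from .model_core import ProjectionLineage

    lineage = ProjectionLineage(system, np.diag(1.0 / s), np.diag(s))
    return ControlledSystem(
        syms=system.syms,
        f_exprs=f_new,
        g_exprs=g_new,
        h_exprs=h_new,
        x0=system.x0 / s,
        u0=system.u0,
        names=system.names,
        extra_syms=system.extra_syms,
        extra_vals=system.extra_vals,
        species_names=system.species_names,
        lineage=lineage,
        time_scale=system.time_scale * t_s,
    )
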