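"""Orchestration of the combined reduction algorithm.

Order of stages, each feeding the next:

1. realise the network as a control-affine system from the user's
   input/output declaration;
2. sample candidate nondimensionalisations, score each by the
   order-of-magnitude spread of its dimensionless parameter set, apply the
   best;
3. conservation analysis: left null space of the stoichiometry matrix,
   speed-ranked selection of the slowest species for algebraic elimination;
4. forward-selection proper lumping until the error budget would be
   violated, the stiffness coefficient falls below the critical value
   chi_c, or one state remains;
5. empirical Gramians on the lumped system, Laub balancing, and truncation
   scanning every candidate dimension downward, keeping the smallest that
   meets the error budget (Hankel ordering does not guarantee monotone
   error for nonlinear systems);
6. report: per-stage dimensions, error, stiffness, projections, the chosen
   scaling and eliminations, and importance-index tables.

If the Gramian stage fails numerically (the stiffness failure mode), the
best lumped model is returned with a diagnostic rather than failing.
"""

from __future__ import annotations

import json
import math
import time as _time
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nondim
from .balancing import (
    GramianPair,
    PerturbationDesign,
    balancing_transform,
    empirical_controllability_gramian,
    empirical_observability_gramian,
    importance_indices,
    truncate,
)
from .conservation import eliminate_states, left_null_space, select_eliminations, speed_rank
from .errors import (
    BlowUpError,
    GramianFailureError,
    NonConvergenceError,
    RankError,
)
from .lumping import LumpConfig, forward_selection_lump, galerkin_reduce
from .model_core import ControlledSystem, build_state_space, stoichiometry_matrix
from .simulation import (
    ErrorReport,
    Protocol,
    find_steady_state,
    max_relative_error,
    simulate,
    stiffness_coefficient,
)

__all__ = [
    "ReductionConfig",
    "StageRecord",
    "ReductionReport",
    "run_combined_reduction",
    "validate_reduction",
]


@dataclass
class ReductionConfig:
    """Tunables of the combined algorithm.

    max_error : maximum tolerated maximal relative error (default 5%).
    chi_c : critical stiffness below which lumping hands over to balanced
        truncation (default 250).
    n_nondim_candidates : sampled nondimensionalisations (default 50).
    protocol : the input perturbation protocol used both to score lumping
        candidates and to validate truncations.
    design kwargs : perturbation-multiplier interval and counts for the
        empirical Gramians.
    """

    max_error: float = 0.05
    chi_c: float = 250.0
    n_nondim_candidates: int = 50
    protocol: Protocol = field(default_factory=Protocol)
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9
    pert_low: float = 0.2
    pert_high: float = 1.8
    n_input_scales: int = 8
    n_state_scales: int = 8
    gramian_horizon: float = None
    T_avg: float = None
    apply_nondim: bool = True

    def __post_init__(self):
        if not (0 <= self.max_error < 1):
            raise ValueError("max_error must lie in [0, 1)")
        if self.chi_c <= 1:
            raise ValueError("chi_c must exceed 1")


@dataclass
class StageRecord:
    method: str          # conservation | lump | truncate
    dim: int
    error: float
    chi: float
    wall_time: float


@dataclass
class ReductionReport:
    """Everything needed to reproduce and apply the reduction."""

    stages: list
    final_system: ControlledSystem
    scaling: object = None
    conservation: object = None
    scheme: object = None          # LumpingScheme
    transform: object = None       # BalancingTransform or None
    gramians: object = None        # GramianPair or None
    indices: object = None         # ImportanceIndices or None
    diagnostics: list = field(default_factory=list)
    config: ReductionConfig = None

    @property
    def final_error(self):
        return self.stages[-1].error if self.stages else 0.0

    def summary(self) -> str:
        lines = ["stage        dim   error        chi"]
        for s in self.stages:
            err = "-" if math.isnan(s.error) else f"{100 * s.error:.3g}%"
            chi = "-" if math.isnan(s.chi) else f"{s.chi:.4g}"
            lines.append(f"{s.method:<12} {s.dim:>3}   {err:<10} {chi}")
        for d in self.diagnostics:
            lines.append(f"note: {d}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "stages": [
                {
                    "method": s.method,
                    "dim": s.dim,
                    "error": None if math.isnan(s.error) else s.error,
                    "chi": None if math.isnan(s.chi) else s.chi,
                    "wall_time": s.wall_time,
                }
                for s in self.stages
            ],
            "diagnostics": self.diagnostics,
            "final_dim": self.final_system.n,
        }
        if self.scheme is not None:
            payload["lumping"] = json.loads(self.scheme.to_json())
        if self.transform is not None:
            payload["hankel"] = self.transform.hankel_full.tolist()
            payload["T1"] = self.transform.T1.tolist()
            payload["S1"] = self.transform.S1.tolist()
        if self.indices is not None:
            payload["indices"] = self.indices.to_frame().to_dict(orient="records")
        if self.scaling is not None:
            payload["scaling"] = {
                "time_scale": self.scaling.time_scale,
                "state_scales": list(map(float, self.scaling.state_scales)),
            }
        return json.dumps(payload, indent=1)


def _score(system, reference, protocol, rtol, atol):
    try:
        traj = simulate(
            system,
            u=protocol.u_fn(system),
            t_end=protocol.t_end,
            t_eval=protocol.times(),
            rtol=rtol,
            atol=atol,
        )
    except BlowUpError:
        return math.inf
    return max_relative_error(reference, traj).E


def _chi_or_nan(system, x=None):
    try:
        return stiffness_coefficient(system, x)
    except Exception:
        return math.nan


def run_combined_reduction(network, spec, config: ReductionConfig) -> ReductionReport:
    """Run the full combined reduction on a reaction network.

    Returns the lowest-dimensional model whose maximal relative output
    error under the validation protocol stays within ``config.max_error``.
    """
    stages = []
    diagnostics = []
    t0 = _time.perf_counter()

    full = build_state_space(network, spec)
    try:
        find_steady_state(full, rtol=config.rtol)
    except NonConvergenceError as exc:
        raise NonConvergenceError(
            f"model is not asymptotically stable under the unperturbed input: {exc}"
        ) from exc

    # --- nondimensionalisation ------------------------------------------
    scaling = None
    system = full
    if config.apply_nondim:
        candidates = nondim.propose_scalings(
            network, n_candidates=config.n_nondim_candidates, seed=config.seed
        )
        scored = [(nondim.score_scaling(c.scaled_parameters), i) for i, c in enumerate(candidates)]
        scored.sort()
        scaling = candidates[scored[0][1]]
        system = nondim.apply_scaling(full, scaling)

    proto = config.protocol
    reference = simulate(
        system,
        u=proto.u_fn(system),
        t_end=proto.t_end,
        t_eval=proto.times(),
        rtol=config.rtol,
        atol=config.atol,
    )

    # --- conservation analysis ------------------------------------------
    N = stoichiometry_matrix(network)
    # drop rows of species converted to inputs, rescale to the applied scaling
    keep = [i for i, sid in enumerate(network.species_ids) if sid in full.names]
    N = N[keep]
    gamma = left_null_space(N).astype(float)
    if scaling is not None:
        # relations Gamma x = const become Gamma diag(s) x_scaled = const
        gamma = gamma * scaling.scales_for(full.names)[None, :]
    try:
        x_star = find_steady_state(system, rtol=config.rtol)
    except NonConvergenceError:
        x_star = None
    ranking = speed_rank(system, x_star) if x_star is not None else speed_rank(system)
    conservation = select_eliminations(gamma, system.x0, ranking)
    realisation = eliminate_states(system, conservation, ranking)
    system = realisation.system
    stages.append(
        StageRecord(
            "conservation", system.n, 0.0, _chi_or_nan(system),
            _time.perf_counter() - t0,
        )
    )

    # --- forward-selection lumping --------------------------------------
    t0 = _time.perf_counter()
    lump_cfg = LumpConfig(
        max_error=config.max_error,
        chi_c=config.chi_c,
        protocol=proto,
        T_avg=config.T_avg,
        rtol=config.rtol,
        atol=config.atol,
    )
    scheme = forward_selection_lump(system, lump_cfg)
    lumped = (
        galerkin_reduce(system, scheme.L, scheme.L_bar)
        if scheme.ntilde < scheme.n
        else system
    )
    if scheme.ntilde < scheme.n:
        stages.append(
            StageRecord(
                "lump", lumped.n, scheme.per_step_error[-1],
                scheme.per_step_chi[-1], _time.perf_counter() - t0,
            )
        )
    best = lumped
    best_E = scheme.per_step_error[-1] if scheme.per_step_error else 0.0

    # --- empirical balanced truncation ----------------------------------
    t0 = _time.perf_counter()
    transform = None
    indices = None
    gramians = None
    try:
        design_p = PerturbationDesign.sample(
            seed=config.seed,
            n_input=config.n_input_scales,
            n_state=config.n_state_scales,
            low=config.pert_low,
            high=config.pert_high,
            horizon=config.gramian_horizon or proto.t_end,
        )
        x_star_l = find_steady_state(lumped, rtol=config.rtol)
        P = empirical_controllability_gramian(
            lumped, design_p, x_star=x_star_l, rtol=config.rtol, atol=config.atol
        )
        Q = empirical_observability_gramian(
            lumped, design_p, x_star=x_star_l, rtol=config.rtol, atol=config.atol
        )
        gramians = GramianPair(P=P, Q=Q, design=design_p)
        indices = importance_indices(P, Q, labels=lumped.names)
        found = None
        for n_red in range(lumped.n - 1, 0, -1):
            try:
                tf = balancing_transform(P, Q, n_red)
            except RankError:
                continue
            cand = truncate(lumped, tf)
            E = _score(cand, reference, proto, config.rtol, config.atol)
            if E <= config.max_error:
                found = (cand, tf, E)
        if found is not None:
            best, transform, best_E = found[0], found[1], found[2]
            stages.append(
                StageRecord(
                    "truncate", best.n, best_E, _chi_or_nan(best),
                    _time.perf_counter() - t0,
                )
            )
    except (GramianFailureError, NonConvergenceError) as exc:
        diagnostics.append(
            f"empirical truncation unavailable ({exc.__class__.__name__}: {exc}); "
            "returning the lumped model"
        )

    return ReductionReport(
        stages=stages,
        final_system=best,
        scaling=scaling,
        conservation=conservation,
        scheme=scheme,
        transform=transform,
        gramians=gramians,
        indices=indices,
        diagnostics=diagnostics,
        config=config,
    )


def validate_reduction(original, reduced, protocol: Protocol) -> ErrorReport:
    """Simulate both systems under the protocol and return the maximal
    relative output error; a blow-up of the reduced model is reported as an
    infeasible reduction, not raised."""
    reference = simulate(
        original,
        u=protocol.u_fn(original),
        t_end=protocol.t_end,
        t_eval=protocol.times(),
    )
    try:
        candidate = simulate(
            reduced,
            u=protocol.u_fn(reduced),
            t_end=protocol.t_end,
            t_eval=protocol.times(),
        )
    except BlowUpError as exc:
        warnings.warn(f"reduced model could not be simulated: {exc}", stacklevel=2)
        nt, p = len(protocol.times()), original.p
        return ErrorReport(
            pointwise=np.full((nt, p), np.nan),
            E=math.inf,
            guard_mask=np.zeros((nt, p), bool),
            infeasible=True,
        )
    return max_relative_error(reference, candidate)
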