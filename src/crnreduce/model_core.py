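"""Control-affine state-space representation of reaction networks.

A biochemical reaction network is held in two forms:

* :class:`ReactionNetwork` — the structural description (species, reactions
  with kinetic laws, parameters, compartments), as read from SBML or built
  programmatically.
* :class:`ControlledSystem` — the evaluable control-affine realisation

  .. math::

      \\dot x(t) = f(x(t)) + \\sum_{i=1}^{l} g_i(x(t))\\,u_i(t),
      \\qquad y(t) = h(x(t)),

  with a symbolic right-hand side (sympy) lambdified for numerics, an exact
  symbolic Jacobian, and bookkeeping that lets reduced systems (conservation
  eliminated, lumped, balanced-truncated, rescaled) be lifted back to the
  original species coordinates.

The user declares which species or parameters act as inputs ``u`` and which
combination of species is the observed output ``h(x)`` through
:class:`InputOutputSpec`.
"""

from __future__ import annotations

import json
import keyword
import math
import os
import re
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .errors import (
    AffineDecompositionError,
    SBMLParseError,
    UnsupportedFeatureError,
)

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "InputOutputSpec",
    "ControlledSystem",
    "stoichiometry_matrix",
    "build_state_space",
    "load_sbml",
    "export_model",
    "import_model",
    "network_to_sbml",
]


_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _check_identifier(ident: str) -> str:
    if not _ID_RE.match(ident) or keyword.iskeyword(ident):
        raise ValueError(f"invalid identifier {ident!r}")
    return ident


def _sympify(expr, local_names=None):
    """Parse an expression string into sympy without evaluating names like
    ``E`` or ``S`` to constants (sympy's E is Euler's number)."""
    if isinstance(expr, sp.Expr):
        return expr
    locals_ = {} if local_names is None else {n: sp.Symbol(n) for n in local_names}
    # every bare name becomes a Symbol, never a sympy singleton
    for name in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", str(expr)):
        locals_.setdefault(name, sp.Symbol(name))
    return sp.sympify(expr, locals=locals_)


# ---------------------------------------------------------------------------
# Structural network description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    """A chemical species with an initial concentration (one shared
    concentration unit across the model) living in a compartment."""

    id: str
    initial_concentration: float
    compartment: str = "cell"

    def __post_init__(self):
        _check_identifier(self.id)
        if not math.isfinite(self.initial_concentration) or self.initial_concentration < 0:
            raise ValueError(
                f"species {self.id!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """One reaction with integer stoichiometries on each side and a kinetic
    rate law (an expression over species and parameter identifiers, in
    concentration/time units)."""

    id: str
    reactants: dict
    products: dict
    rate: sp.Expr

    def __post_init__(self):
        _check_identifier(self.id)
        for side in (self.reactants, self.products):
            for sid, coeff in side.items():
                if int(coeff) != coeff or coeff < 0:
                    raise ValueError(
                        f"reaction {self.id!r}: stoichiometry of {sid!r} must be "
                        f"a non-negative integer, got {coeff}"
                    )
        object.__setattr__(self, "rate", _sympify(self.rate))


@dataclass
class ReactionNetwork:
    """Species, reactions, kinetic parameters and compartment volumes.

    Invariants enforced at construction: species identifiers are unique,
    every identifier referenced by a rate law is a declared species,
    parameter or compartment, initial concentrations are non-negative and
    stoichiometric coefficients are non-negative integers.
    """

    species: list
    reactions: list
    parameters: dict = field(default_factory=dict)
    compartments: dict = field(default_factory=lambda: {"cell": 1.0})

    def __post_init__(self):
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species identifiers: {dup}")
        for pid, val in self.parameters.items():
            _check_identifier(pid)
            if not math.isfinite(val):
                raise ValueError(f"parameter {pid!r} is not finite")
        for cid, vol in self.compartments.items():
            if vol <= 0:
                raise ValueError(f"compartment {cid!r} volume must be > 0")
        declared = set(ids) | set(self.parameters) | set(self.compartments)
        for rxn in self.reactions:
            for sid in list(rxn.reactants) + list(rxn.products):
                if sid not in ids:
                    raise ValueError(
                        f"reaction {rxn.id!r} references undeclared species {sid!r}"
                    )
            for sym in rxn.rate.free_symbols:
                if str(sym) not in declared:
                    raise ValueError(
                        f"reaction {rxn.id!r} rate law references undeclared "
                        f"identifier {sym!s}"
                    )
        missing = {s.compartment for s in self.species} - set(self.compartments)
        if missing:
            raise ValueError(f"undeclared compartments: {sorted(missing)}")

    # -- convenience views ------------------------------------------------
    @property
    def species_ids(self):
        return [s.id for s in self.species]

    @property
    def n_species(self):
        return len(self.species)

    @property
    def x0(self):
        return np.array([s.initial_concentration for s in self.species], float)

    def rate_exprs(self, substitute_parameters=True):
        """Rate law of each reaction, optionally with numeric parameter and
        compartment values substituted."""
        subs = {}
        if substitute_parameters:
            subs = {sp.Symbol(k): v for k, v in self.parameters.items()}
            subs.update({sp.Symbol(k): v for k, v in self.compartments.items()})
        return [rxn.rate.xreplace(subs) for rxn in self.reactions]

    def odes(self, substitute_parameters=True):
        """Symbolic concentration ODE right-hand sides d[x_i]/dt.

        SBML kinetic laws are extensive (substance/time); the concentration
        rate of species *i* divides by its compartment volume.
        """
        N = stoichiometry_matrix(self)
        rates = self.rate_exprs(substitute_parameters)
        vols = {c: v for c, v in self.compartments.items()}
        out = []
        for i, spec in enumerate(self.species):
            expr = sp.Integer(0)
            for j, r in enumerate(rates):
                if N[i, j]:
                    expr = expr + int(N[i, j]) * r
            out.append(sp.expand(expr / vols[spec.compartment]))
        return out


def stoichiometry_matrix(network: ReactionNetwork) -> np.ndarray:
    """Net stoichiometry matrix N (n_species x n_reactions, integer).

    Entry (i, j) is the net production of species *i* by reaction *j*
    (products minus reactants); reversible reactions keep a single net
    column, their direction being carried by the sign of the rate law.
    """
    n, r = network.n_species, len(network.reactions)
    N = np.zeros((n, r), dtype=int)
    index = {sid: i for i, sid in enumerate(network.species_ids)}
    for j, rxn in enumerate(network.reactions):
        for sid, coeff in rxn.reactants.items():
            N[index[sid], j] -= int(coeff)
        for sid, coeff in rxn.products.items():
            N[index[sid], j] += int(coeff)
    return N


# ---------------------------------------------------------------------------
# Input/output declaration
# ---------------------------------------------------------------------------

INPUT_MODES = ("additive-rate", "parameter-scale")


@dataclass
class InputOutputSpec:
    """Declaration of input channels and the output expression.

    ``inputs`` is a list of ``(identifier, mode)`` pairs:

    * ``parameter-scale`` — the input multiplies the named rate constant
      (baseline ``u0 = 1`` reproduces the nominal model);
    * ``additive-rate`` — the input *replaces* the named parameter or the
      concentration of the named (boundary) species, so ``g_i`` is the flux
      per unit input; baseline ``u0`` is the nominal value.

    ``output_expression`` is any expression over species identifiers, e.g. a
    sum of the free and complexed forms of a phosphorylated protein.
    """

    inputs: list
    output_expression: object

    def __post_init__(self):
        for ident, mode in self.inputs:
            _check_identifier(ident)
            if mode not in INPUT_MODES:
                raise ValueError(f"unknown input mode {mode!r}; use one of {INPUT_MODES}")
        self.output_expression = _sympify(self.output_expression)


# ---------------------------------------------------------------------------
# Lineage: how a system's coordinates relate to the full species space
# ---------------------------------------------------------------------------


class Lineage:
    """Identity lineage: the system's coordinates *are* the species."""

    def lift(self, system, x):
        return np.asarray(x, float)

    def pert_map(self, system):
        return np.eye(system.n)

    def rebuild(self, system, full_x0):
        full_x0 = np.asarray(full_x0, float)
        new = system.replace(x0=full_x0)
        return new, full_x0


class ConservationLineage(Lineage):
    """Coordinates are the retained species of a conservation-eliminated
    realisation of ``inner``; conserved totals live in the trailing entries
    of ``extra_vals`` and are functions of the full initial condition."""

    def __init__(self, inner, gamma, eliminated, retained, ge_inv):
        self.inner = inner              # ControlledSystem the elimination acted on
        self.gamma = np.asarray(gamma, float)
        self.eliminated = list(eliminated)
        self.retained = list(retained)
        self.ge_inv = np.asarray(ge_inv, float)

    @property
    def c(self):
        return len(self.eliminated)

    def assemble(self, x_ret, totals):
        """Full inner-coordinate state from retained states + totals."""
        x = np.empty(self.inner.n)
        x[self.retained] = x_ret
        gr = self.gamma[:, self.retained]
        x[self.eliminated] = self.ge_inv @ (totals - gr @ np.asarray(x_ret, float))
        return x

    def lift(self, system, x):
        totals = system.extra_vals[-self.c:]
        return self.inner.lift(self.assemble(np.asarray(x, float), totals))

    def pert_map(self, system):
        pm_inner = self.inner.pert_map()
        return pm_inner[:, self.retained]

    def rebuild(self, system, full_x0):
        inner2, x_inner = self.inner.rebuild(full_x0)
        totals = self.gamma @ x_inner
        extra = np.concatenate([inner2.extra_vals, totals])
        lineage = ConservationLineage(
            inner2, self.gamma, self.eliminated, self.retained, self.ge_inv
        )
        new = system.replace(extra_vals=extra, x0=x_inner[self.retained], lineage=lineage)
        return new, new.x0


class ProjectionLineage(Lineage):
    """Coordinates are a linear projection ``z = P x_inner`` with lifting
    ``x_inner ~= Pbar z`` (lumping, balancing truncation, state rescaling)."""

    def __init__(self, inner, P, Pbar):
        self.inner = inner
        self.P = np.asarray(P, float)
        self.Pbar = np.asarray(Pbar, float)

    def lift(self, system, x):
        return self.inner.lift(self.Pbar @ np.asarray(x, float))

    def pert_map(self, system):
        return self.inner.pert_map() @ self.Pbar

    def rebuild(self, system, full_x0):
        inner2, x_inner = self.inner.rebuild(full_x0)
        lineage = ProjectionLineage(inner2, self.P, self.Pbar)
        new = system.replace(
            extra_vals=inner2.extra_vals, x0=self.P @ x_inner, lineage=lineage
        )
        return new, new.x0


# ---------------------------------------------------------------------------
# Controlled system
# ---------------------------------------------------------------------------


class ControlledSystem:
    """Evaluable control-affine system with symbolic backing.

    Parameters
    ----------
    syms : sequence of sympy Symbols, the state variables (length n).
    f_exprs : length-n sequence of sympy expressions, the drift.
    g_exprs : n x l sympy Matrix (or nested list), one column per input
        channel; may have zero columns for an autonomous system.
    h_exprs : length-p sequence of output expressions.
    x0, u0 : initial state and unperturbed input.
    names : display names for the states (default: the symbols).
    extra_syms / extra_vals : non-state symbols bound to numeric values at
        evaluation time (conserved totals).
    species_names : labels of the original full-model species.
    lineage : how these coordinates map back to the full species space.
    time_scale : one unit of internal system time equals ``time_scale``
        units of original model time (set by nondimensionalisation).
    """

    def __init__(
        self,
        syms,
        f_exprs,
        g_exprs,
        h_exprs,
        x0,
        u0,
        names=None,
        extra_syms=(),
        extra_vals=(),
        species_names=None,
        lineage=None,
        time_scale=1.0,
    ):
        self.syms = tuple(syms)
        self.f_exprs = sp.Matrix([sp.sympify(e) for e in f_exprs])
        g = sp.Matrix(g_exprs) if not isinstance(g_exprs, sp.MatrixBase) else g_exprs
        if g.shape[0] == 0 or g.shape[1] == 0:
            g = sp.zeros(len(self.syms), g.shape[1] if g.shape[0] else 0)
        self.g_exprs = g
        self.h_exprs = sp.Matrix([sp.sympify(e) for e in h_exprs])
        self.x0 = np.atleast_1d(np.asarray(x0, float))
        self.u0 = np.atleast_1d(np.asarray(u0, float)) if np.size(u0) else np.zeros(0)
        self.names = list(names) if names is not None else [str(s) for s in self.syms]
        self.extra_syms = tuple(extra_syms)
        self.extra_vals = np.asarray(extra_vals, float)
        self.species_names = (
            list(species_names) if species_names is not None else list(self.names)
        )
        self.lineage = lineage if lineage is not None else Lineage()
        self.time_scale = float(time_scale)
        if self.f_exprs.shape[0] != self.n or len(self.x0) != self.n:
            raise ValueError("f/x0 dimension mismatch")
        if self.g_exprs.shape != (self.n, self.l):
            raise ValueError(
                f"g must be {self.n} x {self.l}, got {self.g_exprs.shape}"
            )
        self._cache = {}

    # -- dimensions -------------------------------------------------------
    @property
    def n(self):
        return len(self.syms)

    @property
    def l(self):
        return len(self.u0)

    @property
    def p(self):
        return self.h_exprs.shape[0]

    # -- construction helpers --------------------------------------------
    def replace(self, **kw):
        args = dict(
            syms=self.syms,
            f_exprs=self.f_exprs,
            g_exprs=self.g_exprs,
            h_exprs=self.h_exprs,
            x0=self.x0,
            u0=self.u0,
            names=self.names,
            extra_syms=self.extra_syms,
            extra_vals=self.extra_vals,
            species_names=self.species_names,
            lineage=self.lineage,
            time_scale=self.time_scale,
        )
        args.update(kw)
        return ControlledSystem(**args)

    # -- numeric evaluation ------------------------------------------------
    def _lambdify(self, key, exprs):
        if key not in self._cache:
            args = list(self.syms) + list(self.extra_syms)
            self._cache[key] = sp.lambdify(args, exprs, modules="numpy")
        return self._cache[key]

    def _call(self, key, exprs, x):
        fn = self._lambdify(key, exprs)
        out = fn(*np.asarray(x, float), *self.extra_vals)
        return np.asarray(out, float)

    def f(self, x):
        return self._call("f", self.f_exprs, x).reshape(self.n)

    def g(self, x):
        if self.l == 0:
            return np.zeros((self.n, 0))
        return self._call("g", self.g_exprs, x).reshape(self.n, self.l)

    def h(self, x):
        return self._call("h", self.h_exprs, x).reshape(self.p)

    def rhs(self, x, u=None):
        u = self.u0 if u is None else np.atleast_1d(np.asarray(u, float))
        out = self.f(x)
        if self.l:
            out = out + self.g(x) @ u
        return out

    def jac(self, x, u=None):
        """Symbolic Jacobian of ``f(x) + g(x) u`` (default ``u = u0``)."""
        u = self.u0 if u is None else np.atleast_1d(np.asarray(u, float))
        key = ("jac", tuple(np.round(u, 15)))
        if key not in self._cache:
            total = self.f_exprs
            for i in range(self.l):
                total = total + self.g_exprs[:, i] * float(u[i])
            jac_expr = total.jacobian(self.syms)
            args = list(self.syms) + list(self.extra_syms)
            self._cache[key] = sp.lambdify(args, jac_expr, modules="numpy")
        out = self._cache[key](*np.asarray(x, float), *self.extra_vals)
        return np.asarray(out, float).reshape(self.n, self.n)

    # -- lineage ----------------------------------------------------------
    def lift(self, x):
        """Map a state in current coordinates to full species coordinates."""
        return self.lineage.lift(self, x)

    def pert_map(self):
        """(n_species x n) matrix whose column i is the full-space direction
        in which a unit perturbation of current coordinate i is realised."""
        return self.lineage.pert_map(self)

    def rebuild(self, full_x0):
        """Re-derive this system for a perturbed *full-model* initial
        condition: conserved totals are recomputed from ``full_x0`` so the
        perturbation cannot violate conservation.  Returns the rebuilt
        system and the initial state in current coordinates."""
        return self.lineage.rebuild(self, np.asarray(full_x0, float))

    # -- sanity -----------------------------------------------------------
    def validate(self, rtol=1e-5):
        """Check that f, g, h evaluate at x0 and that the symbolic Jacobian
        agrees with a finite-difference estimate."""
        x0 = self.x0
        for fn in (self.f, self.g, self.h):
            val = fn(x0)
            if not np.all(np.isfinite(val)):
                raise ValueError(f"{fn.__name__} not finite at x0")
        J = self.jac(x0)
        Jfd = np.zeros_like(J)
        step = 1e-6 * (1.0 + np.abs(x0))
        for j in range(self.n):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += step[j]
            xm[j] -= step[j]
            Jfd[:, j] = (self.rhs(xp) - self.rhs(xm)) / (2 * step[j])
        scale = max(np.max(np.abs(J)), 1e-30)
        err = np.max(np.abs(J - Jfd)) / scale
        if err > rtol * 100:  # central differences are ~1e-10 accurate; allow head-room
            raise ValueError(f"Jacobian mismatch: rel err {err:.2e}")
        return True

    def __repr__(self):
        return (
            f"ControlledSystem(n={self.n}, l={self.l}, p={self.p}, "
            f"states={self.names})"
        )


# ---------------------------------------------------------------------------
# Network -> state space
# ---------------------------------------------------------------------------


def build_state_space(network: ReactionNetwork, spec: InputOutputSpec) -> ControlledSystem:
    """Realise a network plus input/output declaration as Eq.-(1)-form
    control-affine dynamics.

    Raises :class:`AffineDecompositionError` if an input identifier enters
    any rate law nonlinearly, and ``ValueError`` for unknown identifiers.
    """
    sids = network.species_ids
    known = set(sids) | set(network.parameters)
    for ident, _mode in spec.inputs:
        if ident not in known:
            raise ValueError(f"input identifier {ident!r} is not a species or parameter")
    for sym in spec.output_expression.free_symbols:
        if str(sym) not in sids:
            raise ValueError(f"output expression references unknown species {sym!s}")

    odes = network.odes(substitute_parameters=False)
    param_subs = {sp.Symbol(k): sp.Float(v) for k, v in network.parameters.items()}
    param_subs.update({sp.Symbol(k): sp.Float(v) for k, v in network.compartments.items()})

    u_syms, u0 = [], []
    removed_species = []
    for idx, (ident, mode) in enumerate(spec.inputs):
        u = sp.Symbol(f"_u{idx}")
        u_syms.append(u)
        target = sp.Symbol(ident)
        if mode == "parameter-scale":
            if ident not in network.parameters:
                raise ValueError(
                    f"parameter-scale input {ident!r} must name a parameter"
                )
            odes = [e.xreplace({target: target * u}) for e in odes]
            u0.append(1.0)
        else:  # additive-rate: u replaces the parameter value / species conc.
            odes = [e.xreplace({target: u}) for e in odes]
            if ident in network.parameters:
                u0.append(float(network.parameters[ident]))
                param_subs.pop(target, None)
            else:
                removed_species.append(ident)
                u0.append(float(network.species[sids.index(ident)].initial_concentration))
            if target in spec.output_expression.free_symbols:
                raise ValueError(
                    f"species {ident!r} is an input and cannot appear in the output"
                )

    keep = [i for i, sid in enumerate(sids) if sid not in removed_species]
    syms = tuple(sp.Symbol(sids[i]) for i in keep)
    odes = [sp.expand(odes[i].xreplace(param_subs)) for i in keep]

    # affine split: f = rhs|_{u=0}, g_i = d(rhs)/d(u_i); residual dependence on
    # any input symbol means the model is not control-affine.
    zero_u = {u: 0 for u in u_syms}
    f_exprs = [e.xreplace(zero_u) for e in odes]
    g_cols = []
    for u in u_syms:
        col = [sp.expand(sp.diff(e, u)) for e in odes]
        g_cols.append(col)
    for u in u_syms:
        for col in g_cols:
            for entry in col:
                if u in entry.free_symbols:
                    raise AffineDecompositionError(
                        f"input {u!s} enters the dynamics nonlinearly "
                        f"(term {entry!s}); the control-affine form requires "
                        "each input to appear linearly"
                    )
    g_exprs = sp.Matrix([[g_cols[i][j] for i in range(len(u_syms))] for j in range(len(keep))]) \
        if u_syms else sp.zeros(len(keep), 0)

    h_expr = spec.output_expression.xreplace(param_subs)
    x0 = network.x0[keep]
    system = ControlledSystem(
        syms,
        f_exprs,
        g_exprs,
        [h_expr],
        x0=x0,
        u0=np.asarray(u0, float),
        names=[sids[i] for i in keep],
        species_names=[sids[i] for i in keep],
    )
    hval = system.h(x0)
    if not np.all(np.isfinite(hval)):
        raise ValueError("output expression does not evaluate to a finite value at x0")
    return system


# ---------------------------------------------------------------------------
# SBML input
# ---------------------------------------------------------------------------


def _require_libsbml():
    import libsbml  # noqa: deferred so the numerics work without it

    return libsbml


def load_sbml(document: str) -> ReactionNetwork:
    """Read an SBML Level 2/3 document (text or file path) into a
    :class:`ReactionNetwork`.

    Supported constructs: compartments, species (initialConcentration or
    initialAmount), global and local parameters, reactions with kinetic
    laws, and function definitions (inlined).  Events, algebraic/assignment/
    rate rules and constraints are outside the ODE core and raise
    :class:`UnsupportedFeatureError`; a reaction without a kinetic law does
    too.
    """
    libsbml = _require_libsbml()
    looks_like_path = len(document) < 4096 and "\n" not in document and "<" not in document
    if looks_like_path and os.path.exists(document):
        doc = libsbml.readSBMLFromFile(document)
    else:
        doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLParseError("SBML parse error: " + "; ".join(m.strip() for m in msgs))
    model = doc.getModel()
    if model is None:
        raise SBMLParseError("document contains no model")

    if model.getNumEvents():
        raise UnsupportedFeatureError("SBML events are not supported")
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        kind = rule.getElementName()
        raise UnsupportedFeatureError(f"SBML {kind} rules are not supported")
    if model.getNumConstraints():
        raise UnsupportedFeatureError("SBML constraints are not supported")
    if model.getNumFunctionDefinitions():
        # inline user function definitions so rate laws are plain expressions
        props = libsbml.ConversionProperties()
        props.addOption("expandFunctionDefinitions", True)
        if doc.convert(props) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise UnsupportedFeatureError("could not inline SBML functionDefinitions")
        model = doc.getModel()

    compartments = {}
    for i in range(model.getNumCompartments()):
        comp = model.getCompartment(i)
        size = comp.getSize()
        compartments[comp.getId()] = 1.0 if (size is None or math.isnan(size)) else size
    if not compartments:
        compartments = {"cell": 1.0}

    species = []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        if s.isSetInitialConcentration():
            conc = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            conc = s.getInitialAmount() / compartments.get(s.getCompartment(), 1.0)
        else:
            conc = 0.0
        comp = s.getCompartment() or next(iter(compartments))
        species.append(Species(s.getId(), float(conc), comp))

    parameters = {}
    for i in range(model.getNumParameters()):
        par = model.getParameter(i)
        parameters[par.getId()] = float(par.getValue()) if par.isSetValue() else 0.0

    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        kl = rxn.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise UnsupportedFeatureError(
                f"reaction {rxn.getId()!r} has no kinetic law"
            )
        # local parameters get a reaction-scoped name
        local = {}
        n_local = (
            kl.getNumLocalParameters()
            if hasattr(kl, "getNumLocalParameters") and kl.getNumLocalParameters()
            else kl.getNumParameters()
        )
        getter = (
            kl.getLocalParameter
            if hasattr(kl, "getLocalParameter") and kl.getNumLocalParameters()
            else kl.getParameter
        )
        for k in range(n_local):
            par = getter(k)
            scoped = f"{rxn.getId()}_{par.getId()}"
            local[par.getId()] = scoped
            parameters[scoped] = float(par.getValue()) if par.isSetValue() else 0.0

        formula = libsbml.formulaToL3String(kl.getMath())
        rate = _parse_l3_formula(formula, local)
        reactants = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            reactants[ref.getSpecies()] = reactants.get(ref.getSpecies(), 0) + int(
                ref.getStoichiometry() if ref.isSetStoichiometry() else 1
            )
        products = {}
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            products[ref.getSpecies()] = products.get(ref.getSpecies(), 0) + int(
                ref.getStoichiometry() if ref.isSetStoichiometry() else 1
            )
        reactions.append(Reaction(rxn.getId(), reactants, products, rate))

    return ReactionNetwork(species, reactions, parameters, compartments)


_L3_FUNCS = {
    "exp": sp.exp,
    "ln": sp.log,
    "log": sp.log,
    "log10": lambda x: sp.log(x, 10),
    "sqrt": sp.sqrt,
    "abs": sp.Abs,
    "pow": sp.Pow,
    "power": sp.Pow,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "tanh": sp.tanh,
    "floor": sp.floor,
    "ceiling": sp.ceiling,
}


def _parse_l3_formula(formula: str, local_renames: dict) -> sp.Expr:
    """Parse a libsbml L3 formula string into sympy.

    Time-dependent or piecewise laws are outside the autonomous ODE core.
    """
    for bad in ("piecewise", "delay", "time", "rateOf"):
        if re.search(rf"\b{bad}\b", formula):
            raise UnsupportedFeatureError(
                f"kinetic law uses unsupported construct {bad!r}: {formula}"
            )
    text = formula.replace("^", "**")
    locals_ = dict(_L3_FUNCS)
    for name in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", text):
        if name in locals_:
            continue
        locals_[name] = sp.Symbol(local_renames.get(name, name))
    try:
        return sp.sympify(text, locals=locals_)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise UnsupportedFeatureError(f"cannot parse kinetic law {formula!r}: {exc}")


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def network_to_sbml(network: ReactionNetwork, model_id="model") -> str:
    """Serialise a reaction network as SBML Level 3 Version 1."""
    libsbml = _require_libsbml()
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(model_id)
    for cid, vol in network.compartments.items():
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setSize(float(vol))
        comp.setConstant(True)
    for s in network.species:
        spec = model.createSpecies()
        spec.setId(s.id)
        spec.setCompartment(s.compartment)
        spec.setInitialConcentration(float(s.initial_concentration))
        spec.setHasOnlySubstanceUnits(False)
        spec.setBoundaryCondition(False)
        spec.setConstant(False)
    for pid, val in network.parameters.items():
        par = model.createParameter()
        par.setId(pid)
        par.setValue(float(val))
        par.setConstant(True)
    for rxn in network.reactions:
        r = model.createReaction()
        r.setId(rxn.id)
        r.setReversible(True)
        r.setFast(False)
        for sid, coeff in rxn.reactants.items():
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid, coeff in rxn.products.items():
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        kl = r.createKineticLaw()
        math_ast = libsbml.parseL3Formula(_expr_to_l3(rxn.rate))
        if math_ast is None:
            raise ValueError(f"cannot serialise rate law of {rxn.id!r}")
        kl.setMath(math_ast)
    return libsbml.writeSBMLToString(doc)


def _expr_to_l3(expr: sp.Expr) -> str:
    text = sp.StrPrinter({"full_prec": False}).doprint(sp.expand(expr))
    return text.replace("**", "^")


def export_model(system: ControlledSystem, format: str = "sbml", metadata=None) -> str:
    """Serialise a (possibly reduced) system.

    ``format="sbml"`` — states become SBML species and the dynamics at the
    unperturbed input ``u0`` become one pseudo-reaction per state (the net
    production rate), so lumped models — whose states are sums of species —
    remain valid SBML; the lump membership is recorded in an annotation.
    This round-trips through :func:`load_sbml`.

    ``format="json"`` — full serialised ODE definition: symbolic right-hand
    sides for f, g, h, initial state, baseline input and any conserved
    totals, plus whatever ``metadata`` is supplied (projection matrices,
    Hankel values, Gramians for truncated models).
    """
    if format == "json":
        payload = {
            "states": [str(s) for s in system.syms],
            "names": system.names,
            "f": [str(e) for e in system.f_exprs],
            "g": [[str(system.g_exprs[i, j]) for j in range(system.l)] for i in range(system.n)],
            "h": [str(e) for e in system.h_exprs],
            "x0": system.x0.tolist(),
            "u0": system.u0.tolist(),
            "extra": {str(s): float(v) for s, v in zip(system.extra_syms, system.extra_vals)},
            "time_scale": system.time_scale,
            "species_names": system.species_names,
        }
        if metadata:
            payload["metadata"] = _jsonable(metadata)
        return json.dumps(payload, indent=1)
    if format == "sbml":
        libsbml = _require_libsbml()
        doc = libsbml.SBMLDocument(3, 1)
        model = doc.createModel()
        model.setId("reduced_model")
        comp = model.createCompartment()
        comp.setId("cell")
        comp.setSize(1.0)
        comp.setConstant(True)
        subs = {s: sp.Float(v) for s, v in zip(system.extra_syms, system.extra_vals)}
        rhs = system.f_exprs + (
            system.g_exprs * sp.Matrix(system.u0) if system.l else sp.zeros(system.n, 1)
        )
        for i, sym in enumerate(system.syms):
            spec = model.createSpecies()
            spec.setId(str(sym))
            spec.setCompartment("cell")
            spec.setInitialConcentration(float(system.x0[i]))
            spec.setHasOnlySubstanceUnits(False)
            spec.setBoundaryCondition(False)
            spec.setConstant(False)
            spec.setAnnotation(
                f'<membership xmlns="https://crnreduce/ns">{system.names[i]}</membership>'
            )
        for i, sym in enumerate(system.syms):
            r = model.createReaction()
            r.setId(f"d_{sym}")
            r.setReversible(True)
            r.setFast(False)
            ref = r.createProduct()
            ref.setSpecies(str(sym))
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
            for other in system.syms:
                if other != sym and other in rhs[i].free_symbols:
                    mod = r.createModifier()
                    mod.setSpecies(str(other))
            kl = r.createKineticLaw()
            expr = sp.expand(rhs[i].xreplace(subs))
            ast = libsbml.parseL3Formula(_expr_to_l3(expr))
            if ast is None:
                raise ValueError(f"cannot serialise rate of state {sym}")
            kl.setMath(ast)
        return libsbml.writeSBMLToString(doc)
    raise ValueError(f"unsupported export format {format!r}; use 'sbml' or 'json'")


def import_model(text: str) -> ControlledSystem:
    """Inverse of ``export_model(..., format='json')``."""
    payload = json.loads(text)
    syms = tuple(sp.Symbol(s) for s in payload["states"])
    local = {str(s): s for s in syms}
    extra_syms = tuple(sp.Symbol(k) for k in payload.get("extra", {}))
    local.update({str(s): s for s in extra_syms})

    def parse(e):
        return _sympify(e, local_names=list(local))

    f = [parse(e) for e in payload["f"]]
    n = len(f)
    gl = payload["g"]
    ncols = len(gl[0]) if gl and gl[0] else 0
    g = sp.Matrix([[parse(gl[i][j]) for j in range(ncols)] for i in range(n)]) \
        if ncols else sp.zeros(n, 0)
    h = [parse(e) for e in payload["h"]]
    return ControlledSystem(
        syms,
        f,
        g,
        h,
        x0=payload["x0"],
        u0=payload["u0"],
        names=payload.get("names"),
        extra_syms=extra_syms,
        extra_vals=[payload["extra"][str(s)] for s in extra_syms],
        species_names=payload.get("species_names"),
        time_scale=payload.get("time_scale", 1.0),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
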