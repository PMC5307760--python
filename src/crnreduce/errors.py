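"""Exception hierarchy.

Several failures are *signals* the reduction pipeline is designed to absorb
(a candidate reduction that cannot be integrated is scored infeasible, not
fatal); they are still raised as exceptions at the operation level so that
callers can distinguish them.
"""


class CrnReduceError(Exception):
    """Base class for all package errors."""


class SBMLParseError(CrnReduceError):
    """The document is not well-formed SBML."""


class UnsupportedFeatureError(CrnReduceError):
    """The SBML document uses a construct outside the supported ODE core.

    The offending construct (events, algebraic/assignment rules, missing
    kinetic laws, ...) is named in the message.
    """


class AffineDecompositionError(CrnReduceError):
    """A declared input enters the dynamics nonlinearly.

    The control-affine form ``xdot = f(x) + sum_i g_i(x) u_i`` requires every
    input to appear linearly in the right-hand side.
    """


class BlowUpError(CrnReduceError):
    """Stiff integration failed (step-size underflow / non-finite state).

    Carries ``time``, the integration time at which failure occurred.  The
    pipeline treats this as "reduction infeasible at this dimension", not as
    a crash.
    """

    def __init__(self, message, time=None):
        super().__init__(message)
        self.time = time


class NonConvergenceError(CrnReduceError):
    """No steady state was located within the allotted horizon."""


class DegenerateOutputError(CrnReduceError):
    """Every time point of an output fell below the relative-error guard."""


class UndefinedStiffnessError(CrnReduceError):
    """All Jacobian eigenvalues are numerically zero."""


class SingularityError(CrnReduceError):
    """A steady-state lumping inverse hit an all-zero block."""


class DegeneratePairError(CrnReduceError):
    """Both members of a lumped pair are identically zero on the averaging
    interval."""


class EliminationInfeasibleError(CrnReduceError):
    """No assignment of species to conservation relations keeps the
    eliminated sub-matrix invertible."""


class GramianFailureError(CrnReduceError):
    """A perturbed simulation used to assemble an empirical Gramian blew up.

    This is the stiffness failure mode that lumping, used as a
    preconditioner, exists to avoid.
    """

    def __init__(self, message, perturbation=None):
        super().__init__(message)
        self.perturbation = perturbation


class RankError(CrnReduceError):
    """Requested reduced dimension exceeds the numerical rank of the
    balancing problem."""

    def __init__(self, message, max_feasible=None):
        super().__init__(message)
        self.max_feasible = max_feasible


class UndefinedIndexError(CrnReduceError):
    """Both Gramians are identically zero; importance indices undefined."""


class GenerationError(CrnReduceError):
    """A synthetic-fixture generator was asked for an infeasible
    configuration."""
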