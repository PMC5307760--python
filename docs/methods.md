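# Methods

`crnreduce` reduces controlled biochemical reaction-network ODE models —
systems of the control-affine form

    dx/dt = f(x) + Σᵢ gᵢ(x) uᵢ ,   y = h(x)

where x are species concentrations, u declared inputs (a ligand level, a
scaled binding rate) and y a declared output combination of species — while
preserving the input–output response. Four techniques are composed:
nondimensionalisation, conservation analysis, proper lumping and empirical
balanced truncation. This note records the model assumptions, the numerical
choices, and what the synthetic fixtures do and do not establish.

## The control-affine realisation

Models enter as SBML (Level 2/3) or programmatic `ReactionNetwork` objects.
Inputs come in two modes: *parameter-scale* (u multiplies a named rate
constant; baseline u₀ = 1) and *additive-rate* (u replaces a parameter or a
boundary-species concentration; baseline u₀ is the nominal value). The
right-hand side is split as f = rhs|_{u=0}, gᵢ = ∂rhs/∂uᵢ; any residual
dependence of gᵢ on an input means the model is not affine in u and is
rejected rather than linearised, since every downstream construction
assumes affinity. The Jacobian is computed symbolically (sympy) and checked
against finite differences at construction.

Reduced systems carry a *lineage*: the composition of projections and
eliminations that produced them. This lets any reduced state be lifted back
to species coordinates, and — crucially for the Gramian stage — lets a
perturbation of the full initial condition rebuild the reduced system with
consistently recomputed conserved totals.

## Error metric and stiffness

Reduction quality is the maximal relative output error
E = sup over time and outputs of |yᵢ(t) − ȳᵢ(t)| / |yᵢ(t)|, evaluated on
the reference grid with the candidate interpolated by monotone cubic
(PCHIP) splines. The bare metric has no zero protection, so time points
with |yᵢ(t)| < δ·max_t|yᵢ| are masked (δ = 1e−3 by default) and reported;
an output that is masked everywhere is an error, not an E of infinity.

The stiffness coefficient is χ = max|λ| / min|λ| over Jacobian eigenvalues
at a reference state. Moduli are used (the spectrum of a reaction network
is generally complex), and eigenvalues below 1e−9 of the largest modulus
are excluded: closed networks carry one exact zero mode per conserved
moiety, which would otherwise make every such model infinitely stiff. χ is
invariant under diagonal state rescaling and uniform time rescaling, which
the tests verify on random linear systems.

## Nondimensionalisation

With a fully parameterised model the only purpose of rescaling is
floating-point conditioning, so the package samples 50 candidate scalings
(time scale = reciprocal of a sampled rate constant; species scales drawn
from the species' initial value, its conserved total, or the global maximum
initial value) and keeps the candidate minimising
σ = log₁₀(max p̃ / min p̃), the order-of-magnitude spread of the
dimensionless parameter set. p̃ is taken as the nonzero monomial
coefficients of the scaled polynomial right-hand side — exact for mass
action; non-polynomial rate laws fall back to {p·t_s}. Because a scaling is
a similarity transform plus a time rescale, the output trajectory in
original units is invariant under the choice (asserted on every fixture);
only conditioning differs, so the sampling scheme cannot bias any reported
error. The simulator stores the time scale on the system and converts at
the boundary, so all user-facing times stay in original units.

## Conservation analysis and speed ranking

The rank of the stoichiometry matrix N is decided by a column-pivoted
Householder QR of Nᵀ (|R_kk| > rank_tol·|R₁₁|, rank_tol = 1e−9), the
numerically stable route for large models; the left-null basis itself is
computed exactly over the rationals (N is integer) and scaled to
smallest-integer form. A greedy integer sparsification (pairwise row
combinations that shrink support) recovers natural moiety vectors from the
raw rational basis — without it, a mixed basis can force the elimination of
a fast species and spoil the lumping stage.

One species is eliminated per relation. Species are ranked by |J_ii| at the
unperturbed steady state — the outgoing concentration rate of each state —
and the *slowest* are eliminated, keeping fast species explicit for lumping
to absorb. Relations are processed most-constrained-first (fewest candidate
species) and each takes its slowest still-available species subject to the
eliminated submatrix of Γ remaining invertible; an infeasible assignment is
reported with the offending relation. Conserved totals are stored as
symbols bound at evaluation time (functions of the initial condition), so
Gramian-stage perturbations of x₀ update them automatically.

## Proper lumping

A proper lumping x̃ = Lx (L ∈ {0,1}, columns pairwise orthogonal) keeps
lumped states interpretable as sums of concentrations. Reduced dynamics use
the Galerkin projection f̃ = L f(L̄ x̃) for a generalised right-inverse L̄
with L L̄ = I. Three inverses are implemented:

* **Moore–Penrose** L⁺ = Lᵀ(LLᵀ)⁻¹ — uniform within-block weights;
* **steady-state** L̄ = X Lᵀ(LXLᵀ)⁻¹, X = diag(x*) — reconstructs the
  unperturbed steady state exactly, singular when a block's steady state is
  entirely zero (raised as a distinct error);
* **time-averaged** — pairwise weights w_h = (1/T)∫₀ᵀ x_h/(x_h+x_k) dt by
  trapezoidal quadrature on the unperturbed trajectory, with sub-guard
  points excluded and the average renormalised to the included measure. As
  T grows this converges to the steady-state inverse when the steady state
  is nonzero, but remains finite when it is zero. T defaults to the time at
  which ‖x(t) − x*‖/‖x₀ − x*‖ < 1e−3.

Any multi-state lump is the composition of pairwise lumps (L = L_out·L_in,
L̄ = L̄_in·L̄_out), which is how the averaged inverse generalises.

Forward selection lumps one pair per step: every unordered pair is tried
with both the steady-state and the averaged inverse, each candidate is
simulated under the scoring protocol (by default the same step-input
protocol used for final validation — the choice is configurable because no
single canonical scoring input exists), and the minimum-E candidate is
applied. Blow-ups score E = ∞ and are excluded rather than fatal. Ties
prefer the lower resulting χ, then lexicographic pair order. The loop exits
when the best candidate would exceed the error budget (inclusive ≤
comparison), when χ falls below the critical value χ_c (default 250, and
checked once before the loop: a system already below χ_c is not lumped), or
at one state. The greedy assumption — that the best k-dimensional lumping
extends the best (k+1)-dimensional one — is adopted as-is; there is no
backtracking. Lumping tends to absorb fast-equilibrating pairs first and so
strips stiffness with each step; this is an observed tendency on the stiff
fixtures (asserted there), not a theorem.

## Empirical Gramians and balanced truncation

Empirical Gramians generalise the linear controllability/observability
Gramians to nonlinear systems via perturbed simulations around the
unperturbed steady state x*.

*Controllability*: an impulse of strength c through channel i displaces the
state to x* + c·gᵢ(x*); the state deviation z(t) = x(t) − x* is integrated
as a quadrature-weighted outer product, normalised by 1/c², averaged over
perturbation magnitudes and summed over channels. Magnitudes derive from
multipliers sampled uniformly on [0.2, 1.8] of the baseline input by
default (c = (m−1)·u_ref). The impulse realisation is chosen because it
makes the construction converge, for linear systems, to the Lyapunov
controllability Gramian — the package's correctness oracle: a sustained
step held over the horizon would measure deviations that tend to the
*perturbed* steady state and the integral would not converge to any
Lyapunov quantity.

*Observability*: per magnitude, each state coordinate is displaced by
a = (m−1)·sᵢ (sᵢ = |x*ᵢ|, or 1 for zero coordinates). The displacement is
realised in full species coordinates and the system rebuilt from the
perturbed full initial condition, which recomputes the conserved totals —
no perturbation can step off the conservation manifold. Output deviations
from the unperturbed output, normalised per run, assemble Q.

Quadrature is trapezoidal on the solver grid (401 points over the horizon
by default); both matrices are symmetrised. A blown-up perturbed run raises
a Gramian-failure error naming the perturbation — this is precisely the
stiffness failure mode the lumping preconditioner exists to avoid, and the
pipeline degrades gracefully to the lumped model when it happens.

Balancing follows the square-root route: Cholesky factors 𝒫 = LᵀL,
𝒬 = RᵀR (a ridge of 1e−12·trace/n is added before factorisation to
tolerate quadrature-level semidefiniteness), SVD of LRᵀ = UΣVᵀ, and
T₁ = Σ₁^{−1/2}V₁ᵀR, S₁ = LᵀU₁Σ₁^{−1/2}. Both transformed Gramians then
equal diag(Σ₁), the Hankel singular values. Requesting more states than the
numerical rank of LRᵀ (relative cutoff 1e−10) raises an error carrying the
maximal feasible dimension. Truncation is the same Galerkin projection with
(T₁, S₁) in place of (L, L̄).

Per-state importance indices are read from the Gramian diagonals in the
(lumped) biological coordinates: ν_c = √diag 𝒫 and ν_o = √diag 𝒬, each
rescaled to maximum one, and ν their elementwise product rescaled again. A
zero index means the state neither responds to the input (ν_c) nor moves
the output (ν_o).

## The combined pipeline

Order: realise → nondimensionalise → conservation-eliminate (speed-ranked)
→ forward-selection lumping until E-violation, χ < χ_c, or ñ = 1 →
empirical Gramians → balancing → truncation. The truncation stage scans
every candidate dimension from ñ−1 downward and keeps the *smallest* that
meets the error budget, rather than stopping at the first failure, because
Hankel ordering does not guarantee monotone error for nonlinear systems.
The returned model is the lowest-dimensional one with E ≤ max_error
(default 5%) under the validation protocol. Pipeline runs are deterministic
for a fixed seed and configuration. Simulation uses LSODA with the analytic
Jacobian (rtol 1e−6, atol 1e−9 by default); steady states come from long
integration over doubling horizons followed by Newton polishing, with
non-convergence (limit cycles, drift) reported as such.

## Synthetic fixtures: what they establish

* **LTI fixtures** (random stable A shifted left of a margin, random B, C)
  carry exact Lyapunov Gramians and Hankel spectra. They are the
  quantitative oracle for the Gramian and balancing stages: empirical
  Gramians must match the Lyapunov solutions elementwise within 5% after
  trace normalisation, and truncated-model L2 output error must respect the
  classical 2·Σσ bound for unit-energy inputs.
* **Conserved mass-action networks** — conversion cycles coupled by
  catalytic cross-reactions — have a prescribed left-null dimension and
  exercise the conservation machinery.
* **The stiff phosphorelay** (kinase A, response regulator Y, phosphatase
  Z, slow adaptation enzyme B; 9 species, 10 reactions, 4 moieties;
  ligand-modulated autophosphorylation as input, total phosphorylated Y as
  output) emulates the structure of receptor-signalling models: the
  phosphotransfer/phosphatase block runs `stiff_ratio` times faster than
  the rest, giving χ ≈ 6·10³ at `stiff_ratio` = 1000, with the
  phosphorylated kinase and its transfer complex as the designated
  fast-equilibrating lumpable pair. The pipeline regression asserts the
  combined algorithm at least halves the dimension at E ≤ 5% with lumping
  pushing χ below χ_c first.

These fixtures emulate stiffness, conservation and fast equilibration, but
not every feature of published models: rate laws are mass action (no
Michaelis–Menten saturation in the stiff path), dimensions are small enough
for exhaustive cross-checks, and parameters are not noisy. Passing tests
demonstrates the algorithmic machinery is correct at these scales; accuracy
on any real model still depends on its structure and parameterisation,
which is why the per-dimension error table is recomputed for every run. The
accession-dependent `scripts/reduce_case_study.py` applies the identical
pipeline to externally supplied SBML models (including adding a
user-parameterised depletion reaction for models with an accumulating pool
that would otherwise be unstable — the depletion rate is exposed as a flag
because no canonical value exists).

## Problem sizes and defaults

Default problem sizes were chosen so the full suite runs comfortably on a
single CPU: 4–5-state LTI fixtures (10 seeds for the Gramian oracle), the
9-species phosphorelay for the end-to-end pipeline, 8 perturbation
magnitudes per Gramian with a 401-point quadrature grid. Larger designs
(the 100-simulation protocol on [0.2, 1.8]) are a constructor call away and
scale linearly in simulation count.

## Known limitations

* Improper (overlapping) and nonlinear lumpings are out of scope, as are
  SBML events, delays, algebraic/assignment rules and stochastic semantics.
* Balancing assumes a stable system about x*; unstable or oscillatory
  models are rejected at the steady-state stage.
* The greedy lumping search can miss a better non-greedy lumping; the
  scoring protocol is a single input pattern, so reductions are validated
  for inputs like it, not for all signals.
* Reductions hold at the given parameterisation; robustness across
  parameter space (e.g. by Latin-hypercube perturbation of parameters
  during scoring) is not implemented.
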