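# crnreduce

Combined model reduction for **controlled biochemical reaction networks**:
conservation analysis, proper lumping (as a stiffness-reducing
preconditioner) and empirical balanced truncation, composed into one
automated pipeline that takes an SBML model plus a declaration of inputs
and outputs and returns the lowest-dimensional reduced model meeting an
error budget.

## Who this is for

Systems-biology and quantitative-pharmacology modellers working with
stiff, nonlinear, high-dimensional ODE models of signalling pathways —
models where a receptor-level quantity acts as an *input* u(t) and a
combination of intracellular species is the *output* y(t), and where the
goal of reduction is to preserve that input–output response (dose–response
behaviour) rather than every internal concentration.

## The method

Models are realised in control-affine state-space form

```
ẋ(t) = f(x(t)) + Σᵢ gᵢ(x(t)) uᵢ(t),      y(t) = h(x(t)),
```

and reduced in stages:

1. **Nondimensionalisation** — 50 sampled scalings, keep the one
   minimising σ = log₁₀(max p̃ / min p̃), the order-of-magnitude spread of
   the dimensionless parameter set (conditioning only; dynamics are
   invariant).
2. **Conservation analysis** — left null space Γ of the stoichiometry
   matrix via column-pivoted Householder QR plus an exact integer basis;
   one species per conserved moiety is eliminated algebraically. Species
   are *speed-ranked* by |J_ii| at the unperturbed steady state and the
   slowest eliminated, keeping fast species explicit for lumping.
3. **Proper lumping** — forward selection: at each step every pair of
   states is trially lumped (x̃ = Lx, reduced dynamics by the Galerkin
   projection f̃ = L f(L̄x̃)) with both the steady-state inverse
   L̄ = XLᵀ(LXLᵀ)⁻¹ and a time-averaged inverse; the lowest-error pair is
   applied until the error budget, χ < χ_c, or one state. Lumping strips
   stiffness (χ = max|λ|/min|λ| of the Jacobian), which is what makes the
   next stage numerically feasible.
4. **Empirical balanced truncation** — controllability/observability
   Gramians 𝒫, 𝒬 from perturbed simulations (input impulses and
   conservation-consistent initial-condition perturbations, multipliers
   sampled on 0.2–1.8 of baseline), square-root balancing
   (𝒫 = LᵀL, 𝒬 = RᵀR, SVD of LRᵀ, T₁ = Σ₁^{-1/2}V₁ᵀR, S₁ = LᵀU₁Σ₁^{-1/2}),
   then truncation keeping the smallest dimension within budget.

Per-state **importance indices** ν_c = √diag𝒫, ν_o = √diag𝒬 (each
rescaled to max 1) and their product ν quantify each (lumped) state's role
in carrying the input signal to the output.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

The built-in stiff phosphorelay fixture (kinase A, response regulator Y,
phosphatase Z, slow adaptation enzyme B; 9 species, 4 conserved moieties;
ligand-modulated autophosphorylation input, total phosphorylated regulator
`Y_P + Y_P_Z` output):

```python
import numpy as np
import crnreduce as cr

network, iospec = cr.make_phosphorelay(stiff_ratio=1000.0)
config = cr.ReductionConfig(
    max_error=0.05, chi_c=250.0, seed=1,
    protocol=cr.Protocol(u=np.array([1.0]), t_end=8.0),  # step input
)
report = cr.run_combined_reduction(network, iospec, config)
print(report.summary())
```

prints

```
stage        dim   error        chi
conservation   5   0%         6216
lump           3   1.25%      9
```

Read: conservation analysis removed the four moiety totals exactly
(9 → 5 states, stiffness χ ≈ 6.2·10³); two forward-selection lumps brought
the model to 3 states at a maximal relative output error of 1.25% while
collapsing χ to 9 — below the critical χ_c = 250 at which balanced
truncation becomes numerically safe; truncation then found no smaller
model within the 5% budget, so the 3-state lumped model is returned. The
importance table (`report.indices.to_frame()`) shows the lumped variable
containing the phosphorylated kinase (`A_P+A_P_Y+B_P`) carries the
input–output signal (ν = 1).

From the shell, the same run on any SBML file:

```
crnreduce reduce --sbml model.xml --input k_in:additive-rate \
    --output "Y_P + Y_P_Z" --max-error 0.05 --chi-c 250 \
    --seed 1 --report out/
crnreduce indices  --sbml model.xml --input k_in:additive-rate --output "Y_P + Y_P_Z"
crnreduce validate --original model.xml --input k_in:additive-rate \
    --output "Y_P + Y_P_Z" --reduced out/reduced_model.json
```

Published case-study models fetched from a model repository (including
ones needing an added depletion reaction to be asymptotically stable) are
handled by `scripts/reduce_case_study.py`; see its docstring.

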