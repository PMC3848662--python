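# Methods

## Model and discretisation

The solver integrates the coupled Nernst–Planck/Poisson system on a bounded
two-dimensional cell domain Ω (an ellipse with semi-axes a, b) with membrane
∂Ω. Species fluxes combine Fickian diffusion and electrical drift; the
membrane is impermeable (zero total flux) and electrically grounded (φ = 0
on ∂Ω). Reaction kinetics enter as pointwise rate functions of the local
concentration vector.

The Slotboom change of variables Zᵢ = Cᵢ·pᵢ with pᵢ = exp((mᵢ/dᵢ)φ/V_T),
qᵢ = 1/pᵢ, rewrites each species equation as

    ∂(qᵢZᵢ)/∂t − div(dᵢ qᵢ ∇Zᵢ) = Fᵢ(q₁Z₁, …),

a weighted diffusion problem whose P1 Galerkin matrices are symmetric and,
for positive weights, positive definite. Per time step (implicit Euler,
uniform dt):

1. **Poisson step** (decoupled, lagged charge): solve
   ε·Q_{Y×Y} φ_Y = [Σᵢ zᵢ Mᵢ(φⁿ) ξᵢⁿ − β]_Y on the interior node set Y,
   with Q the Laplace stiffness matrix, Mᵢ the mass matrix weighted by the
   species' Slotboom factor at the old potential, and β the fixed-charge
   load. Dirichlet rows are eliminated (reduced system), not penalized, and
   the factorization of ε·Q_{Y×Y} is computed once per mesh and reused.
2. **Factor refresh**: qᵢ ← exp(−(mᵢ/dᵢ)φⁿ⁺¹/V_T), evaluated by
   interpolating nodal φ to quadrature points before exponentiation.
3. **Species solves**: (Aᵢⁿ⁺¹ + dt·Rᵢⁿ⁺¹)ξᵢⁿ⁺¹ = Aᵢⁿξᵢⁿ + dt·Sᵢⁿ⁺¹ with
   the weighted mass A and stiffness R carrying the new factors and the
   history term the old ones. Nonlinear rates are linearized by a Picard
   loop with a Gauss–Seidel sweep: each rate term's own-species factor is
   taken at the new iterate (assembled into the matrix as a nonnegative
   reaction mass matrix), factors of already-updated species at iterate
   k+1, the rest at k. The loop stops when the summed L2 increment over the
   looped species drops below eps.

Per model: the basic (Michaelis–Menten reduced) system solves the enzyme
first (it has no reaction term), iterates only the substrate with the
saturation denominator lagged, and solves the product last with the
converged substrate. The suicide-substrate and cooperative systems sweep
all species inside one loop, initialized from the previous time level.

Discrete total mass of a reaction-free species, 1ᵀAⁿξⁿ, is conserved
exactly by this scheme (the constant test function annihilates the
stiffness term), which the tests verify to 1e-10 relative.

## Units and parameters

Concentrations are in μM, time in s, lengths in the (dimensionless-looking)
domain units of the cell geometry, so diffusion coefficients are in domain
area per second. Potential is carried in mV; only the Slotboom exponents
divide by the thermal voltage V_T = 25.693 mV (configurable), which keeps
the exponents dimensionless (φ₀ = −80 mV ↦ −3.114). The Poisson step is
solved directly in the mV-scale simulation units with permittivity ε.

Assumptions the data do not fix (all configurable):

- **Mobilities** default to the Einstein relation mᵢ = zᵢdᵢ, i.e. the
  Slotboom exponent coefficient mᵢ/dᵢ equals the valence in thermal-voltage
  units.
- **Permittivity** ε defaults to 1.0 simulation units; the fixed-charge
  density f is used as a constant source of 0.1 units in the reference
  configurations.
- **Initial potential**: interior nodes at φ₀, membrane nodes at the
  grounded value 0 (φ₀ and the boundary condition conflict at t = 0; the
  membrane value wins on ∂Ω).
- **Cooperative rate constants**: only the pseudo-equilibrium constants
  K₁ = (k₋₁+k₂)/k₁ and K₂ = (k₄+k₋₃)/k₃ are prescribed (1000 and 0.001 for
  positive, 0.5 and 100 for negative cooperativity); the package fixes
  k₋₁ = k₂ = k₋₃ = k₄ = 1 s⁻¹ and derives k₁, k₃. Any direct set of six
  constants can be given instead.
- **Second-order rate constants** (suicide k₁; cooperative k₁, k₃) are
  interpreted per μM per second; constants annotated in M or M⁻¹s⁻¹ in a
  configuration are converted to the μM-based internal units on load.
- **Suicide reference horizon**: with k₁=2, k₋₁=4, k₂=12, k₃=10, k₄=2 and
  e₀ = s₀ = 0.5 μM the substrate falls below 1% of s₀ around t ≈ 8 s (the
  well-mixed limit of the same system, integrated independently with an
  adaptive ODE method, agrees); the bundled run therefore integrates to
  T = 12 s to reach the post-exhaustion plateau, while the time-step
  robustness study uses the shorter T = 4 s horizon.

## Numerical choices

- **Quadrature**: symmetric 3-point degree-2 rule (edge midpoints) by
  default — exact for products of P1 functions — with a 6-point degree-4
  rule available for the exponential weights. For the smooth, thermally
  scaled exponents of the reference runs the two rules agree to better than
  1e-3 relative.
- **Exponent clamp**: Slotboom exponents are clipped at ±50 before
  exponentiation (a global counter records clamp events). The reference
  runs stay far below the clamp (|exponent| ≲ 13).
- **Linear solves**: direct sparse LU per system; the matrices A + dt·R
  (+ dt·reaction mass) are symmetric positive definite for positive
  weights. The Poisson factorization is cached per mesh.
- **Picard control**: eps = 1e-4 (in L2-of-concentration units) for every
  preset — the tolerance is only prescribed for the basic model and is
  reused for the others — with an iteration cap of 50; on non-convergence
  the last iterate is accepted with a warning (configurable to raise).
  Reference runs converge in 2–5 iterations per step.
- **Mesh generation**: boundary nodes exactly on the ellipse at equal
  arc-length spacing ≈ 0.8·h_target, staggered concentric elliptical rings
  of interior points, scipy Delaunay triangulation (the domain is convex,
  so the triangulation conforms). Deterministic; h ≤ 1.25·h_target; the
  center (0,0) is always a node, anchoring the "center of the cell" probe
  (nearest node, ties to the lowest index).
- **Degenerate inputs**: non-conforming meshes (an edge in more than two
  triangles), non-positive triangle areas, empty interiors (no Poisson
  unknowns), negative initial concentrations, non-finite rates and invalid
  units are all rejected with specific errors.

## Study harness

The convergence error of a run is E_h = dt·Σᵢ Σₙ max_k ‖Zᵢⁿ'ᵏ⁺¹ − Zᵢⁿ'ᵏ‖_L2,
accumulated from the Picard increments; species solved outside a loop
contribute zero. The mesh ladder h = 0.3, 0.1, 0.05 ties the step to the
mesh via dt = h·T/16, refining space and time together. Study horizons are
T = 0.2 s (basic) and T = 1 s (suicide, cooperative) — desk-scale values
that still exercise the nonlinear dynamics; the printed mesh-refinement
tables of the source experiments depend on an unstated mesh generator,
quadrature and horizon, so the package asserts the strict monotone decrease
of E_h rather than point values. The time-step robustness study integrates
one model at dt, dt/2, dt/4 (each rounded to an exact divisor of T) on a
single mesh with h = 0.2 and reports pairwise relative L2 discrepancies of
the final product field; observed spatial order is the log–log least-squares
slope of error against h, verified at [1.8, 2.2] for the Poisson solve
against the manufactured solution φ = (1−r²)/4 on the unit disk.

## What the tests do and do not show

The reference configurations use spatially constant initial concentrations,
a constant fixed charge and an idealised elliptical cell, so passing tests
demonstrate correctness of the discretisation and the coupling algorithm —
agreement with closed-form element matrices, adaptive-quadrature oracles,
a scalar backward-Euler oracle in the well-mixed limit, exact conservation
identities and the expected convergence orders — not fidelity to any
particular measured cell geometry or heterogeneous charge distribution.

Known limitations:

- At coarse mesh/time resolution the basic reference run develops a thin
  charge-induced layer of the product species at the membrane (the
  accumulated product charge raises the interior potential to ≈ +300 mV,
  i.e. ≈ 12 thermal volts); where that layer is unresolved the consistent
  mass matrix produces transient local over- and undershoots, which decay
  as the field approaches its Boltzmann quasi-equilibrium (in Slotboom
  variables that equilibrium is spatially constant and is represented
  exactly). The reference-resolution runs (h = 0.1, dt = 1e-3) remain
  nonnegative throughout; negative excursions, when they occur on coarser
  studies, are logged.
- First-order accuracy in time (implicit Euler) and P1 accuracy in space;
  no upwinding/mass lumping, no adaptive time stepping, no Newton coupling,
  2D only, straight-edged boundary elements.
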