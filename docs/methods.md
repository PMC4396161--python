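# Methods

## Model

A single cardiac cell occupies the ellipse Ω with semi-axes a = 2, b = 1
(cell center at the origin).  Six species — enzyme E, substrate S,
intermediates X and Y, product P, inactivated enzyme Ei, in this fixed order
C1…C6 — carry charges z = (1, −1, 1, 1, 1, −1) and diffusivities
d = (1e-3, 2e-3, 5e-3, 1e-3, 2e-3, 4e-6).  Each concentration obeys a
Nernst–Planck conservation law: the flux combines Fickian diffusion and
electromigration with mobility m_i = d_i z_i · Fa/(R·Te) (Einstein
relation), and the reaction term F_i is the mass-action rate of the
suicide-substrate scheme E+S ⇌ X → Y, Y → E+P (k3) or Y → Ei (k4).
Species boundaries are no-flux (closed cell): total flux J_i·n = 0 on ∂Ω.

The membrane potential φ satisfies a cable-type equation
∂φ/∂t = D Δφ − (Fa/Cm) Σ z_i F_i + (1/Cm) I_stim(t) f(x) with
D = 1/(ρ·S·Cm), φ = φ_rest = 0 mV on ∂Ω (Dirichlet) and initial interior
value φ0 = −80 mV.  The point stimulus at the center is mollified as
f = exp(−1000(x² + y²)).  An optional linear leak −g_leak(φ − φ_rest)/Cm
(default g_leak = 0) exists for sensitivity studies only.

### Charge bookkeeping

With the stated valences the binding step E + S → X does not conserve
charge (+1 − 1 → +1).  The species table is implemented exactly as stated;
no correction is applied, and no electroneutrality constraint is imposed
(the potential equation is a cable/RC model, not a Poisson equation).

## Units

All PDE quantities live in a single "model unit" system: time in **seconds**,
potential in mV, concentrations in μM, lengths in the units of the ellipse.
Parameters quoted per second (rate constants, dt, T, stimulus onset and
duration) enter verbatim.  Two physical factors are not pinned down by the
available parameter set and default to **1 in model units**, exposed as
`PhysicalConstants.beta_drift` (the Fa/(R·Te) of the Einstein relation) and
`PhysicalConstants.faraday_model` (the Fa of the potential equation); both
are configurable, and the SI values of Fa and R are available for real-unit
mobility calculations via `einstein_mobility`.

`cable_diffusion` is the one genuine unit conversion: with Cm = 2.0 μF/cm²,
S = 0.2 μm⁻¹ and ρ = 162 Ω·cm it yields D = 0.00154 cm²/ms.  Because the
solver's time unit is the second, the PDE uses this coefficient re-expressed
per second (1.543 cm²/s).  Keeping the raw per-millisecond number against
seconds-based time would slow diffusion a thousand-fold and turn the AP into
a sustained plateau; the seconds-based reading produces the triangular,
repolarizing AP the model is meant to exhibit.  The nominal d_i (quoted in
m²/s) are likewise taken as model-unit numbers; they are physically enormous
for ions but are part of the stated parameter set.

## Discretization

* **Mesh.** Deterministic built-in mesher: points on concentric elliptical
  rings (outermost exactly on ∂Ω) spaced ≈ h radially and circumferentially,
  staggered ring-to-ring, Delaunay-triangulated (the point cloud is convex,
  so all simplices are interior).  Achieved h = max element diameter is
  reported everywhere; targets h ∈ {0.2, 0.15, 0.1} land within 1.5·h.
  Meshes at different h are independent (non-nested).  Gmsh MSH v2.2 ASCII
  read/write with physical tags 1 (boundary lines) and 2 (interior
  triangles); no curved elements.
* **Space.** P1 Lagrange elements.  Mass and stiffness use exact closed-form
  element integrals; the consistent mass matrix is the default (row-sum
  lumping available for experiments).  The drift operator
  A(φ)_ij = m_i ∫ ψ_j ∇φ_h·∇ψ_i is exact for P1 (∇φ_h elementwise
  constant); its columns sum to zero, which is what makes discrete species
  mass conservation exact under no-flux boundaries.  Integration by parts is
  oriented so the no-flux condition generates no boundary term.  The
  Gaussian stimulus load uses a 7-point degree-5 Gauss rule per element,
  with optional uniform element subdivision when the source (width
  1/√1000 ≈ 0.03) must be integrated accurately on coarse meshes; at the
  production h the load is a controlled mollification of the Dirac, not a
  spectrally accurate integral.
* **Time.** One step advances (1) the potential by Heun's explicit RK2
  (the common two-stage second-order Runge–Kutta) with C frozen at C^n and a
  Gershgorin CFL estimate that warns (not aborts) if dt looks explicit-
  unstable; then (2) the six concentrations by backward-Euler Galerkin
  transport using φ^{n+1}, with the reaction lagged and fixed-point (Picard)
  iterated to relative tolerance 1e-10, cap 50 (2–6 iterations in practice
  at dt = 1e-5).  The φ↔C coupling is not re-iterated within a step.  A full
  6n×6n block-Newton variant using the analytic reaction Jacobian is
  available (`scheme="newton"`); it matches Picard to ~1e-14 and exists as a
  robustness cross-check.  Linear systems use direct sparse LU; the
  factorizations are rebuilt each step because the drift operator depends on
  φ^{n+1}.

## Verification choices

* **Error norm.** L2-in-space at final time, √(eᵀMe), with the max over
  saved time levels also reported.  Any tabulated absolute error in an
  unspecified norm is not comparable to these numbers; only convergence
  *rates* are asserted.
* **MMS.** u = e^{−t} sin x cos y with a compensating source; Dirichlet data
  from the exact trace; dt = dt0·(h/h0)² so the O(dt) backward-Euler error
  tracks the O(h²) spatial error; dt0 = 2e-3 at h0 = 0.2 with T = 0.1.
  A drift-on variant (prescribed φ = x·y) checks the electromigration
  assembly at the same order.  Observed fitted order ≈ 1.9 on the three
  production levels.  Note the two-point order formula applied to the
  tabulated error pair (19e-5 at h = 0.2, 95e-6 at h = 0.1) gives 1.0, which
  sits in tension with second-order spatial accuracy; with the error-norm
  definition and dt-refinement rule unavailable, both readings are recorded
  and neither absolute value is reproduced.
* **Stability.** The full stimulated scenario on one h = 0.15 mesh at
  dt ∈ {1e-5, 5e-6, 2.5e-6}; pairwise max-norm differences of the final
  fields (φ: ~2e-5 mV on an 80 mV field; C: first-order halving with dt).
* **Electrophysiological validation.** The stimulus response of a run is its
  center-probe trace minus the no-stimulus trace; the two runs are
  bit-identical before onset, so this isolates the AP from the slow
  relaxation of the −80 mV initial condition toward the grounded membrane
  (diffusion length √(4DT) ≈ 0.3 ≪ b at T = 6 ms, so the relaxation is a
  boundary layer, but on coarse meshes its numerical tail reaches the
  center).  An AP is "detected" when the peak response reaches half that of
  the reference −200 μA/cm² run — the model's response is only weakly
  nonlinear, so all-or-none holds relative to this detector, with the
  bisection threshold landing near half the reference amplitude.
  Excitability uses the pre-onset window with tolerance 5% of the AP
  response.  Morphology: AP duration is the span where |response| exceeds
  half its peak; plateau fraction is the part of that span within 5% of the
  peak ("exhausted"/"inactivated" endpoints for the kinetics are
  operationalized as s < 1e-3·s0, available enzyme e+x+y < 1e-3·e0 at
  T∞ = 50/k4, since no numeric criterion is stated anywhere).

## Conserved quantities

The rates satisfy two algebraic identities at any state: the enzyme moiety
e + x + y + ei and the substrate moiety s + x + y + p + ei are constant
(Ei counts in both — it is an enzyme–inhibitor complex whose inhibitor is
substrate-derived).  Because transport conserves each species integral
exactly (no-flux, zero column sums of K and A), both moiety *integrals* are
conserved by the full scheme to solver precision at every step, stimulus or
not.  This is the main structural invariant the tests lean on.

## Problem sizes and defaults

Production runs use h = 0.15 (≈ 500 nodes, 900 triangles), dt = 1e-5 s,
T = 0.006 s (600 steps); convergence studies use the three tabulated levels;
the stability study adds dt/2 and dt/4 (1800 extra steps); validation runs
~10 full simulations for the bisection.  These sizes resolve every asserted
behavior; all studies scale to finer meshes through their parameters.

## What the defaults do and do not show

The default configuration is the published parameter set, and the test suite
exercises the model only there and at nearby scales.  Passing tests show
correct assembly, conservation, convergence order and the three validation
behaviors for this configuration; they do not calibrate the two model-unit
factors against laboratory units, do not cover anisotropic resistivity,
3D domains, cell-volume changes, or drift-dominated regimes that would need
stabilized (SUPG/upwind) transport, and pixel-level reproduction of any
published figure is out of scope.
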