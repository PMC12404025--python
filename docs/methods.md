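# Methods

## Model

The response stage solves the RPA eigenproblem `Ω F = ω² F` over the
occupied×virtual pair space of a converged restricted Kohn–Sham reference.
For pure (LDA-type) functionals the super-matrices are

    A = (ε_a − ε_i) δ + B,
    B = 2 ⟨ai‖k̄⟩ O_k̄l̄ ⟨l̄‖bj⟩,
    O = G⁻¹ + G⁻¹ ⟨m̄| f_xc[ρ̃] |n̄⟩ G⁻¹,

where `k̄, l̄` index primitive Hermite Gaussian auxiliary functions, `G` is
their Coulomb metric, and the kernel is evaluated at the *fitted* density
ρ̃ = Σ x_k̄ k̄(r) (never at the orbital density — that is the defining ADFT
choice, kept even though the host SCF integrates its own XC term from the
orbital density; the difference feeds only the kernel, not the orbitals).

Hybrid functionals add exact-exchange blocks `−c_F (ab‖ij)` and
`−c_F (aj‖bi)` that destroy the index alignment between ERIs and excitation
vectors.  The hybrid diagonal approximation keeps only the diagonal
`(aa‖ii)` part of the first block, and drops the second entirely, giving

    (A−B) ≈ (ε_a − ε_i − Δ_ai) δ,
    (A+B) ≈ (ε_a − ε_i − Δ_ai) δ + 4 ⟨ai‖k̄⟩ O^GH ⟨l̄‖bj⟩,
    Δ_ai  = c_F [ α M_a G⁻¹ M_iᵀ + β M̄_a Ḡ⁻¹ M̄_iᵀ ],

with `M_p = ⟨pp‖k̄⟩` the diagonal-MO-pair three-center matrix, computed by
contracting per-MO product densities inside the integral loop (no stored
AO→MO transformation).  The barred quantities use the long-range
`erf(ωr)/r` operator; (α, β, ω) are the CAM coefficients, `c_F` the global
mixing.  Global hybrids are (α, β) = (1, 0); inverse (HSE-type) range
separation is β < 0, which yields the short-range `erfc` exchange in the
complete-fitting limit of the same formula.  The semilocal exchange kernel
carries the complementary fraction: the global-hybrid O matrix uses
`f_xc − c_F f_x`, the range-separated one `f_x^SR + f_c`, both realized by
one attenuated-exchange bracket `[1 − α_eff − β_eff g(a)]` with
`α_eff = c_F α`, `β_eff = c_F β`, `a = ω/(2 k_F)`; its ω→0 / ω→∞ limits
reduce to `(1 − α_eff)` and `(1 − α_eff − β_eff)` times the Dirac form and
are verified in the tests.

The Tamm–Dancoff mode diagonalizes `A ≈ (ε_a−ε_i−Δ_ai)δ + 2⟨ai‖k̄⟩O⟨l̄‖bj⟩`
(diagonal shift retained, singlet coupling factor 2).  The triplet channel
drops the Hartree `G⁻¹` term and replaces the kernel by the spin-flip
second derivative `∂²E_xc/∂m²` (equal to the singlet kernel for any
spin-scaling exchange functional; VWN5 spin stiffness for correlation,
evaluated by Richardson-extrapolated central differences in the
magnetization).  Triplet oscillator strengths are reported as zero
(spin-forbidden from a closed-shell singlet ground state).

Oscillator strengths use the length gauge,
`d_I = Σ_ai μ_ai √(2(ε_a−ε_i−Δ_ai)/ω_I) F_ai`, `f_I = (2/3) ω_I |d_I|²`;
the average dynamic polarizability is the sum-over-states form whose poles
sit exactly at the computed excitation energies.

## Integrals

All integrals use the McMurchie–Davidson scheme: Hermite expansion
coefficients for orbital products, the R-tensor recursion seeded by Boys
function values for Coulomb interactions, and the `(−1)^|k̄|` phase for the
two-center Hermite expansion against auxiliary functions.  The
erf-attenuated operator only rescales the reduced exponent
(α → αω²/(α+ω²), prefactor √(α̃/α)), so plain, long-range and CAM operators
share one code path; a CAM kernel is the linear combination of the two.
The Boys function uses an exp(−T)-scaled ascending series at the top order
plus downward recursion for T ≤ 35, and the asymptotic value plus upward
recursion above (absolute accuracy ~1e-14 to order 32).  Four-center ERIs
exist only for the SCF exchange of hybrids and the exact-exchange oracle;
they are guarded at N_bas ≤ 120.  No far-field multipole pathway is
implemented (such expansions are a speed optimization only); the
near-field recurrence is exact at all distances.

## SCF host

Restricted Kohn–Sham with RI-J fitted Coulomb (variational Coulomb-metric
fit, `x = G⁻¹J`), grid-integrated semilocal XC from the orbital density,
and conventional four-center Fock exchange with operator
`c_F(α + β erf(ωr))/r`.  Exact four-center exchange in the SCF isolates the
HDA as the only fitted-exchange approximation in the pipeline; orbital
energies therefore differ slightly from codes that also fit the SCF
exchange.  Convergence: DIIS (depth 8) on the `FPS−SPF` commutator, energy
tol 1e-8 Ha, density RMS 1e-6, core-Hamiltonian guess, hard error on a
degenerate HOMO at Aufbau filling.

## Numerical choices

* **Grid.**  Becke fuzzy-cell partition (3 step-function iterations, no
  size adjustment); Gauss–Chebyshev radial points under the rational Becke
  mapping; a product Gauss–Legendre(cosθ) × uniform(φ) angular grid
  (default 75 × 18 × 36 per atom) instead of a table-based angular scheme —
  exact to comparable spherical-harmonic degree with no stored
  coefficients.  The angular axes come from a deterministic molecule-fixed
  frame (first two independent bond vectors), so the grid co-rotates with
  the molecule and all grid-based quantities are rotationally covariant to
  floating-point precision; for linear molecules the undetermined azimuth
  is harmless because the density is axially symmetric.
* **Kernel screening.**  The LDA kernel diverges as ρ^(−2/3); grid points
  where the fitted density falls below 1e-7 (where the fit carries no
  information and small negative excursions are clamped at the 1e-14 floor)
  contribute zero to the kernel matrices.  Without the screen the clamped
  tail dominates the integrals.
* **Metric solves.**  All metric solves are Jacobi-preconditioned
  (unit-diagonal scaling — pure numerics, same solution).  The plain metric
  must be positive definite: Cholesky failure raises a linear-dependence
  error naming the offending functions.  The erf-attenuated metric is
  exponentially rank-deficient for compact auxiliary functions (the
  long-range operator resolves only their charges), so attenuated solves
  use a truncated eigendecomposition with a 1e-12 relative cutoff.
  `G⁻¹` is symmetrized exactly after the solve.
* **Davidson.**  Deterministic unit-vector guesses on the smallest
  diagonal elements (ties broken by pair index), diagonal preconditioner,
  two-pass Gram–Schmidt, collapse restart at 12·n_roots subspace vectors,
  residual tol 1e-6 (tests that compare against dense diagonalization
  tighten it to 1e-10).
* **Derivatives.**  Dirac exchange potential/kernel and the VWN5 potential
  are analytic; the VWN5 kernel, the short-range-exchange kernel and
  potential use Richardson-extrapolated central differences with relative
  steps 1e-4–1e-5 (validated against analytic limits and quadrature in the
  tests).  The attenuation bracket switches to a Taylor expansion in
  1/(2a) for a > 10 where the closed form cancels catastrophically.
* **Instabilities.**  The RPA factorization requires
  `ε_a − ε_i − Δ_ai > 0`; violations raise an instability error listing
  the offending pairs, as does a negative Ω eigenvalue.

## Fixtures and what the tests show

The fixture generator emits H2, HeH+, LiH, H2O (STO-3G for all; 6-31G for
H and O) and idealized staggered linear alkanes C_nH_{2n+2}, each with
even-tempered s + spd Hermite auxiliary sets chosen to span the orbital
product-density exponents while keeping the scaled metric condition number
near 1e8 (denser sets become numerically linearly dependent).  These are
explicit shipped sets, not automatically generated production auxiliary
sets, and the semilocal host is LDA/VWN5 rather than a GGA: the named
functional presets (pbe0, b3lyp, cam-b3lyp, lc-lda, hse06) carry only the
published *mixing* parameters of those functionals.  Consequently the test
suite validates the machinery — integral identities against independent
quadrature oracles, reduction identities, the diagonal-restriction
definition of the HDA, eigensolver agreement, invariances — and the
qualitative physics of toy systems; it does not reproduce benchmark
excitation statistics of production GGA-hybrid calculations on real test
sets, which require large orbital/auxiliary bases this package is not
sized for.

One documented divergence from the large-system regime: on these
few-electron fixtures the HDA deviates *more* from the four-center oracle
for singlets than for triplets.  The dominant toy-system error is the
dropped diagonal `(ai‖ia)` exchange and its first-order interference with
the strong singlet Hartree+kernel coupling, while the nearly-diagonal toy
triplet problem is approximated well; the opposite (triplet-worse)
behaviour of extended systems arises from dense triplet manifolds near
triplet instability, a regime these fixtures cannot reach.  The cost-proxy
scaling check (log–log slope of N_occ·N_virt·N_aux vs N_bas below 3 across
alkanes n = 2–8) demonstrates the structural index-alignment property, not
wall-clock performance.

Problem sizes used throughout (toy molecules, ≤ 13 AOs, ≤ 80 auxiliary
functions, full dense reference solvers) are the package's intended desk
scale; the matrix-free operator is the piece that carries over to large
systems.
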