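# tdadft

Density-fitted TD-DFT linear response with the **hybrid diagonal
approximation (HDA)** — vertical singlet/triplet excitation energies,
oscillator strengths and dynamic polarizabilities of closed-shell molecules
for pure, global-hybrid and range-separated-hybrid functionals.

## The problem

Auxiliary density functional theory (ADFT) expands the electron density in
primitive Hermite Gaussian auxiliary functions; its linear-response variant
(TD-ADFT) solves the Casida/RPA eigenproblem

```
Ω F = ω² F,
Ω_ai,bj = (ε_a − ε_i)² δ_ab δ_ij + 4 √(ε_a−ε_i) ⟨ai‖k̄⟩ O_k̄l̄ ⟨l̄‖bj⟩ √(ε_b−ε_j)
```

entirely through *three-center* ERIs ⟨ai‖k̄⟩ and the auxiliary-space
coupling matrix `O = G⁻¹ + G⁻¹⟨f_xc[ρ̃]⟩G⁻¹`.  Because the ERI indices stay
aligned with the excitation-vector indices, Ω is applied matrix-free at
O(N_occ·N_virt·N_aux) cost — but this structure breaks down for hybrid
functionals, whose exact-exchange response couples all four MO indices.

The HDA restores the pure-functional structure by keeping only the
*diagonal* exact-exchange elements, folded into orbital-energy shifts

```
Δ_ai = c_F [ α · M_a G⁻¹ M_iᵀ + β · M̄_a Ḡ⁻¹ M̄_iᵀ ],   M_p,k̄ = ⟨pp‖k̄⟩,
```

with (α, β, ω) the CAM range-separation parameters (barred quantities use
the long-range `erf(ωr)/r` operator).  The eigenproblem then reads exactly
like the pure case with `ε_a − ε_i → ε_a − ε_i − Δ_ai`, so the matrix-free
solver, the Davidson diagonalizer, and the sub-cubic cost per apply all
survive unchanged.  Δ is assembled once, outside the eigensolver, from the
diagonal-MO-pair matrix **M** computed inside the integral loop — no stored
AO→MO transformation.

The package implements the full stack from scratch: Gaussian94 basis
parsing, McMurchie–Davidson integrals (plain and erf-attenuated operators),
restricted Kohn–Sham SCF with RI-J Coulomb fitting, Becke-partitioned
quadrature grids, the LDA/VWN5 kernel and its attenuated short-range
variant, the HDA response stage, and a dense four-center reference solver
used as the exact-exchange oracle the HDA is measured against.

## Worked example

```bash
cat > water.yaml <<EOF
fixture: h2o
functional: pbe0
n_roots: 5
eigensolver: dense
EOF
tdadft run water.yaml
```

prints (STO-3G orbital basis, LDA semilocal host with PBE0 mixing c_F = 0.25):

```
root  spin     omega_ev     f           dominant  weight
1     singlet  11.88900454  0.00250577  5->6      0.99999973
2     singlet  14.11598308  0.00000000  5->7      0.99999973
3     singlet  14.51645218  0.05817205  4->6      0.96099534
4     singlet  17.71294401  0.04491901  4->7      0.82399650
5     singlet  21.77069595  0.90341312  3->6      0.82290335
```

`omega_ev` are the HDA excitation energies; `f` the length-gauge oscillator
strengths (root 2 is dipole-forbidden); `dominant` the leading
occupied→virtual pair.  The mean HDA shift on this system is ≈ 4.4 eV —
the Fock-exchange diagonal raises excitations far above the pure-LDA
spectrum, as hybrid functionals must.  Other subcommands: `tdadft scf`
(checkpoint), `excite` (from checkpoint), `fixtures`, `spectrum`.

From Python:

```python
from tdadft import make_functional
from tdadft.fixtures import generate_fixture
from tdadft.scf import run_scf
from tdadft.response import ResponseEngine

fx = generate_fixture("h2o")
res, env = run_scf(fx.molecule, fx.ao_basis(), fx.aux_basis(), make_functional("pbe0"))
engine = ResponseEngine(res, env)
print(engine.excitations(n_roots=5).omega_ev)
```

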