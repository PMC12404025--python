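"""Restricted Kohn-Sham SCF with density-fitted Coulomb term.

The host SCF is conventional restricted Kohn-Sham: the Coulomb term is
density fitted (RI-J with the Coulomb metric), the XC term is integrated on
the molecular grid from the orbital density, and Fock exchange (for
hybrids) uses conventional four-center ERIs with the operator
c_F (alpha + beta erf(omega r))/r.  Exact four-center exchange keeps the
response stage's hybrid diagonal approximation as the only fitted-exchange
approximation in the pipeline.

Convergence: DIIS on the FPS-SPF commutator, energy tol 1e-8 Ha, density
RMS tol 1e-6, core-Hamiltonian initial guess (deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from . import lda
from .basis import AuxiliaryFunction, BasisFunction
from .functionals import FunctionalSpec
from .grid import MolecularGrid, ao_values, build_grid
from .integrals import (
    CoulombMetric,
    CoulombOperator,
    OneElectron,
    ThreeCenterERIs,
    coulomb_metric,
    four_center,
    one_electron,
    three_center,
)
from .molecule import Molecule


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFOptions:
    energy_tol: float = 1e-8
    density_tol: float = 1e-6
    diis_depth: int = 8
    max_iterations: int = 200
    grid_level: str = "default"


@dataclass
class SCFResult:
    mo_coeff: np.ndarray  # (nbas, nmo)
    mo_energy: np.ndarray  # hartree, non-decreasing
    n_occ: int
    energy: float
    fit_coefficients: np.ndarray  # x_k of the converged fitted density
    density: np.ndarray  # AO density matrix P
    functional: FunctionalSpec
    converged: bool
    n_iterations: int
    history: list[float] = field(default_factory=list)

    @property
    def n_mo(self) -> int:
        return self.mo_coeff.shape[1]

    @property
    def n_virt(self) -> int:
        return self.n_mo - self.n_occ

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("mo_coeff", data=self.mo_coeff)
            fh.create_dataset("mo_energy", data=self.mo_energy)
            fh.create_dataset("fit_coefficients", data=self.fit_coefficients)
            fh.create_dataset("density", data=self.density)
            fh.attrs["n_occ"] = self.n_occ
            fh.attrs["energy"] = self.energy
            fh.attrs["converged"] = self.converged
            fh.attrs["n_iterations"] = self.n_iterations
            for key in ("name", "c_F", "cam_alpha", "cam_beta", "rs_omega", "inverse"):
                fh.attrs[f"functional_{key}"] = getattr(
                    self.functional, key if key != "name" else "name"
                )

    @classmethod
    def load(cls, path) -> "SCFResult":
        import h5py

        with h5py.File(path, "r") as fh:
            func = FunctionalSpec(
                name=str(fh.attrs["functional_name"]),
                c_F=float(fh.attrs["functional_c_F"]),
                cam_alpha=float(fh.attrs["functional_cam_alpha"]),
                cam_beta=float(fh.attrs["functional_cam_beta"]),
                rs_omega=float(fh.attrs["functional_rs_omega"]),
                inverse=bool(fh.attrs["functional_inverse"]),
            )
            return cls(
                mo_coeff=fh["mo_coeff"][...],
                mo_energy=fh["mo_energy"][...],
                n_occ=int(fh.attrs["n_occ"]),
                energy=float(fh.attrs["energy"]),
                fit_coefficients=fh["fit_coefficients"][...],
                density=fh["density"][...],
                functional=func,
                converged=bool(fh.attrs["converged"]),
                n_iterations=int(fh.attrs["n_iterations"]),
            )


def fit_density(P: np.ndarray, t3: ThreeCenterERIs | np.ndarray, metric: CoulombMetric) -> np.ndarray:
    """Variational Coulomb-metric density fit: x = G^-1 J, J_k = sum P <mn||k>."""
    tensor = t3.tensor if isinstance(t3, ThreeCenterERIs) else t3
    J = np.einsum("mn,mnk->k", P, tensor)
    return metric.solve(J)


def _semilocal_xc(rho, functional: FunctionalSpec):
    """(energy density, potential) of the semilocal part on the grid."""
    a, b, w = functional.sr_alpha, functional.sr_beta, functional.rs_omega
    ex = lda.sr_exchange_energy_density(rho, a, b, w)
    if b == 0.0:
        vx = (1.0 - a) * lda.dirac_potential(rho)
    else:
        rho_c = np.maximum(rho, lda.RHO_FLOOR)
        h = 1e-5 * rho_c

        def e(r):
            return lda.sr_exchange_energy_density(r, a, b, w)

        d1 = (e(rho_c + h) - e(rho_c - h)) / (2.0 * h)
        d2 = (e(rho_c + 0.5 * h) - e(rho_c - 0.5 * h)) / h
        vx = (4.0 * d2 - d1) / 3.0
    if functional.correlation == "vwn5":
        ec = lda.vwn5_energy_density(rho)
        vc = lda.vwn5_potential(rho)
    else:
        ec = np.zeros_like(ex)
        vc = np.zeros_like(ex)
    return ex + ec, vx + vc


@dataclass
class SCFEnvironment:
    """Precomputed integrals shared by SCF and the response stage."""

    molecule: Molecule
    basis: list[BasisFunction]
    aux: list[AuxiliaryFunction]
    one_e: OneElectron
    metric: CoulombMetric
    t3: ThreeCenterERIs
    grid: MolecularGrid
    ao_grid: np.ndarray
    eri_plain: np.ndarray | None = None
    eri_erf: np.ndarray | None = None
    metric_erf: CoulombMetric | None = None
    t3_erf: ThreeCenterERIs | None = None


def build_environment(
    molecule: Molecule,
    basis: list[BasisFunction],
    aux: list[AuxiliaryFunction],
    functional: FunctionalSpec,
    grid_level: str = "default",
    need_four_center: bool | None = None,
) -> SCFEnvironment:
    one_e = one_electron(molecule, basis)
    metric = coulomb_metric(molecule, aux)
    t3 = three_center(molecule, basis, aux)
    grid = build_grid(molecule, grid_level)
    aog = ao_values(basis, grid.points)
    env = SCFEnvironment(molecule, basis, aux, one_e, metric, t3, grid, aog)
    if need_four_center is None:
        need_four_center = functional.is_hybrid
    if need_four_center:
        env.eri_plain = four_center(basis)
    if functional.fock_erf_weight != 0.0:
        erf_op = functional.erf_operator()
        env.eri_erf = four_center(basis, erf_op)
    if functional.is_range_separated:
        erf_op = functional.erf_operator()
        env.metric_erf = coulomb_metric(molecule, aux, erf_op)
        env.t3_erf = three_center(molecule, basis, aux, erf_op)
    return env


def run_scf(
    molecule: Molecule,
    basis: list[BasisFunction],
    aux: list[AuxiliaryFunction],
    functional: FunctionalSpec,
    options: SCFOptions | None = None,
    environment: SCFEnvironment | None = None,
) -> tuple[SCFResult, SCFEnvironment]:
    """Converge the restricted Kohn-Sham problem; returns (result, environment)."""
    options = options or SCFOptions()
    if molecule.n_electrons % 2 != 0:
        raise ValueError("odd electron count: unrestricted SCF unsupported")
    n_occ = molecule.n_electrons // 2
    env = environment or build_environment(
        molecule, basis, aux, functional, options.grid_level
    )
    S, T, V = env.one_e.overlap, env.one_e.kinetic, env.one_e.nuclear
    H = T + V
    nb = len(basis)
    if n_occ > nb:
        raise ValueError("more occupied orbitals than basis functions")
    w = env.grid.weights
    aog = env.ao_grid
    wp = functional.fock_plain_weight
    we = functional.fock_erf_weight
    if wp != 0.0 and env.eri_plain is None:
        raise ValueError("hybrid SCF needs four-center ERIs in the environment")

    e_nuc = molecule.nuclear_repulsion()

    def fock_and_energy(P):
        J_aux = np.einsum("mn,mnk->k", P, env.t3.tensor)
        x = env.metric.solve(J_aux)
        Jmat = np.einsum("k,mnk->mn", x, env.t3.tensor)
        e_coul = float(x @ J_aux) - 0.5 * float(x @ (env.metric.matrix @ x))
        rho = np.einsum("mn,mp,np->p", P, aog, aog, optimize=True)
        rho = np.maximum(rho, 0.0)
        e_dens, v_xc = _semilocal_xc(rho, functional)
        Vxc = (aog * (w * v_xc)[None, :]) @ aog.T
        Vxc = 0.5 * (Vxc + Vxc.T)
        e_xc = float(w @ e_dens)
        F = H + Jmat + Vxc
        e_exch = 0.0
        if wp != 0.0:
            K = np.einsum("rs,prqs->pq", P, env.eri_plain)
            F -= 0.5 * wp * K
            e_exch -= 0.25 * wp * float(np.sum(P * K))
        if we != 0.0:
            Ke = np.einsum("rs,prqs->pq", P, env.eri_erf)
            F -= 0.5 * we * Ke
            e_exch -= 0.25 * we * float(np.sum(P * Ke))
        energy = float(np.sum(P * H)) + e_coul + e_xc + e_exch + e_nuc
        return F, energy, x

    # deterministic core-Hamiltonian guess
    eps, C = sla.eigh(H, S)
    P = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T

    diis_F: list[np.ndarray] = []
    diis_E: list[np.ndarray] = []
    history: list[float] = []
    e_old = np.inf
    P_old = P
    converged = False
    x = np.zeros(len(aux))
    for it in range(1, options.max_iterations + 1):
        F, energy, x = fock_and_energy(P)
        err = F @ P @ S - S @ P @ F
        diis_F.append(F)
        diis_E.append(err)
        if len(diis_F) > options.diis_depth:
            diis_F.pop(0)
            diis_E.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.sum(diis_E[i] * diis_E[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:m]
                F = sum(c * f for c, f in zip(coef, diis_F))
            except np.linalg.LinAlgError:
                pass
        eps, C = sla.eigh(F, S)
        if n_occ < nb and abs(eps[n_occ] - eps[n_occ - 1]) < 1e-8:
            raise RuntimeError(
                "degenerate HOMO at Aufbau filling; fractional occupation unsupported"
            )
        P = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        history.append(energy)
        d_rms = float(np.sqrt(np.mean((P - P_old) ** 2)))
        de = abs(energy - e_old)
        if de < options.energy_tol and d_rms < options.density_tol:
            converged = True
            break
        e_old, P_old = energy, P

    if not converged:
        raise SCFConvergenceError(
            f"SCF not converged after {options.max_iterations} iterations: "
            f"dE={de:.3e}, dP_rms={d_rms:.3e}"
        )
    # final consistent quantities at the converged density
    F, energy, x = fock_and_energy(P)
    eps, C = sla.eigh(F, S)
    P = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    x = fit_density(P, env.t3, env.metric)
    result = SCFResult(
        mo_coeff=C,
        mo_energy=eps,
        n_occ=n_occ,
        energy=energy,
        fit_coefficients=x,
        density=P,
        functional=functional,
        converged=True,
        n_iterations=it,
        history=history,
    )
    return result, env
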