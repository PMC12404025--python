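"""Linear-response stage: HDA shifts, matrix-free Omega operator, Davidson
eigensolver, oscillator strengths, dynamic polarizability, and the dense
full-hybrid reference used as the exact-exchange oracle.

Conventions
-----------
Occupied orbitals i,j; virtual a,b.  Transition pairs are flattened as
(i, a) -> i * n_virt + a.  Excitation energies are stored in hartree; the
``omega_ev`` property converts with 1 Ha = 27.211386245988 eV.

The RPA eigenproblem solved is  Omega F = omega^2 F  with

    Omega_ai,bj = (de_ai)^2 delta + 4 sqrt(de_ai) <ai||k> O_kl <l||bj> sqrt(de_bj)

where de_ai = eps_a - eps_i - Delta_ai and Delta is the hybrid diagonal
approximation (HDA) shift

    Delta_ai = c_F [ alpha M_a G^-1 M_i^T + beta Mbar_a Gbar^-1 Mbar_i^T ]

built from the diagonal-MO-pair three-center matrix M_p = <pp||kbar>
(plain operator) and its erf-attenuated counterpart.  Delta is computed
once, outside the eigensolver.  Setting c_F = 0 recovers the pure
TD-ADFT operator exactly.

The Tamm-Dancoff mode diagonalizes A = diag(de) + 2 <ai||k> O <l||bj>
(the HDA diagonal shift retained, singlet coupling factor 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .basis import AuxiliaryFunction, BasisFunction
from .constants import HARTREE_EV
from .functionals import FunctionalSpec
from .integrals import CoulombMetric, CoulombOperator, PLAIN, three_center
from .molecule import Molecule
from .scf import SCFEnvironment, SCFResult
from .xc import OMatrix, response_kernel_matrices


class InstabilityError(RuntimeError):
    """Non-positive response diagonal (ground-state / triplet instability)."""


class DavidsonError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# M matrix and HDA shifts


@dataclass
class MMatrix:
    """M_p,kbar = <pp || kbar> for every canonical MO p."""

    matrix: np.ndarray  # (n_mo, naux)
    operator: CoulombOperator


def m_matrix(
    scf: SCFResult,
    molecule: Molecule,
    basis: list[BasisFunction],
    aux: list[AuxiliaryFunction],
    operator: CoulombOperator = PLAIN,
) -> MMatrix:
    """Diagonal-MO-pair three-center integrals via the in-loop pathway.

    The per-MO product densities Q^p_{mu nu} = c_{mu p} c_{nu p} are
    contracted inside the integral loop, so no AO three-center tensor is
    transformed or stored.  Equals the naive double transformation
    C^T <mu nu||k> C exactly (same arithmetic, different order).
    """
    C = scf.mo_coeff
    q = np.einsum("mp,np->pmn", C, C)
    mat = three_center(molecule, basis, aux, operator, mo_products=q)
    return MMatrix(mat, operator)


@dataclass
class HDAShift:
    """Delta_ia (hartree) over occupied x virtual pairs."""

    delta: np.ndarray  # (n_occ, n_virt)
    variant: str  # "gh" | "rs"
    c_F: float

    @property
    def flat(self) -> np.ndarray:
        return self.delta.reshape(-1)


def hda_shift(
    m: MMatrix,
    metric: CoulombMetric,
    functional: FunctionalSpec,
    n_occ: int,
    variant: str | None = None,
    m_erf: MMatrix | None = None,
    metric_erf: CoulombMetric | None = None,
) -> HDAShift:
    """HDA super-vector elements Delta_ai = c_F sum_kl M_ak G^-1_kl M_il.

    Range-separated variant adds the beta-weighted erf-operator term with
    its own (attenuated) metric.  Identically zero when c_F = 0.
    """
    if variant is None:
        variant = "rs" if functional.is_range_separated else "gh"
    n_mo = m.matrix.shape[0]
    n_virt = n_mo - n_occ
    if functional.c_F == 0.0:
        return HDAShift(np.zeros((n_occ, n_virt)), variant, 0.0)
    occ = m.matrix[:n_occ]
    virt = m.matrix[n_occ:]
    delta = functional.cam_alpha * (occ @ metric.solve(virt.T))
    if variant == "rs" and functional.cam_beta != 0.0:
        if m_erf is None or metric_erf is None:
            raise ValueError("range-separated HDA shift needs attenuated M and metric")
        occ_e = m_erf.matrix[:n_occ]
        virt_e = m_erf.matrix[n_occ:]
        delta = delta + functional.cam_beta * (occ_e @ metric_erf.solve(virt_e.T))
    return HDAShift(functional.c_F * delta, variant, functional.c_F)


# ---------------------------------------------------------------------------
# MO three-center tensor


def mo_three_center(scf: SCFResult, t3_tensor: np.ndarray) -> np.ndarray:
    """<ai||k> tensor, shape (n_occ, n_virt, naux)."""
    C = scf.mo_coeff
    occ = C[:, : scf.n_occ]
    virt = C[:, scf.n_occ :]
    return np.einsum("mnk,mi,na->iak", t3_tensor, occ, virt, optimize=True)


def mo_three_center_full(scf: SCFResult, t3_tensor: np.ndarray) -> np.ndarray:
    """<pq||k> for all MO pairs (used by the fitted-exchange oracle path)."""
    C = scf.mo_coeff
    return np.einsum("mnk,mp,nq->pqk", t3_tensor, C, C, optimize=True)


# ---------------------------------------------------------------------------
# Omega operator


class OmegaOperator:
    """Matrix-free RPA Omega (or TDA A) apply for one spin channel.

    Cost per apply is O(n_occ n_virt n_aux): one contraction of the trial
    vector into auxiliary space, one small O multiply, one back
    contraction.  The dense matrix is never formed unless explicitly
    requested for oracle comparisons.
    """

    def __init__(
        self,
        eps_occ: np.ndarray,
        eps_virt: np.ndarray,
        shift: HDAShift,
        t_ia: np.ndarray,  # (n_occ, n_virt, naux)
        o_matrix: OMatrix,
        mode: str = "rpa",
        coupling_factor: float | None = None,
    ) -> None:
        self.n_occ, self.n_virt, self.n_aux = t_ia.shape
        self.mode = mode
        de = eps_virt[None, :] - eps_occ[:, None] - shift.delta
        self.de = de.reshape(-1)
        if mode == "rpa" and np.any(self.de <= 0.0):
            bad = np.argwhere(de <= 0.0)
            pairs = [(int(i), int(a + self.n_occ)) for i, a in bad[:8]]
            raise InstabilityError(
                f"non-positive shifted orbital-energy differences for pairs {pairs}; "
                "the RPA factorization requires eps_a - eps_i - Delta_ai > 0"
            )
        self.t = t_ia.reshape(self.n_occ * self.n_virt, self.n_aux)
        self.o = o_matrix.matrix
        self.spin = o_matrix.spin
        if coupling_factor is None:
            coupling_factor = 4.0 if mode == "rpa" else 2.0
        self.coupling = coupling_factor
        self.sq = np.sqrt(np.abs(self.de))

    @property
    def dim(self) -> int:
        return self.n_occ * self.n_virt

    def apply(self, vec: np.ndarray) -> np.ndarray:
        v = np.asarray(vec)
        if self.mode == "rpa":
            u = self.t.T @ (self.sq * v)
            w = self.o @ u
            return self.de ** 2 * v + self.coupling * self.sq * (self.t @ w)
        u = self.t.T @ v
        w = self.o @ u
        return self.de * v + self.coupling * (self.t @ w)

    def diagonal(self) -> np.ndarray:
        k_diag = np.einsum("pk,kl,pl->p", self.t, self.o, self.t, optimize=True)
        if self.mode == "rpa":
            return self.de ** 2 + self.coupling * self.de * k_diag
        return self.de + self.coupling * k_diag

    def dense(self) -> np.ndarray:
        coup = self.coupling * np.einsum(
            "pk,kl,ql->pq", self.t, self.o, self.t, optimize=True
        )
        if self.mode == "rpa":
            m = np.diag(self.de ** 2) + self.sq[:, None] * coup * self.sq[None, :]
        else:
            m = np.diag(self.de) + coup
        return 0.5 * (m + m.T)


# ---------------------------------------------------------------------------
# Davidson


def davidson(
    operator: OmegaOperator,
    n_roots: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_subspace: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lowest eigenpairs of a symmetric operator by block Davidson.

    Deterministic start: unit vectors on the n_roots smallest diagonal
    elements (ties broken by pair index).  Diagonal preconditioner;
    collapse restart when the subspace exceeds ``max_subspace``
    (default 12 * n_roots, capped at the full dimension).
    """
    dim = operator.dim
    if n_roots > dim:
        raise ValueError(f"{n_roots} roots requested in dimension {dim}")
    if max_subspace is None:
        max_subspace = min(dim, max(12 * n_roots, n_roots + 8))
    diag = operator.diagonal()
    order = np.argsort(diag, kind="stable")
    V = np.zeros((dim, n_roots))
    for c, idx in enumerate(order[:n_roots]):
        V[idx, c] = 1.0

    def orthonormalize(block: np.ndarray) -> np.ndarray:
        """Two-pass modified Gram-Schmidt QR, dropping rank-deficient columns."""
        cols = []
        for c in range(block.shape[1]):
            v = block[:, c].copy()
            for _ in range(2):
                for q in cols:
                    v -= (q @ v) * q
            nrm = np.linalg.norm(v)
            if nrm > 1e-10:
                cols.append(v / nrm)
        return np.column_stack(cols)

    for _ in range(max_iter):
        Q = orthonormalize(V)
        AQ = np.column_stack([operator.apply(Q[:, c]) for c in range(Q.shape[1])])
        H = Q.T @ AQ
        H = 0.5 * (H + H.T)
        theta, s = np.linalg.eigh(H)
        theta, s = theta[:n_roots], s[:, :n_roots]
        ritz = Q @ s
        res = AQ @ s - ritz * theta[None, :]
        rnorm = np.linalg.norm(res, axis=0)
        if np.all(rnorm < tol) or Q.shape[1] == dim:
            return theta, ritz
        base = ritz if Q.shape[1] >= max_subspace else Q
        new_dirs = []
        for k in range(n_roots):
            if rnorm[k] < tol:
                continue
            denom = diag - theta[k]
            denom = np.where(np.abs(denom) < 1e-8, np.sign(denom + 1e-300) * 1e-8, denom)
            for cand in (res[:, k] / denom, res[:, k]):
                d = cand.copy()
                for _ in range(2):
                    d -= base @ (base.T @ d)
                    for nd in new_dirs:
                        d -= (nd @ d) * nd
                nrm = np.linalg.norm(d)
                if nrm > 1e-8 * np.linalg.norm(cand):
                    new_dirs.append(d / nrm)
                    break
        if not new_dirs:
            if np.all(rnorm < 100 * tol):
                return theta, ritz
            raise DavidsonError(f"Davidson stagnated; residual norms {rnorm}")
        V = np.column_stack([base] + new_dirs)
    raise DavidsonError(
        f"Davidson not converged after {max_iter} iterations; residuals {rnorm}"
    )


# ---------------------------------------------------------------------------
# Excitation results


@dataclass
class ExcitationResult:
    omega: np.ndarray  # hartree, ascending
    vectors: np.ndarray  # (n_pairs, n_roots) F eigenvectors (RPA) or X (TDA)
    xpy: np.ndarray  # (X+Y) amplitudes, same shape
    oscillator_strengths: np.ndarray
    transition_dipoles: np.ndarray  # (3, n_roots)
    spin: str
    mode: str
    approximation: str
    n_occ: int
    n_virt: int
    de: np.ndarray  # shifted orbital-energy differences (flattened)

    @property
    def omega_ev(self) -> np.ndarray:
        return self.omega * HARTREE_EV

    def dominant_pair(self, root: int) -> tuple[int, int, float]:
        """(i, a, weight) of the largest amplitude for one root."""
        v = self.vectors[:, root]
        idx = int(np.argmax(np.abs(v)))
        i, a = divmod(idx, self.n_virt)
        return i, a + self.n_occ, float(v[idx] ** 2 / (v @ v))


def _transition_dipoles(
    mu_ia: np.ndarray, vectors: np.ndarray, de: np.ndarray, omega: np.ndarray, mode: str
) -> np.ndarray:
    """Length-gauge transition dipoles from the eigenvectors.

    RPA:  d_I = sum_ai mu_ai sqrt(2 de_ai / omega_I) F_ai
    TDA:  d_I = sum_ai mu_ai sqrt(2) X_ai
    """
    n_roots = vectors.shape[1]
    d = np.zeros((3, n_roots))
    for r in range(n_roots):
        if mode == "rpa":
            w = np.sqrt(2.0 * de / max(omega[r], 1e-30))
        else:
            w = np.full_like(de, np.sqrt(2.0))
        d[:, r] = mu_ia @ (w * vectors[:, r])
    return d


def oscillator_strengths(
    omega: np.ndarray, transition_dipoles: np.ndarray
) -> np.ndarray:
    """f_I = (2/3) omega_I |d_I|^2 (length gauge)."""
    if np.any(omega <= 0):
        raise InstabilityError("non-positive excitation energy in oscillator strengths")
    return (2.0 / 3.0) * omega * np.sum(transition_dipoles ** 2, axis=0)


def solve_excitations(
    operator: OmegaOperator,
    mu_ia: np.ndarray,  # (3, n_pairs) MO transition dipole integrals
    n_roots: int,
    method: str = "davidson",
    approximation: str = "hda",
    tol: float = 1e-6,
) -> ExcitationResult:
    """Solve the response eigenproblem for the lowest ``n_roots`` states."""
    n_roots = min(n_roots, operator.dim)
    if method == "dense":
        evals, evecs = np.linalg.eigh(operator.dense())
        evals, evecs = evals[:n_roots], evecs[:, :n_roots]
    elif method == "davidson":
        evals, evecs = davidson(operator, n_roots, tol=tol)
    else:
        raise ValueError(f"unknown eigensolver method {method!r}")
    if operator.mode == "rpa":
        if np.any(evals <= 0):
            raise InstabilityError(
                f"negative Omega eigenvalue(s) {evals[evals <= 0]}: response instability"
            )
        omega = np.sqrt(evals)
    else:
        if np.any(evals <= 0):
            raise InstabilityError(
                f"negative TDA excitation energies {evals[evals <= 0]}"
            )
        omega = evals
    # deterministic sign convention: largest amplitude positive
    for r in range(evecs.shape[1]):
        idx = np.argmax(np.abs(evecs[:, r]))
        if evecs[idx, r] < 0:
            evecs[:, r] = -evecs[:, r]
    dip = _transition_dipoles(mu_ia, evecs, operator.de, omega, operator.mode)
    if operator.spin == "triplet":
        dip = np.zeros_like(dip)  # spin-forbidden from the closed-shell ground state
    f = oscillator_strengths(omega, dip)
    if operator.mode == "rpa":
        xpy = np.sqrt(operator.de)[:, None] * evecs / np.sqrt(omega)[None, :]
    else:
        xpy = evecs.copy()
    return ExcitationResult(
        omega=omega,
        vectors=evecs,
        xpy=xpy,
        oscillator_strengths=f,
        transition_dipoles=dip,
        spin=operator.spin if operator.spin else "singlet",
        mode=operator.mode,
        approximation=approximation,
        n_occ=operator.n_occ,
        n_virt=operator.n_virt,
        de=operator.de.copy(),
    )


# ---------------------------------------------------------------------------
# Dynamic polarizability (sum over states)


def dynamic_polarizability(
    result: ExcitationResult, omega_grid, pole_guard: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Average dynamic polarizability abar(w) = (axx + ayy + azz)/3 from the
    sum-over-states form; grid points within ``pole_guard`` of a pole are
    skipped with a warning.  Needs the (near-)full spectrum to be faithful.
    """
    omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    d2 = np.sum(result.transition_dipoles ** 2, axis=0)  # |d_I|^2
    keep = np.ones(len(omega_grid), dtype=bool)
    for wI in result.omega:
        near = np.abs(np.abs(omega_grid) - wI) < pole_guard
        if np.any(near):
            warnings.warn(
                f"polarizability grid point(s) within {pole_guard} of pole at {wI:.8f} skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            keep &= ~near
    w = omega_grid[keep]
    denom = result.omega[None, :] ** 2 - w[:, None] ** 2
    alpha = (2.0 / 3.0) * np.sum(result.omega[None, :] * d2[None, :] / denom, axis=1)
    return w, alpha


# ---------------------------------------------------------------------------
# Dense full-hybrid reference (exact-exchange oracle)


def _mo_eri(eri_ao: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.einsum(
        "mnst,mp,nq,sr,tu->pqru", eri_ao, C, C, C, C, optimize=True
    )


@dataclass
class FullHybridMatrices:
    A: np.ndarray
    B: np.ndarray
    n_occ: int
    n_virt: int


def full_hybrid_matrices(
    scf: SCFResult,
    t_ia: np.ndarray,
    o_matrix: OMatrix,
    functional: FunctionalSpec,
    eri_ao: np.ndarray | None = None,
    eri_ao_erf: np.ndarray | None = None,
    exchange: str = "exact",
    t3_full_plain: np.ndarray | None = None,
    t3_full_erf: np.ndarray | None = None,
    metric: CoulombMetric | None = None,
    metric_erf: CoulombMetric | None = None,
    restriction: str | None = None,
) -> FullHybridMatrices:
    """Assemble the dense (A, B) super-matrices of the full hybrid response.

    ``exchange="exact"``: Fock-exchange blocks from four-center MO ERIs
    (the oracle the HDA is measured against).
    ``exchange="fitted"``: exchange blocks density-fitted like the HDA,
    so that ``restriction="hda-diagonal"`` reproduces the HDA bitwise.
    ``restriction="hda-diagonal"``: keep only the diagonal (aa||ii)
    exchange of the first exchange term and drop the second, i.e. the
    structural definition of the HDA.
    """
    n_occ, n_virt, _ = t_ia.shape
    nov = n_occ * n_virt
    eps = scf.mo_energy
    de0 = eps[n_occ:][None, :] - eps[:n_occ][None, :].T  # (n_occ, n_virt)
    t = t_ia.reshape(nov, -1)
    coup = 2.0 * np.einsum("pk,kl,ql->pq", t, o_matrix.matrix, t, optimize=True)
    A = np.diag(de0.reshape(-1)) + coup
    B = coup.copy()

    wp = functional.fock_plain_weight
    we = functional.fock_erf_weight
    if wp != 0.0 or we != 0.0:
        ex_abij = np.zeros((n_occ, n_virt, n_occ, n_virt))
        ex_ajbi = np.zeros_like(ex_abij)
        occ_sl = slice(0, n_occ)
        virt_sl = slice(n_occ, None)

        def add_exchange(weight, eri_ao_op, t3_full, metric_op):
            nonlocal ex_abij, ex_ajbi
            if weight == 0.0:
                return
            if exchange == "exact":
                if eri_ao_op is None:
                    raise ValueError("exact exchange oracle needs AO four-center ERIs")
                mo = _mo_eri(eri_ao_op, scf.mo_coeff)
                # (ab|ij) -> i,a,j,b ; (aj|bi) -> i,a,j,b
                ex_abij += weight * np.einsum("abij->iajb", mo[virt_sl, virt_sl, occ_sl, occ_sl])
                ex_ajbi += weight * np.einsum("ajbi->iajb", mo[virt_sl, occ_sl, virt_sl, occ_sl])
            elif exchange == "fitted":
                if t3_full is None or metric_op is None:
                    raise ValueError("fitted exchange needs full MO 3c tensor and metric")
                ginv_t_oo = metric_op.solve(
                    t3_full[occ_sl, occ_sl].reshape(n_occ * n_occ, -1).T
                )  # (naux, n_occ^2)
                ab = t3_full[virt_sl, virt_sl].reshape(n_virt * n_virt, -1)
                abij = (ab @ ginv_t_oo).reshape(n_virt, n_virt, n_occ, n_occ)
                ex_abij += weight * np.einsum("abij->iajb", abij)
                aj = t3_full[virt_sl, occ_sl].reshape(n_virt * n_occ, -1)
                ginv_t_vo = metric_op.solve(t3_full[virt_sl, occ_sl].reshape(n_virt * n_occ, -1).T)
                ajbi = (aj @ ginv_t_vo).reshape(n_virt, n_occ, n_virt, n_occ)
                ex_ajbi += weight * np.einsum("ajbi->iajb", ajbi)
            else:
                raise ValueError(f"unknown exchange path {exchange!r}")

        add_exchange(wp, eri_ao, t3_full_plain, metric)
        add_exchange(we, eri_ao_erf, t3_full_erf, metric_erf)

        ex_abij = ex_abij.reshape(nov, nov)
        ex_ajbi = ex_ajbi.reshape(nov, nov)
        if restriction == "hda-diagonal":
            ex_abij = np.diag(np.diag(ex_abij))
            ex_ajbi = np.zeros_like(ex_ajbi)
        elif restriction is not None:
            raise ValueError(f"unknown restriction {restriction!r}")
        A -= ex_abij
        B -= ex_ajbi
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)
    return FullHybridMatrices(A, B, n_occ, n_virt)


def solve_full_hybrid(
    matrices: FullHybridMatrices,
    mu_ia: np.ndarray,
    n_roots: int,
    mode: str = "rpa",
    spin: str = "singlet",
    approximation: str = "oracle",
) -> ExcitationResult:
    """Solve the dense RPA problem via (A-B)^1/2 (A+B) (A-B)^1/2, or TDA."""
    A, B = matrices.A, matrices.B
    nov = A.shape[0]
    n_roots = min(n_roots, nov)
    if mode == "tda":
        evals, evecs = np.linalg.eigh(A)
        if np.any(evals[:n_roots] <= 0):
            raise InstabilityError("negative TDA excitation energy in reference solver")
        omega = evals[:n_roots]
        vecs = evecs[:, :n_roots]
        de = np.diag(A)  # effective diagonal (only used for dipole weights in RPA)
        dip = _transition_dipoles(mu_ia, vecs, de, omega, "tda")
        if spin == "triplet":
            dip = np.zeros_like(dip)
        f = oscillator_strengths(omega, dip)
        return ExcitationResult(
            omega, vecs, vecs.copy(), f, dip, spin, "tda", approximation,
            matrices.n_occ, matrices.n_virt, de,
        )
    amb = A - B
    evals_amb, v = np.linalg.eigh(amb)
    if np.any(evals_amb <= 0):
        raise InstabilityError(
            f"(A - B) not positive definite (min eigenvalue {evals_amb.min():.3e})"
        )
    half = v @ np.diag(np.sqrt(evals_amb)) @ v.T
    omega2, F = np.linalg.eigh(half @ (A + B) @ half)
    omega2, F = omega2[:n_roots], F[:, :n_roots]
    if np.any(omega2 <= 0):
        raise InstabilityError("negative omega^2 in reference RPA solver")
    omega = np.sqrt(omega2)
    for r in range(F.shape[1]):
        idx = np.argmax(np.abs(F[:, r]))
        if F[idx, r] < 0:
            F[:, r] = -F[:, r]
    # (X+Y) = (A-B)^{1/2} F / sqrt(omega); transition dipole d = mu . (X+Y) sqrt(2)
    xpy = half @ F / np.sqrt(omega)[None, :]
    dip = np.sqrt(2.0) * (mu_ia @ xpy)
    if spin == "triplet":
        dip = np.zeros_like(dip)
    f = oscillator_strengths(omega, dip)
    return ExcitationResult(
        omega, F, xpy, f, dip, spin, "rpa", approximation,
        matrices.n_occ, matrices.n_virt, np.diag(amb),
    )


# ---------------------------------------------------------------------------
# High-level engine


class ResponseEngine:
    """Bundles the response-stage quantities for one converged SCF."""

    def __init__(
        self,
        scf: SCFResult,
        env: SCFEnvironment,
        functional: FunctionalSpec | None = None,
    ) -> None:
        self.scf = scf
        self.env = env
        self.functional = functional or scf.functional
        self.molecule = env.molecule
        self.n_occ = scf.n_occ
        self.n_virt = scf.n_virt

        self.o_matrices = response_kernel_matrices(
            env.molecule, env.aux, env.grid, env.metric, self.functional,
            scf.fit_coefficients,
        )
        self.t_ia = mo_three_center(scf, env.t3.tensor)
        self._m = None
        self._m_erf = None
        self._shift = None
        mu_ao = env.one_e.dipole
        occ = scf.mo_coeff[:, : self.n_occ]
        virt = scf.mo_coeff[:, self.n_occ :]
        mu = np.einsum("xmn,mi,na->xia", mu_ao, occ, virt, optimize=True)
        self.mu_ia = mu.reshape(3, -1)

    @property
    def m(self) -> MMatrix:
        if self._m is None:
            self._m = m_matrix(self.scf, self.env.molecule, self.env.basis, self.env.aux)
        return self._m

    @property
    def m_erf(self) -> MMatrix | None:
        if self._m_erf is None and self.functional.is_range_separated:
            self._m_erf = m_matrix(
                self.scf, self.env.molecule, self.env.basis, self.env.aux,
                self.functional.erf_operator(),
            )
        return self._m_erf

    @property
    def shift(self) -> HDAShift:
        if self._shift is None:
            self._shift = hda_shift(
                self.m, self.env.metric, self.functional, self.n_occ,
                m_erf=self.m_erf, metric_erf=self.env.metric_erf,
            )
        return self._shift

    def operator(
        self, spin: str = "singlet", mode: str = "rpa", approximation: str = "hda"
    ) -> OmegaOperator:
        o = self.o_matrices[spin]
        eps = self.scf.mo_energy
        if approximation == "pure":
            shift = HDAShift(np.zeros((self.n_occ, self.n_virt)), "gh", 0.0)
        elif approximation == "hda":
            shift = self.shift
        else:
            raise ValueError(f"unknown approximation {approximation!r} for the operator")
        return OmegaOperator(
            eps[: self.n_occ], eps[self.n_occ :], shift, self.t_ia, o, mode=mode
        )

    def excitations(
        self,
        n_roots: int = 10,
        spin: str = "singlet",
        mode: str = "rpa",
        method: str = "davidson",
        approximation: str = "hda",
        tol: float = 1e-6,
    ) -> ExcitationResult:
        if approximation == "oracle":
            return self.reference_full_hybrid(n_roots, spin=spin, mode=mode)
        op = self.operator(spin, mode, approximation)
        return solve_excitations(
            op, self.mu_ia, n_roots, method=method, approximation=approximation, tol=tol
        )

    def reference_full_hybrid(
        self,
        n_roots: int = 10,
        spin: str = "singlet",
        mode: str = "rpa",
        exchange: str = "exact",
        restriction: str | None = None,
    ) -> ExcitationResult:
        """Dense full hybrid response; the exact-exchange oracle for the HDA."""
        env = self.env
        t3_full = t3_full_erf = None
        if exchange == "fitted":
            t3_full = mo_three_center_full(self.scf, env.t3.tensor)
            if self.functional.fock_erf_weight != 0.0:
                t3_full_erf = mo_three_center_full(self.scf, env.t3_erf.tensor)
        mats = full_hybrid_matrices(
            self.scf,
            self.t_ia,
            self.o_matrices[spin],
            self.functional,
            eri_ao=env.eri_plain,
            eri_ao_erf=env.eri_erf,
            exchange=exchange,
            t3_full_plain=t3_full,
            t3_full_erf=t3_full_erf,
            metric=env.metric,
            metric_erf=env.metric_erf,
            restriction=restriction,
        )
        return solve_full_hybrid(
            mats, self.mu_ia, n_roots, mode=mode, spin=spin,
            approximation="oracle" if restriction is None else "hda-restricted",
        )
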