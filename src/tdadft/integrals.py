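"""Molecular integrals over contracted Cartesian Gaussians and primitive
Hermite Gaussian auxiliary functions.

Everything is built on the McMurchie-Davidson scheme: an orbital product is
expanded in Hermite Gaussians through the E coefficients, and Coulomb
interactions between Hermite distributions are generated by the R-tensor
recursion seeded with Boys function values,

    [sbar]^(n) = 2 pi^(5/2) / (zeta_p zeta_c sqrt(zeta_p + zeta_c))
                 * (-2 alpha)^n * kappa_AB * F_n(T),
    T = alpha (P - C)^2,   alpha = zeta_p zeta_c / (zeta_p + zeta_c).

The interaction of an orbital-pair Hermite distribution with a Hermite
auxiliary function of index kbar carries the (-1)^|kbar| phase of the
two-center Hermite expansion; contraction over primitives happens after the
recursion.

Supported two-electron operators: plain 1/r, the long-range erf(w r)/r, and
any linear combination (alpha + beta erf(w r))/r (CAM form).  The erf
attenuation only rescales the reduced exponent, alpha -> alpha w^2 /
(alpha + w^2), plus a sqrt(alpha~/alpha) prefactor, so all recurrences are
shared between operators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .basis import AuxiliaryFunction, BasisFunction
from .boys import boys_array
from .molecule import Molecule

TWO_PI_POW = 2.0 * math.pi ** 2.5


class CapabilityError(RuntimeError):
    """Requested computation beyond the supported problem-size guard."""


class LinearDependenceError(RuntimeError):
    """Auxiliary set numerically linearly dependent under the Coulomb metric."""


@dataclass(frozen=True)
class CoulombOperator:
    """Two-electron kernel (alpha + beta * erf(omega r)) / r."""

    alpha: float = 1.0
    beta: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.beta != 0.0 and self.omega <= 0.0:
            raise ValueError("erf-attenuated operator needs omega > 0")

    @classmethod
    def plain(cls) -> "CoulombOperator":
        return cls(1.0, 0.0, 0.0)

    @classmethod
    def erf(cls, omega: float) -> "CoulombOperator":
        return cls(0.0, 1.0, omega)

    @property
    def tag(self) -> str:
        if self.beta == 0.0:
            return f"plain*{self.alpha:g}" if self.alpha != 1.0 else "plain"
        return f"cam(alpha={self.alpha:g},beta={self.beta:g},omega={self.omega:g})"


PLAIN = CoulombOperator.plain()


# ---------------------------------------------------------------------------
# Hermite machinery


def hermite_expansion(la: int, lb: int, ab: float, za: float, zb: float) -> np.ndarray:
    """1D McMurchie-Davidson E coefficients.

    Returns E[i, j, t] such that x_A^i x_B^j exp(-za x_A^2) exp(-zb x_B^2)
    = sum_t E[i,j,t] Lambda_t(x; p, P) with x_A = x - A etc. and ab = A - B.
    E[0,0,0] carries the 1D geometry factor exp(-mu ab^2).
    """
    p = za + zb
    mu = za * zb / p
    pa = -zb * ab / p  # P - A
    pb = za * ab / p  # P - B
    inv2p = 0.5 / p
    E = np.zeros((la + 1, lb + 1, la + lb + 2))
    E[0, 0, 0] = math.exp(-mu * ab * ab)
    for i in range(la):
        for t in range(i + 2):
            E[i + 1, 0, t] = (
                (inv2p * E[i, 0, t - 1] if t > 0 else 0.0)
                + pa * E[i, 0, t]
                + (t + 1) * E[i, 0, t + 1]
            )
    for j in range(lb):
        for i in range(la + 1):
            for t in range(i + j + 2):
                E[i, j + 1, t] = (
                    (inv2p * E[i, j, t - 1] if t > 0 else 0.0)
                    + pb * E[i, j, t]
                    + (t + 1) * E[i, j, t + 1]
                )
    return E


def r_tensor(tmax: tuple[int, int, int], alpha, rpc) -> np.ndarray:
    """Hermite Coulomb integrals R^0_{tuv}(alpha, R_PC), batched.

    alpha: scalar or (N,); rpc: (3,) or (N, 3).
    Returns array of shape (tx+1, ty+1, tz+1, N).
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    rpc = np.atleast_2d(np.asarray(rpc, dtype=float))
    if alpha.shape[0] == 1 and rpc.shape[0] > 1:
        alpha = np.broadcast_to(alpha, (rpc.shape[0],)).copy()
    tx, ty, tz = tmax
    ntot = tx + ty + tz
    T = alpha * np.einsum("ij,ij->i", rpc, rpc)
    F = boys_array(ntot, T)  # (ntot+1, N)
    powers = (-2.0 * alpha)[None, :] ** np.arange(ntot + 1)[:, None]
    base = powers * F

    cache: dict[tuple[int, int, int, int], np.ndarray] = {}

    def R(t: int, u: int, v: int, n: int) -> np.ndarray:
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (t, u, v, n)
        hit = cache.get(key)
        if hit is not None:
            return hit
        if t == u == v == 0:
            val = base[n]
        elif t > 0:
            val = (t - 1) * R(t - 2, u, v, n + 1) + rpc[:, 0] * R(t - 1, u, v, n + 1)
        elif u > 0:
            val = (u - 1) * R(t, u - 2, v, n + 1) + rpc[:, 1] * R(t, u - 1, v, n + 1)
        else:
            val = (v - 1) * R(t, u, v - 2, n + 1) + rpc[:, 2] * R(t, u, v - 1, n + 1)
        cache[key] = val
        return val

    out = np.empty((tx + 1, ty + 1, tz + 1, alpha.shape[0]))
    for t in range(tx + 1):
        for u in range(ty + 1):
            for v in range(tz + 1):
                out[t, u, v] = R(t, u, v, 0)
    return out


def coulomb_r_tensor(
    tmax: tuple[int, int, int], alpha, rpc, operator: CoulombOperator
) -> np.ndarray:
    """Operator-weighted R tensor: alpha_cam * R(alpha) + beta_cam *
    sqrt(alpha~/alpha) * R(alpha~) with alpha~ the erf-attenuated exponent."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    out = None
    if operator.alpha != 0.0:
        out = operator.alpha * r_tensor(tmax, alpha, rpc)
    if operator.beta != 0.0:
        w2 = operator.omega ** 2
        att = alpha * w2 / (alpha + w2)
        scale = np.sqrt(att / alpha)
        part = operator.beta * scale[None, None, None, :] * r_tensor(tmax, att, rpc)
        out = part if out is None else out + part
    if out is None:
        raise ValueError("null Coulomb operator")
    return out


def hermite_value(zeta: float, kbar: tuple[int, int, int], center, points) -> np.ndarray:
    """Values of the Hermite Gaussian Lambda_kbar(r; zeta, C) on a point batch."""
    pts = np.atleast_2d(points)
    d = pts - np.asarray(center)[None, :]
    out = np.exp(-zeta * np.einsum("ij,ij->i", d, d))
    sq = math.sqrt(zeta)
    for dim in range(3):
        k = kbar[dim]
        if k == 0:
            continue
        t = sq * d[:, dim]
        h_prev, h = np.ones_like(t), 2.0 * t
        for n in range(1, k):
            h_prev, h = h, 2.0 * t * h - 2.0 * n * h_prev
        out *= (sq ** k) * (h if k >= 1 else h_prev)
    return out


# ---------------------------------------------------------------------------
# One-electron integrals


@dataclass
class OneElectron:
    overlap: np.ndarray
    kinetic: np.ndarray
    nuclear: np.ndarray
    dipole: np.ndarray  # (3, nbas, nbas), origin at `origin`
    origin: np.ndarray


def one_electron(molecule: Molecule, basis: list[BasisFunction], origin=None) -> OneElectron:
    nb = len(basis)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    S = np.zeros((nb, nb))
    Tm = np.zeros((nb, nb))
    V = np.zeros((nb, nb))
    D = np.zeros((3, nb, nb))
    charges = np.array([a.atomic_number for a in molecule.atoms], dtype=float)
    centers = molecule.coordinates

    for i in range(nb):
        bi = basis[i]
        for j in range(i + 1):
            bj = basis[j]
            ab = bi.origin - bj.origin
            s = t = 0.0
            d3 = np.zeros(3)
            v = 0.0
            for za, ca in zip(bi.exponents, bi.coefficients):
                for zb, cb in zip(bj.exponents, bj.coefficients):
                    c = ca * cb
                    p = za + zb
                    P = (za * bi.origin + zb * bj.origin) / p
                    sqp = math.sqrt(math.pi / p)
                    # per-dimension E tables (extra order for kinetic l+2)
                    Es = [
                        hermite_expansion(bi.lmn[d], bj.lmn[d] + 2, ab[d], za, zb)
                        for d in range(3)
                    ]
                    s1 = [Es[d][bi.lmn[d], bj.lmn[d], 0] * sqp for d in range(3)]
                    s += c * s1[0] * s1[1] * s1[2]
                    # kinetic: -1/2 d^2/dx^2 acting on ket
                    k1 = []
                    for d in range(3):
                        lb = bj.lmn[d]
                        term = 4.0 * zb * zb * Es[d][bi.lmn[d], lb + 2, 0]
                        term -= 2.0 * zb * (2 * lb + 1) * Es[d][bi.lmn[d], lb, 0]
                        if lb >= 2:
                            term += lb * (lb - 1) * Es[d][bi.lmn[d], lb - 2, 0]
                        k1.append(-0.5 * term * sqp)
                    t += c * (
                        k1[0] * s1[1] * s1[2] + s1[0] * k1[1] * s1[2] + s1[0] * s1[1] * k1[2]
                    )
                    # dipole (length gauge, origin shift included)
                    m1 = [
                        (Es[d][bi.lmn[d], bj.lmn[d], 1] + (P[d] - origin[d]) * Es[d][bi.lmn[d], bj.lmn[d], 0])
                        * sqp
                        for d in range(3)
                    ]
                    d3[0] += c * m1[0] * s1[1] * s1[2]
                    d3[1] += c * s1[0] * m1[1] * s1[2]
                    d3[2] += c * s1[0] * s1[1] * m1[2]
                    # nuclear attraction
                    lmx = bi.lmn[0] + bj.lmn[0]
                    lmy = bi.lmn[1] + bj.lmn[1]
                    lmz = bi.lmn[2] + bj.lmn[2]
                    R = r_tensor((lmx, lmy, lmz), p, P[None, :] - centers)
                    Ex = Es[0][bi.lmn[0], bj.lmn[0], : lmx + 1]
                    Ey = Es[1][bi.lmn[1], bj.lmn[1], : lmy + 1]
                    Ez = Es[2][bi.lmn[2], bj.lmn[2], : lmz + 1]
                    herm = np.einsum("t,u,v,tuvn->n", Ex, Ey, Ez, R)
                    v += -c * (2.0 * math.pi / p) * float(charges @ herm)
            S[i, j] = S[j, i] = s
            Tm[i, j] = Tm[j, i] = t
            V[i, j] = V[j, i] = v
            D[:, i, j] = D[:, j, i] = d3
    return OneElectron(S, Tm, V, D, origin)


# ---------------------------------------------------------------------------
# Auxiliary-function bookkeeping


@dataclass
class AuxSite:
    """All Hermite functions sharing one (center, exponent)."""

    position: np.ndarray
    zeta: float
    members: list[tuple[int, tuple[int, int, int]]]  # (global index, kbar)


def aux_sites(molecule: Molecule, aux: list[AuxiliaryFunction]) -> list[AuxSite]:
    coords = molecule.coordinates
    sites: dict[tuple[int, float], AuxSite] = {}
    for idx, f in enumerate(aux):
        key = (f.center, f.exponent)
        if key not in sites:
            sites[key] = AuxSite(coords[f.center], f.exponent, [])
        sites[key].members.append((idx, f.index))
    return list(sites.values())


@dataclass
class CoulombMetric:
    matrix: np.ndarray
    operator: CoulombOperator
    condition_number: float = field(default=float("nan"))

    def _scaled(self) -> tuple[np.ndarray, np.ndarray]:
        """Diagonal (Jacobi) preconditioning: solve in the unit-diagonal metric.

        Pure numerics - the returned solutions are those of the raw metric.
        """
        d = np.diag(self.matrix)
        if np.any(d <= 0):
            raise LinearDependenceError(
                "Coulomb metric has non-positive diagonal entries "
                f"(functions {np.where(d <= 0)[0].tolist()})"
            )
        s = 1.0 / np.sqrt(d)
        return self.matrix * np.outer(s, s), s

    def cholesky(self) -> np.ndarray:
        """Cholesky factor of the *scaled* metric (diagnostic / PD check)."""
        import scipy.linalg as sla

        gs, _ = self._scaled()
        try:
            return sla.cholesky(gs, lower=True)
        except sla.LinAlgError as exc:
            evals, evecs = np.linalg.eigh(gs)
            bad = np.argsort(evals)[:3]
            offenders = [int(np.argmax(np.abs(evecs[:, b]))) for b in bad]
            raise LinearDependenceError(
                f"Coulomb metric not positive definite; smallest normalized "
                f"eigenvalues {evals[:3]}, dominant functions {offenders}"
            ) from exc

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """G x = rhs.

        Plain metric: Cholesky (positive definiteness is a hard contract;
        failure raises a linear-dependence error naming the offenders).
        Attenuated metric (beta != 0): the erf operator suppresses all
        short-range structure, so compact auxiliary functions become
        numerically indistinguishable and the metric is exponentially
        rank-deficient by construction.  The solve is then restricted to
        the numerically resolved range via a truncated eigendecomposition
        (relative cutoff 1e-12 on the scaled metric).
        """
        import scipy.linalg as sla

        gs, s = self._scaled()
        scaled_rhs = rhs * s if rhs.ndim == 1 else rhs * s[:, None]
        if self.operator.beta != 0.0:
            evals, evecs = np.linalg.eigh(gs)
            cut = 1e-12 * evals[-1]
            inv = np.where(evals > cut, 1.0 / np.maximum(evals, cut), 0.0)
            sol = evecs @ (inv[:, None] * (evecs.T @ np.atleast_2d(scaled_rhs.T).T))
            sol = sol[:, 0] if rhs.ndim == 1 else sol
        else:
            try:
                c = sla.cho_factor(gs, lower=True)
            except sla.LinAlgError:
                self.cholesky()  # raises with diagnostics
                raise
            sol = sla.cho_solve(c, scaled_rhs)
        return sol * s if rhs.ndim == 1 else sol * s[:, None]

    def inverse(self) -> np.ndarray:
        gi = self.solve(np.eye(self.matrix.shape[0]))
        return 0.5 * (gi + gi.T)  # exact symmetry despite finite solve accuracy


@dataclass
class ThreeCenterERIs:
    tensor: np.ndarray  # (nbas, nbas, naux)
    operator: CoulombOperator


def coulomb_metric(
    molecule: Molecule, aux: list[AuxiliaryFunction], operator: CoulombOperator = PLAIN
) -> CoulombMetric:
    """Two-center Coulomb matrix G_{kl} = <kbar || lbar> over auxiliary functions."""
    naux = len(aux)
    sites = aux_sites(molecule, aux)
    G = np.zeros((naux, naux))
    kmax = max((f.total_index for f in aux), default=0)
    for s1 in sites:
        positions = np.array([s2.position for s2 in sites])
        zetas = np.array([s2.zeta for s2 in sites])
        alpha = s1.zeta * zetas / (s1.zeta + zetas)
        pref = TWO_PI_POW / (s1.zeta * zetas * np.sqrt(s1.zeta + zetas))
        rpc = s1.position[None, :] - positions
        R = coulomb_r_tensor((2 * kmax, 2 * kmax, 2 * kmax), alpha, rpc, operator)
        for i1, k1 in s1.members:
            for s2i, s2 in enumerate(sites):
                for i2, k2 in s2.members:
                    if i2 > i1:
                        continue
                    phase = (-1.0) ** sum(k2)
                    val = pref[s2i] * phase * R[k1[0] + k2[0], k1[1] + k2[1], k1[2] + k2[2], s2i]
                    G[i1, i2] = G[i2, i1] = val
    Gs = 0.5 * (G + G.T)
    try:
        cond = float(np.linalg.cond(Gs))
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = float("inf")
    return CoulombMetric(Gs, operator, cond)


def three_center(
    molecule: Molecule,
    basis: list[BasisFunction],
    aux: list[AuxiliaryFunction],
    operator: CoulombOperator = PLAIN,
    mo_products: np.ndarray | None = None,
) -> ThreeCenterERIs | np.ndarray:
    """Three-center ERIs <mu nu || kbar> for the requested operator.

    If ``mo_products`` (nmo, nbas, nbas) is given, the per-MO product
    densities Q^p_{mu nu} are contracted inside the integral loop and the
    (nmo, naux) result is returned instead of the full AO tensor; this is
    the M-matrix pathway that avoids any stored AO->MO transformation.
    """
    nb = len(basis)
    naux = len(aux)
    sites = aux_sites(molecule, aux)
    positions = np.array([s.position for s in sites])
    zetas = np.array([s.zeta for s in sites])
    kmax = tuple(
        max((f.index[d] for f in aux), default=0) for d in range(3)
    )
    if mo_products is not None:
        nmo = mo_products.shape[0]
        out = np.zeros((nmo, naux))
    else:
        out = np.zeros((nb, nb, naux))

    for i in range(nb):
        bi = basis[i]
        for j in range(i + 1):
            bj = basis[j]
            ab = bi.origin - bj.origin
            acc = np.zeros(naux)
            for za, ca in zip(bi.exponents, bi.coefficients):
                for zb, cb in zip(bj.exponents, bj.coefficients):
                    c = ca * cb
                    p = za + zb
                    P = (za * bi.origin + zb * bj.origin) / p
                    Es = [
                        hermite_expansion(bi.lmn[d], bj.lmn[d], ab[d], za, zb)
                        for d in range(3)
                    ]
                    Ex = Es[0][bi.lmn[0], bj.lmn[0]]
                    Ey = Es[1][bi.lmn[1], bj.lmn[1]]
                    Ez = Es[2][bi.lmn[2], bj.lmn[2]]
                    ltot = (
                        bi.lmn[0] + bj.lmn[0],
                        bi.lmn[1] + bj.lmn[1],
                        bi.lmn[2] + bj.lmn[2],
                    )
                    alpha = p * zetas / (p + zetas)
                    pref = c * TWO_PI_POW / (p * zetas * np.sqrt(p + zetas))
                    rpc = P[None, :] - positions
                    R = coulomb_r_tensor(
                        (ltot[0] + kmax[0], ltot[1] + kmax[1], ltot[2] + kmax[2]),
                        alpha,
                        rpc,
                        operator,
                    )
                    for sidx, site in enumerate(sites):
                        for gidx, k in site.members:
                            block = R[
                                k[0] : k[0] + ltot[0] + 1,
                                k[1] : k[1] + ltot[1] + 1,
                                k[2] : k[2] + ltot[2] + 1,
                                sidx,
                            ]
                            phase = (-1.0) ** sum(k)
                            acc[gidx] += (
                                pref[sidx]
                                * phase
                                * float(
                                    np.einsum(
                                        "t,u,v,tuv->",
                                        Ex[: ltot[0] + 1],
                                        Ey[: ltot[1] + 1],
                                        Ez[: ltot[2] + 1],
                                        block,
                                    )
                                )
                            )
            if mo_products is not None:
                w = mo_products[:, i, j] if i == j else mo_products[:, i, j] + mo_products[:, j, i]
                out += w[:, None] * acc[None, :]
            else:
                out[i, j, :] = acc
                out[j, i, :] = acc
    if mo_products is not None:
        return out
    return ThreeCenterERIs(out, operator)


# ---------------------------------------------------------------------------
# Four-center ERIs (oracle / exchange path)


@dataclass
class _HermitePair:
    p: float
    P: np.ndarray
    coef: float
    ltot: tuple[int, int, int]
    E: np.ndarray  # dense (lx+1, ly+1, lz+1) product of 1D E coefficients


def _pair_expansions(basis: list[BasisFunction]) -> list[tuple[int, int, list[_HermitePair]]]:
    pairs = []
    nb = len(basis)
    for i in range(nb):
        bi = basis[i]
        for j in range(i + 1):
            bj = basis[j]
            ab = bi.origin - bj.origin
            plist = []
            for za, ca in zip(bi.exponents, bi.coefficients):
                for zb, cb in zip(bj.exponents, bj.coefficients):
                    p = za + zb
                    P = (za * bi.origin + zb * bj.origin) / p
                    Es = [
                        hermite_expansion(bi.lmn[d], bj.lmn[d], ab[d], za, zb)
                        for d in range(3)
                    ]
                    ltot = tuple(bi.lmn[d] + bj.lmn[d] for d in range(3))
                    Ex = Es[0][bi.lmn[0], bj.lmn[0], : ltot[0] + 1]
                    Ey = Es[1][bi.lmn[1], bj.lmn[1], : ltot[1] + 1]
                    Ez = Es[2][bi.lmn[2], bj.lmn[2], : ltot[2] + 1]
                    E = np.einsum("t,u,v->tuv", Ex, Ey, Ez)
                    plist.append(_HermitePair(p, P, ca * cb, ltot, E))
            pairs.append((i, j, plist))
    return pairs


def four_center(
    basis: list[BasisFunction], operator: CoulombOperator = PLAIN, max_nbas: int = 120
) -> np.ndarray:
    """Full AO ERI tensor (mu nu | op | sigma tau) with 8-fold symmetry.

    Intended for small systems (SCF exchange and oracle checks); guarded by
    ``max_nbas``.
    """
    nb = len(basis)
    if nb > max_nbas:
        raise CapabilityError(f"four-center ERIs guarded at N_bas <= {max_nbas} (got {nb})")
    pairs = _pair_expansions(basis)
    eri = np.zeros((nb, nb, nb, nb))

    # flatten ket primitive pairs, grouped by angular shape for batching
    ket_prims: dict[tuple[int, int, int], list[tuple[int, _HermitePair]]] = {}
    for pair_idx, (_, _, plist) in enumerate(pairs):
        for hp in plist:
            ket_prims.setdefault(hp.ltot, []).append((pair_idx, hp))
    ket_groups = {}
    for shape, items in ket_prims.items():
        qs = np.array([hp.p for _, hp in items])
        Qs = np.array([hp.P for _, hp in items])
        coefs = np.array([hp.coef for _, hp in items])
        Emat = np.array([hp.E for _, hp in items])  # (nk, sx+1, sy+1, sz+1)
        idx = np.array([pi for pi, _ in items])
        ket_groups[shape] = (qs, Qs, coefs, Emat, idx)

    npairs = len(pairs)
    vals = np.zeros((npairs, npairs))
    for bra_idx, (_, _, plist) in enumerate(pairs):
        for hp in plist:
            for shape, (qs, Qs, coefs, Emat, idx) in ket_groups.items():
                lx, ly, lz = hp.ltot
                sx, sy, sz = shape
                alpha = hp.p * qs / (hp.p + qs)
                pref = hp.coef * coefs * TWO_PI_POW / (hp.p * qs * np.sqrt(hp.p + qs))
                rpq = hp.P[None, :] - Qs
                R = coulomb_r_tensor((lx + sx, ly + sy, lz + sz), alpha, rpq, operator)
                # contract ket Hermite expansion with the (-1)^|tuv| phase
                racc = np.zeros((lx + 1, ly + 1, lz + 1, len(qs)))
                for a in range(sx + 1):
                    for b in range(sy + 1):
                        for cdx in range(sz + 1):
                            phase = (-1.0) ** (a + b + cdx)
                            racc += (
                                phase
                                * Emat[:, a, b, cdx][None, None, None, :]
                                * R[a : a + lx + 1, b : b + ly + 1, cdx : cdx + lz + 1, :]
                            )
                contrib = pref * np.einsum("tuv,tuvk->k", hp.E, racc)
                np.add.at(vals, (bra_idx, idx), contrib)

    for bi, (i, j, _) in enumerate(pairs):
        for ki, (s, t, _) in enumerate(pairs):
            v = vals[bi, ki]
            eri[i, j, s, t] = eri[j, i, s, t] = eri[i, j, t, s] = eri[j, i, t, s] = v
    return eri


# ---------------------------------------------------------------------------
# Debug dump


def dump_integrals(path, **named_arrays) -> None:
    """Write named integral arrays to an HDF5 container for debugging."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, arr in named_arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))
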