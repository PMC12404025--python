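"""Becke-partitioned molecular quadrature grid.

Per atom: Gauss-Chebyshev (second kind) radial points under the Becke
rational mapping r = R (1+x)/(1-x), with R tied to the Bragg-Slater radius,
times a product angular grid (Gauss-Legendre in cos(theta), uniform in
phi).  The product grid integrates spherical harmonics exactly up to degree
min(2 n_theta - 1, n_phi - 1) and, unlike table-based angular grids, needs
no stored coefficients.

Angular axes are taken from a deterministic molecule-fixed frame (built
from the first two linearly independent interatomic vectors), so the grid
co-rotates with the molecule and grid-based energies are rotationally
covariant to floating-point precision.

Atomic weights use Becke's fuzzy-cell partition (three iterations of the
polynomial step function, no atomic-size adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisFunction
from .constants import bragg_radius_bohr
from .integrals import hermite_value
from .molecule import Molecule

GRID_LEVELS = {
    "coarse": (40, 12, 24),
    "default": (75, 18, 36),
    "fine": (96, 24, 48),
}


@dataclass
class MolecularGrid:
    points: np.ndarray  # (N, 3) bohr
    weights: np.ndarray  # (N,)
    level: str
    n_radial: int
    n_theta: int
    n_phi: int

    @property
    def size(self) -> int:
        return len(self.weights)


def molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Deterministic right-handed orthonormal frame fixed to the molecule.

    Rotating the molecule rotates the frame identically (up to roundoff),
    which makes the grid covariant.  For atoms/linear molecules the
    under-determined axes fall back to a fixed completion; the density is
    axially symmetric there, so grid integrals are still invariant.
    """
    n = len(coords)
    if n == 1:
        return np.eye(3)
    v1 = coords[1] - coords[0]
    e1 = v1 / np.linalg.norm(v1)
    e2 = None
    for k in range(2, n):
        v = coords[k] - coords[0]
        w = v - (v @ e1) * e1
        if np.linalg.norm(w) > 1e-8 * max(1.0, np.linalg.norm(v)):
            e2 = w / np.linalg.norm(w)
            break
    if e2 is None:
        # linear molecule: complete with the least-aligned Cartesian axis
        probe = np.eye(3)[np.argmin(np.abs(e1))]
        w = probe - (probe @ e1) * e1
        e2 = w / np.linalg.norm(w)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _radial_grid(n: int, rm: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Chebyshev-2 nodes mapped by r = rm (1+x)/(1-x); returns (r, w r^2 dr)."""
    i = np.arange(1, n + 1)
    theta = i * np.pi / (n + 1)
    x = np.cos(theta)
    w_x = np.pi / (n + 1) * np.sin(theta)  # plain dx weights
    r = rm * (1.0 + x) / (1.0 - x)
    dr_dx = 2.0 * rm / (1.0 - x) ** 2
    return r, w_x * dr_dx * r * r


def _angular_grid(n_theta: int, n_phi: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere product grid; weights sum to 4 pi."""
    x, w = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    ct = x[:, None] * np.ones(n_phi)[None, :]
    st = np.sqrt(1.0 - x * x)[:, None] * np.ones(n_phi)[None, :]
    pts = np.stack(
        [st * np.cos(phi)[None, :], st * np.sin(phi)[None, :], ct], axis=-1
    ).reshape(-1, 3)
    wts = (w[:, None] * (2.0 * np.pi / n_phi) * np.ones(n_phi)[None, :]).reshape(-1)
    return pts, wts


def _becke_step(mu: np.ndarray, k: int = 3) -> np.ndarray:
    f = mu
    for _ in range(k):
        f = 1.5 * f - 0.5 * f ** 3
    return 0.5 * (1.0 - f)


def _becke_weights(points: np.ndarray, coords: np.ndarray, atom_index: int) -> np.ndarray:
    natom = len(coords)
    if natom == 1:
        return np.ones(len(points))
    dists = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)  # (N, natom)
    P = np.ones((len(points), natom))
    inv_rab = 1.0 / np.linalg.norm(coords[:, None, :] - coords[None, :, :] + np.eye(natom)[..., None], axis=2)
    for a in range(natom):
        for b in range(natom):
            if a == b:
                continue
            mu = (dists[:, a] - dists[:, b]) * inv_rab[a, b]
            P[:, a] *= _becke_step(mu)
    tot = P.sum(axis=1)
    return P[:, atom_index] / np.where(tot > 0, tot, 1.0)


def build_grid(molecule: Molecule, level: str = "default") -> MolecularGrid:
    if level not in GRID_LEVELS:
        raise ValueError(f"grid level {level!r} not in {sorted(GRID_LEVELS)}")
    n_rad, n_theta, n_phi = GRID_LEVELS[level]
    coords = molecule.coordinates
    frame = molecular_frame(coords)
    ang_pts, ang_wts = _angular_grid(n_theta, n_phi)
    ang_pts = ang_pts @ frame.T  # rotate into the molecule-fixed frame

    all_pts, all_wts = [], []
    for ia, atom in enumerate(molecule.atoms):
        rm = bragg_radius_bohr(atom.symbol)
        if atom.atomic_number > 1:
            rm *= 0.5
        r, wr = _radial_grid(n_rad, rm)
        pts = coords[ia][None, None, :] + r[:, None, None] * ang_pts[None, :, :]
        wts = wr[:, None] * ang_wts[None, :]
        pts = pts.reshape(-1, 3)
        wts = wts.reshape(-1)
        wts = wts * _becke_weights(pts, coords, ia)
        keep = wts > 1e-18
        all_pts.append(pts[keep])
        all_wts.append(wts[keep])
    return MolecularGrid(
        np.concatenate(all_pts),
        np.concatenate(all_wts),
        level,
        n_rad,
        n_theta,
        n_phi,
    )


def ao_values(basis: list[BasisFunction], points: np.ndarray) -> np.ndarray:
    """AO values on the grid, shape (nbas, npoints)."""
    out = np.empty((len(basis), len(points)))
    for i, bf in enumerate(basis):
        d = points - bf.origin[None, :]
        r2 = np.einsum("ij,ij->i", d, d)
        rad = np.zeros(len(points))
        for z, c in zip(bf.exponents, bf.coefficients):
            rad += c * np.exp(-z * r2)
        ang = d[:, 0] ** bf.lmn[0] * d[:, 1] ** bf.lmn[1] * d[:, 2] ** bf.lmn[2]
        out[i] = ang * rad
    return out


def aux_values(aux, coords: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Hermite auxiliary-function values on the grid, shape (naux, npoints)."""
    out = np.empty((len(aux), len(points)))
    for i, f in enumerate(aux):
        out[i] = hermite_value(f.exponent, f.index, coords[f.center], points)
    return out
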