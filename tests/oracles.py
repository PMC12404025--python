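"""Independent numerical oracles for Gaussian integrals.

Deliberately avoids every recursion used by the package: Coulomb integrals
come from the Gaussian transform

    1/r12          = (2/sqrt(pi)) Int_0^inf  exp(-t^2 r12^2) dt
    erf(w r12)/r12 = (2/sqrt(pi)) Int_0^w    exp(-t^2 r12^2) dt

whose inner 6D integral factorizes per Cartesian dimension into 2D
polynomial-times-Gaussian integrals, evaluated exactly by rotated
Gauss-Hermite quadrature; the outer t-integral uses adaptive quadrature.
Overlaps use plain 1D Gauss-Hermite quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermval
from scipy.integrate import quad

_GH_X, _GH_W = np.polynomial.hermite.hermgauss(48)
_U1, _U2 = np.meshgrid(_GH_X, _GH_X, indexing="ij")
_W2 = np.outer(_GH_W, _GH_W)


@dataclass
class Factor:
    """One 1D factor: ('cart', l) -> (x-c)^l e^{-z(x-c)^2};
    ('herm', k) -> z^{k/2} H_k(sqrt(z)(x-c)) e^{-z(x-c)^2}."""

    kind: str
    order: int
    z: float
    c: float

    def poly(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "cart":
            return (x - self.c) ** self.order
        coef = np.zeros(self.order + 1)
        coef[self.order] = 1.0
        return self.z ** (self.order / 2.0) * hermval(
            math.sqrt(self.z) * (x - self.c), coef
        )


@dataclass
class Side:
    """A 1D charge-distribution factor list (one Cartesian dimension)."""

    factors: list[Factor]

    @property
    def zsum(self) -> float:
        return sum(f.z for f in self.factors)

    @property
    def zc(self) -> float:
        return sum(f.z * f.c for f in self.factors)

    @property
    def zc2(self) -> float:
        return sum(f.z * f.c * f.c for f in self.factors)

    def poly(self, x: np.ndarray) -> np.ndarray:
        out = np.ones_like(x)
        for f in self.factors:
            out = out * f.poly(x)
        return out


def _pair_integral_1d(s1: Side, s2: Side, t2: float) -> float:
    """Int dx1 dx2 poly1 poly2 exp(-[z1(x1-.)^2 + z2(x2-.)^2 + t2 (x1-x2)^2])."""
    m11 = s1.zsum + t2
    m22 = s2.zsum + t2
    m12 = -t2
    b = np.array([s1.zc, s2.zc])
    M = np.array([[m11, m12], [m12, m22]])
    xstar = np.linalg.solve(M, b)
    q0 = s1.zc2 + s2.zc2 - xstar @ (M @ xstar)
    lam, V = np.linalg.eigh(M)
    # x = x* + V (u / sqrt(lam))
    x1 = xstar[0] + V[0, 0] * _U1 / math.sqrt(lam[0]) + V[0, 1] * _U2 / math.sqrt(lam[1])
    x2 = xstar[1] + V[1, 0] * _U1 / math.sqrt(lam[0]) + V[1, 1] * _U2 / math.sqrt(lam[1])
    vals = s1.poly(x1) * s2.poly(x2)
    return math.exp(-q0) * float(np.sum(_W2 * vals)) / math.sqrt(lam[0] * lam[1])


def _coulomb_primitive(sides1, sides2, omega: float | None = None) -> float:
    """Coulomb interaction of two primitive 3D distributions.

    sides1/sides2: three Side objects (x, y, z).  ``omega=None`` is the
    plain operator; otherwise the erf(omega r)/r long-range kernel.
    """

    def s_of_t(t: float) -> float:
        t2 = t * t
        out = 1.0
        for d in range(3):
            out *= _pair_integral_1d(sides1[d], sides2[d], t2)
        return out

    if omega is None:
        # substitute t = u/(1-u)
        def integrand(u: float) -> float:
            if u >= 1.0:
                return 0.0
            t = u / (1.0 - u)
            return s_of_t(t) / (1.0 - u) ** 2

        val, _ = quad(integrand, 0.0, 1.0, epsabs=1e-13, epsrel=1e-11, limit=300)
    else:
        val, _ = quad(s_of_t, 0.0, omega, epsabs=1e-13, epsrel=1e-11, limit=300)
    return 2.0 / math.sqrt(math.pi) * val


def _ao_sides(bf, iprim: int) -> list[Side]:
    return [
        Side([Factor("cart", bf.lmn[d], bf.exponents[iprim], bf.origin[d])])
        for d in range(3)
    ]


def _pair_sides(bf1, i1: int, bf2, i2: int) -> list[Side]:
    return [
        Side(
            [
                Factor("cart", bf1.lmn[d], bf1.exponents[i1], bf1.origin[d]),
                Factor("cart", bf2.lmn[d], bf2.exponents[i2], bf2.origin[d]),
            ]
        )
        for d in range(3)
    ]


def _hermite_sides(zeta: float, kbar, center) -> list[Side]:
    return [Side([Factor("herm", kbar[d], zeta, center[d])]) for d in range(3)]


# ---------------------------------------------------------------------------
# public oracle entry points (contracted quantities)


def overlap(bf1, bf2) -> float:
    """Contracted AO overlap by 1D Gauss-Hermite quadrature."""
    out = 0.0
    for i1, c1 in enumerate(bf1.coefficients):
        for i2, c2 in enumerate(bf2.coefficients):
            val = 1.0
            for d in range(3):
                s = Side(
                    [
                        Factor("cart", bf1.lmn[d], bf1.exponents[i1], bf1.origin[d]),
                        Factor("cart", bf2.lmn[d], bf2.exponents[i2], bf2.origin[d]),
                    ]
                )
                z = s.zsum
                x0 = s.zc / z
                q0 = s.zc2 - z * x0 * x0
                x = x0 + _GH_X / math.sqrt(z)
                val *= math.exp(-q0) * float(_GH_W @ s.poly(x)) / math.sqrt(z)
            out += c1 * c2 * val
    return out


def metric_element(aux1, aux2, coords, omega: float | None = None) -> float:
    """<kbar || lbar> between two Hermite auxiliary functions."""
    s1 = _hermite_sides(aux1.exponent, aux1.index, coords[aux1.center])
    s2 = _hermite_sides(aux2.exponent, aux2.index, coords[aux2.center])
    return _coulomb_primitive(s1, s2, omega)


def three_center_element(bf1, bf2, aux, coords, omega: float | None = None) -> float:
    """<mu nu || kbar> for contracted AOs and one Hermite auxiliary function."""
    s_aux = _hermite_sides(aux.exponent, aux.index, coords[aux.center])
    out = 0.0
    for i1, c1 in enumerate(bf1.coefficients):
        for i2, c2 in enumerate(bf2.coefficients):
            out += c1 * c2 * _coulomb_primitive(_pair_sides(bf1, i1, bf2, i2), s_aux, omega)
    return out


def four_center_element(bf1, bf2, bf3, bf4, omega: float | None = None) -> float:
    """(mu nu | sigma tau) for contracted AOs."""
    out = 0.0
    for i1, c1 in enumerate(bf1.coefficients):
        for i2, c2 in enumerate(bf2.coefficients):
            bra = _pair_sides(bf1, i1, bf2, i2)
            for i3, c3 in enumerate(bf3.coefficients):
                for i4, c4 in enumerate(bf4.coefficients):
                    ket = _pair_sides(bf3, i3, bf4, i4)
                    out += c1 * c2 * c3 * c4 * _coulomb_primitive(bra, ket, omega)
    return out


def boys_quadrature(n: int, T: float) -> float:
    """F_n(T) by adaptive quadrature of the defining integral."""
    val, _ = quad(
        lambda t: t ** (2 * n) * math.exp(-T * t * t), 0.0, 1.0,
        epsabs=1e-15, epsrel=1e-13, limit=200,
    )
    return val
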