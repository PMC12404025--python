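"""Local-density functional forms: Dirac exchange, its erf-attenuated
short-range variant, and VWN5 correlation (including spin resolution for
the triplet response kernel).

All energy densities e(rho) are per unit volume (hartree / bohr^3) at the
closed-shell (unpolarized) density rho.  Conventions:

* v(rho)   = de/drho          (XC potential)
* f(rho)   = d^2 e/drho^2     (singlet response kernel wrt total density)
* f_m(rho) = d^2 e/dm^2 |_{m=0}, m = rho_alpha - rho_beta
                               (triplet / spin-flip response kernel)

For any exchange functional with exact spin scaling f_m equals f, so only
correlation needs the spin-resolved form.

The attenuated exchange energy density multiplies the Dirac form by the
bracket  [1 - alpha - beta * g(a)],  a = omega / (2 kF),  kF = (3 pi^2
rho)^(1/3), where

    g(a) = (8/3) a [ sqrt(pi) erf(1/(2a)) + 2a (b - c) ],
    b = exp(-1/(4a^2)) - 1,   c = 2 a^2 b + 1/2,

is the fraction of LDA exchange replaced by the long-range erf operator
(g -> 0 as omega -> 0, g -> 1 as omega -> infinity).  A Taylor expansion in
x = 1/(2a) is used for large a where the closed form cancels
catastrophically.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf as _erf

RHO_FLOOR = 1e-14

C_DIRAC = 0.75 * (3.0 / math.pi) ** (1.0 / 3.0)  # e_x = -C_DIRAC * rho^(4/3)


def _clamp(rho) -> np.ndarray:
    return np.maximum(np.asarray(rho, dtype=float), RHO_FLOOR)


# ---------------------------------------------------------------------------
# Dirac exchange


def dirac_energy_density(rho) -> np.ndarray:
    rho = _clamp(rho)
    return -C_DIRAC * rho ** (4.0 / 3.0)


def dirac_potential(rho) -> np.ndarray:
    rho = _clamp(rho)
    return -(4.0 / 3.0) * C_DIRAC * rho ** (1.0 / 3.0)


def dirac_kernel(rho) -> np.ndarray:
    """f_x = -(4/9) C_x rho^(-2/3); also the triplet exchange kernel."""
    rho = _clamp(rho)
    return -(4.0 / 9.0) * C_DIRAC * rho ** (-2.0 / 3.0)


# ---------------------------------------------------------------------------
# erf attenuation factor


def lr_fraction(a) -> np.ndarray:
    """g(a): fraction of LDA exchange carried by the erf(omega r)/r long range."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = a < 10.0
    if np.any(small):
        asv = a[small]
        x = 1.0 / (2.0 * asv)
        b = np.expm1(-x * x)
        c = 2.0 * asv * asv * b + 0.5
        out[small] = (8.0 / 3.0) * asv * (
            math.sqrt(math.pi) * _erf(x) + 2.0 * asv * (b - c)
        )
    big = ~small
    if np.any(big):
        x = 1.0 / (2.0 * a[big])
        x2 = x * x
        # g = 1 - x^2/9 + x^4/60 - x^6/420 + ... (Taylor of the closed form)
        out[big] = 1.0 - x2 / 9.0 + x2 * x2 / 60.0 - x2 * x2 * x2 / 420.0
    return out


def attenuation_bracket(rho, alpha: float, beta: float, omega: float, fx: float = 1.0):
    """[1 - alpha - beta g(a)] with a = omega sqrt(Fx) / (2 kF), kF = (3 pi^2 rho)^(1/3)."""
    rho = _clamp(rho)
    if beta == 0.0:
        return np.full_like(rho, 1.0 - alpha)
    if omega <= 0.0:
        raise ValueError("attenuated bracket with beta != 0 needs omega > 0")
    kf = (3.0 * math.pi ** 2 * rho) ** (1.0 / 3.0)
    a = omega * math.sqrt(fx) / (2.0 * kf)
    return 1.0 - alpha - beta * lr_fraction(a)


def sr_exchange_energy_density(rho, alpha: float, beta: float, omega: float) -> np.ndarray:
    """Semilocal (short-range complement) exchange energy density.

    alpha/beta are the *effective* CAM coefficients (already multiplied by
    c_F); alpha=1, beta=0 gives identically zero (all exchange is Fock).
    """
    if omega < 0:
        raise ValueError("rs_omega must be >= 0")
    rho = _clamp(rho)
    if beta == 0.0:
        return (1.0 - alpha) * dirac_energy_density(rho)
    return dirac_energy_density(rho) * attenuation_bracket(rho, alpha, beta, omega)


def _fd_second(fn, rho, rel_step: float = 1e-4) -> np.ndarray:
    """Richardson-extrapolated 5-point second derivative in rho."""
    rho = _clamp(rho)
    h = rel_step * rho

    def second(hh):
        return (fn(rho + hh) - 2.0 * fn(rho) + fn(rho - hh)) / (hh * hh)

    d1 = second(h)
    d2 = second(0.5 * h)
    return (4.0 * d2 - d1) / 3.0


def sr_exchange_kernel(rho, alpha: float, beta: float, omega: float) -> np.ndarray:
    """f_x^SR = d^2 e_x^SR / drho^2 (finite differences of the closed form)."""
    rho = _clamp(rho)
    if beta == 0.0:
        return (1.0 - alpha) * dirac_kernel(rho)
    return _fd_second(lambda r: sr_exchange_energy_density(r, alpha, beta, omega), rho)


# ---------------------------------------------------------------------------
# VWN5 correlation

_VWN_P = (0.0310907, -0.10498, 3.72744, 12.9352)  # paramagnetic
_VWN_F = (0.01554535, -0.32500, 7.06042, 18.0578)  # ferromagnetic
_VWN_A = (-1.0 / (6.0 * math.pi ** 2), -0.0047584, 1.13107, 13.0045)  # spin stiffness

_FZ_DEN = 2.0 ** (4.0 / 3.0) - 2.0
_FZ_DD0 = 8.0 / (9.0 * _FZ_DEN)  # f''(0)


def _vwn_g(rs, params) -> np.ndarray:
    A, x0, b, c = params
    x = np.sqrt(rs)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Q = math.sqrt(4.0 * c - b * b)
    atn = np.arctan(Q / (2.0 * x + b))
    return A * (
        np.log(x * x / X)
        + 2.0 * b / Q * atn
        - b * x0 / X0 * (np.log((x - x0) ** 2 / X) + 2.0 * (b + 2.0 * x0) / Q * atn)
    )


def _vwn_dg_drs(rs, params) -> np.ndarray:
    """Analytic d eps / d rs for one VWN fit."""
    A, x0, b, c = params
    x = np.sqrt(rs)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Q = math.sqrt(4.0 * c - b * b)
    t = 2.0 * x + b
    datn = -2.0 * Q / (Q * Q + t * t)  # d/dx arctan(Q/t)
    dX = t
    d_dx = A * (
        2.0 / x
        - dX / X
        + 2.0 * b / Q * datn
        - b * x0 / X0 * (2.0 / (x - x0) - dX / X + 2.0 * (b + 2.0 * x0) / Q * datn)
    )
    return d_dx * 0.5 / x  # d rs -> d x


def _rs(rho) -> np.ndarray:
    return (3.0 / (4.0 * math.pi * _clamp(rho))) ** (1.0 / 3.0)


def _fz(zeta) -> np.ndarray:
    zeta = np.clip(zeta, -1.0, 1.0)
    return ((1.0 + zeta) ** (4.0 / 3.0) + (1.0 - zeta) ** (4.0 / 3.0) - 2.0) / _FZ_DEN


def vwn5_eps(rho, zeta=0.0) -> np.ndarray:
    """Correlation energy per electron eps_c(rs, zeta), VWN5 interpolation."""
    rs = _rs(rho)
    ep = _vwn_g(rs, _VWN_P)
    if np.isscalar(zeta) and zeta == 0.0:
        return ep
    ef = _vwn_g(rs, _VWN_F)
    ea = _vwn_g(rs, _VWN_A)
    z = np.asarray(zeta, dtype=float)
    z4 = z ** 4
    fz = _fz(z)
    return ep + ea * fz / _FZ_DD0 * (1.0 - z4) + (ef - ep) * fz * z4


def vwn5_energy_density(rho, zeta=0.0) -> np.ndarray:
    return _clamp(rho) * vwn5_eps(rho, zeta)


def vwn5_potential(rho) -> np.ndarray:
    """v_c = eps - (rs/3) d eps/d rs at zeta = 0 (analytic)."""
    rs = _rs(rho)
    return _vwn_g(rs, _VWN_P) - rs / 3.0 * _vwn_dg_drs(rs, _VWN_P)


def vwn5_kernel(rho, rel_step: float = 1e-4) -> np.ndarray:
    """Singlet correlation kernel d^2 (rho eps_c)/drho^2 via Richardson FD."""
    return _fd_second(lambda r: vwn5_energy_density(r), rho, rel_step)


def vwn5_triplet_kernel(rho, rel_step: float = 1e-4) -> np.ndarray:
    """Triplet kernel d^2 e_c/dm^2 at m=0 (spin-stiffness direction).

    Central second difference in the magnetization m at fixed total rho;
    e_c is even in m so the difference formula is exact to O(h^4).
    """
    rho = _clamp(rho)
    h = rel_step * rho

    def e_of_m(m):
        zeta = m / rho
        return rho * vwn5_eps(rho, zeta)

    e0 = rho * vwn5_eps(rho)
    d1 = (e_of_m(h) - 2.0 * e0 + e_of_m(-h)) / (h * h)
    d2 = (e_of_m(0.5 * h) - 2.0 * e0 + e_of_m(-0.5 * h)) / (0.25 * h * h)
    return (4.0 * d2 - d1) / 3.0
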