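"""Auxiliary-space exchange-correlation kernel matrices and the O matrix.

The response coupling matrix in auxiliary-function space is

    O = G^-1 + G^-1 <mbar| f |nbar> G^-1

where f is the ADFT kernel evaluated at the *fitted* density rho~ (the
orbital density never enters the response kernel) and <m|f|n> is a grid
contraction over auxiliary-function values.

Variants (all symmetric):

* ``pure``:  f = f_xc = f_x + f_c                      (no Fock exchange)
* ``gh``:    f = f_xc - c_F f_x = (1 - c_F) f_x + f_c  (global hybrid)
* ``rs``:    f = f_x^SR + f_c                          (range separated)

With the attenuated-exchange bracket parametrized by the effective CAM
coefficients (c_F alpha, c_F beta) all three are the same formula; the
variant tag only validates that the request matches the functional.

Triplet channel: the Hartree G^-1 term is dropped and f is replaced by the
spin-flip kernel d^2 E_xc/dm^2 (equal to the singlet kernel for the
exchange part by exact spin scaling; VWN5 spin stiffness for correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lda
from .basis import AuxiliaryFunction
from .functionals import FunctionalSpec
from .grid import MolecularGrid, aux_values
from .integrals import CoulombMetric
from .molecule import Molecule

O_VARIANTS = ("pure", "gh", "rs")


@dataclass
class OMatrix:
    matrix: np.ndarray
    variant: str
    spin: str = "singlet"


def fitted_density_values(
    x: np.ndarray, aux: list[AuxiliaryFunction], molecule: Molecule, points: np.ndarray
) -> np.ndarray:
    """rho~(r) = sum_k x_k kbar(r) on a point batch."""
    vals = aux_values(aux, molecule.coordinates, points)
    return x @ vals


KERNEL_DENSITY_SCREEN = 1e-7


def lda_kernel_values(
    rho,
    functional: FunctionalSpec,
    spin: str = "singlet",
    screen: float = KERNEL_DENSITY_SCREEN,
) -> np.ndarray:
    """Pointwise kernel f(rho~) for the requested spin channel.

    Negative densities are clamped at the 1e-14 floor before evaluation.
    The LDA kernel diverges as rho^(-2/3), so points where the fitted
    density is below ``screen`` (where the fit carries no information and
    small negative excursions are clamped) contribute zero; without this
    screen the clamped tail would dominate the kernel matrices.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < -1e-3):
        import warnings

        warnings.warn(
            f"fitted density reaches {rho.min():.3e}; clamped at the floor",
            RuntimeWarning,
            stacklevel=2,
        )
    live = rho >= screen
    fx = lda.sr_exchange_kernel(rho, functional.sr_alpha, functional.sr_beta, functional.rs_omega)
    if functional.correlation != "none":
        if spin == "singlet":
            fx = fx + lda.vwn5_kernel(rho)
        elif spin == "triplet":
            fx = fx + lda.vwn5_triplet_kernel(rho)
        else:
            raise ValueError(f"unknown spin channel {spin!r}")
    elif spin not in ("singlet", "triplet"):
        raise ValueError(f"unknown spin channel {spin!r}")
    return np.where(live, fx, 0.0)


def kernel_matrix(aux_vals: np.ndarray, weights: np.ndarray, fvals: np.ndarray) -> np.ndarray:
    """<mbar| f |nbar> = sum_p w_p m(r_p) f(r_p) n(r_p); exactly symmetric."""
    m = (aux_vals * (weights * fvals)[None, :]) @ aux_vals.T
    return 0.5 * (m + m.T)


def build_O(
    variant: str,
    metric: CoulombMetric,
    kernel: np.ndarray | None,
    functional: FunctionalSpec | None = None,
) -> OMatrix:
    """O = G^-1 + G^-1 K G^-1; ``kernel=None`` gives the Hartree-only O = G^-1."""
    if variant not in O_VARIANTS:
        raise ValueError(f"unknown O variant {variant!r}")
    if functional is not None:
        if variant == "gh" and functional.cam_beta != 0.0:
            raise ValueError("gh variant requested for a range-separated functional")
        if variant == "rs" and functional.is_range_separated and functional.rs_omega <= 0.0:
            raise ValueError("rs variant needs rs_omega > 0")
    ginv = metric.inverse()
    if kernel is None:
        return OMatrix(ginv.copy(), variant)
    o = ginv + ginv @ kernel @ ginv
    return OMatrix(0.5 * (o + o.T), variant)


def response_kernel_matrices(
    molecule: Molecule,
    aux: list[AuxiliaryFunction],
    grid: MolecularGrid,
    metric: CoulombMetric,
    functional: FunctionalSpec,
    fit_coefficients: np.ndarray,
) -> dict[str, OMatrix]:
    """Assemble the singlet O matrix and the triplet (kernel-only) matrix."""
    avals = aux_values(aux, molecule.coordinates, grid.points)
    rho = fit_coefficients @ avals
    variant = "rs" if functional.is_range_separated else ("gh" if functional.is_hybrid else "pure")

    f_s = lda_kernel_values(rho, functional, "singlet")
    k_s = kernel_matrix(avals, grid.weights, f_s)
    o_singlet = build_O(variant, metric, k_s, functional)

    f_t = lda_kernel_values(rho, functional, "triplet")
    k_t = kernel_matrix(avals, grid.weights, f_t)
    ginv = metric.inverse()
    o_t = ginv @ k_t @ ginv  # no Hartree term in the triplet channel
    o_triplet = OMatrix(0.5 * (o_t + o_t.T), variant, spin="triplet")
    return {"singlet": o_singlet, "triplet": o_triplet}
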