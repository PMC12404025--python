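"""Exchange-correlation functional specification.

A functional is described by the Fock-exchange mixing c_F, the CAM
range-separation coefficients (alpha, beta) of the operator
(alpha + beta erf(omega r))/r, the range-separation parameter rs_omega,
and the semilocal kernel families.  The semilocal host is LDA (Dirac
exchange + VWN5 correlation) or its erf-attenuated short-range variant;
the hybrid machinery (HDA shifts, exchange operators) is agnostic to the
semilocal family.

The effective Fock-exchange operator is c_F * (alpha + beta erf(omega r))/r
and the semilocal exchange keeps the complementary fraction.  Global
hybrids are the special case (alpha, beta) = (1, 0); inverse range
separation (short-range Fock exchange, HSE-type) uses beta < 0, permitted
only with ``inverse=True``.

Named presets carry the mixing parameters of the corresponding published
functionals; their semilocal part here is always the LDA host, so results
are "hybrid parameters X on an LDA host", not reproductions of the full
GGA-based functionals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .integrals import CoulombOperator


@dataclass(frozen=True)
class FunctionalSpec:
    name: str = "lda"
    c_F: float = 0.0
    cam_alpha: float = 1.0
    cam_beta: float = 0.0
    rs_omega: float = 0.0
    inverse: bool = False
    exchange: str = "lda"  # "lda" | "lda-sr" (attenuated complement)
    correlation: str = "vwn5"  # "vwn5" | "none"

    def __post_init__(self) -> None:
        a, b = self.cam_alpha, self.cam_beta
        if not (0.0 <= self.c_F <= 1.0):
            raise ValueError(f"c_F={self.c_F} outside [0, 1]")
        if not (0.0 <= a <= 1.0):
            raise ValueError(f"CAM alpha={a} outside [0, 1]")
        if self.inverse:
            if not (-1.0 <= b <= 0.0):
                raise ValueError(f"inverse functional needs -1 <= beta <= 0, got {b}")
        elif not (0.0 <= b <= 1.0):
            raise ValueError(f"CAM beta={b} outside [0, 1] (set inverse=True for beta < 0)")
        if not (0.0 <= a + b <= 1.0):
            raise ValueError(f"CAM alpha+beta={a + b} outside [0, 1]")
        if self.rs_omega < 0.0:
            raise ValueError("rs_omega must be >= 0")
        if b != 0.0 and self.rs_omega == 0.0:
            raise ValueError("beta != 0 requires rs_omega > 0")
        if self.exchange not in ("lda", "lda-sr"):
            raise ValueError(f"unknown exchange family {self.exchange!r}")
        if self.correlation not in ("vwn5", "none"):
            raise ValueError(f"unknown correlation family {self.correlation!r}")

    # -- derived quantities ------------------------------------------------

    @property
    def is_hybrid(self) -> bool:
        return self.c_F != 0.0

    @property
    def is_range_separated(self) -> bool:
        return self.c_F != 0.0 and self.cam_beta != 0.0

    @property
    def fock_plain_weight(self) -> float:
        """Coefficient of plain-operator Fock exchange."""
        return self.c_F * self.cam_alpha

    @property
    def fock_erf_weight(self) -> float:
        """Coefficient of erf(omega r)/r Fock exchange."""
        return self.c_F * self.cam_beta

    @property
    def sr_alpha(self) -> float:
        """alpha entering the attenuated semilocal exchange bracket."""
        return self.c_F * self.cam_alpha

    @property
    def sr_beta(self) -> float:
        """beta entering the attenuated semilocal exchange bracket."""
        return self.c_F * self.cam_beta

    def exchange_operator(self) -> CoulombOperator:
        """The Fock-exchange two-electron operator c_F (alpha + beta erf)/r."""
        return CoulombOperator(self.fock_plain_weight, self.fock_erf_weight, self.rs_omega)

    def erf_operator(self) -> CoulombOperator:
        return CoulombOperator.erf(self.rs_omega)


def make_functional(
    name: str | None = None,
    c_F: float | None = None,
    cam_alpha: float | None = None,
    cam_beta: float | None = None,
    rs_omega: float | None = None,
    inverse: bool | None = None,
) -> FunctionalSpec:
    """Resolve a preset by name and/or override individual parameters."""
    base = FUNCTIONALS[name.lower()] if name else FunctionalSpec()
    overrides = {}
    if c_F is not None:
        overrides["c_F"] = c_F
    if cam_alpha is not None:
        overrides["cam_alpha"] = cam_alpha
    if cam_beta is not None:
        overrides["cam_beta"] = cam_beta
    if rs_omega is not None:
        overrides["rs_omega"] = rs_omega
    if inverse is not None:
        overrides["inverse"] = inverse
    return replace(base, **overrides) if overrides else base


# Hybrid-mixing parameters from the original functional publications.
# The semilocal host is LDA throughout (see module docstring).
FUNCTIONALS: dict[str, FunctionalSpec] = {
    "lda": FunctionalSpec("lda", 0.0, 1.0, 0.0, 0.0),
    "pbe0": FunctionalSpec("pbe0", 0.25, 1.0, 0.0, 0.0),
    "b3lyp": FunctionalSpec("b3lyp", 0.20, 1.0, 0.0, 0.0),
    "cam-b3lyp": FunctionalSpec(
        "cam-b3lyp", 1.0, 0.19, 0.46, 0.33, exchange="lda-sr"
    ),
    "lc-lda": FunctionalSpec("lc-lda", 1.0, 0.0, 1.0, 0.33, exchange="lda-sr"),
    "hse06": FunctionalSpec(
        "hse06", 1.0, 0.25, -0.25, 0.11, inverse=True, exchange="lda-sr"
    ),
}
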