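"""Run configuration: a flat YAML key/value document with schema-checked
defaults, validated (CAM bounds included) before any computation starts."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .functionals import FunctionalSpec, make_functional

_ALLOWED = {
    "xyz", "basis", "aux_basis", "charge",
    "functional", "c_F", "cam_alpha", "cam_beta", "rs_omega", "inverse",
    "n_roots", "mode", "spin", "approximation", "grid_level",
    "scf_energy_tol", "scf_density_tol", "davidson_tol", "eigensolver",
    "seed", "fixture", "fixture_basis", "spectrum_fwhm_ev", "log_level",
}


@dataclass
class RunConfig:
    xyz: str | None = None
    basis: str | None = None
    aux_basis: str | None = None
    charge: int = 0
    fixture: str | None = None  # alternative to explicit file paths
    fixture_basis: str = "sto-3g"
    functional: str | None = "lda"
    c_F: float | None = None
    cam_alpha: float | None = None
    cam_beta: float | None = None
    rs_omega: float | None = None
    inverse: bool | None = None
    n_roots: int = 10
    mode: str = "rpa"
    spin: str = "singlet"
    approximation: str = "hda"
    grid_level: str = "default"
    scf_energy_tol: float = 1e-8
    scf_density_tol: float = 1e-6
    davidson_tol: float = 1e-6
    eigensolver: str = "davidson"
    seed: int = 0  # property tests / reproducibility bookkeeping only
    spectrum_fwhm_ev: float = 0.3
    log_level: str = "summary"

    def functional_spec(self) -> FunctionalSpec:
        return make_functional(
            self.functional, self.c_F, self.cam_alpha, self.cam_beta,
            self.rs_omega, self.inverse,
        )

    def validate(self) -> "RunConfig":
        self.functional_spec()  # raises on out-of-bounds CAM / c_F parameters
        if self.mode not in ("rpa", "tda"):
            raise ValueError(f"mode must be rpa or tda, got {self.mode!r}")
        if self.spin not in ("singlet", "triplet"):
            raise ValueError(f"spin must be singlet or triplet, got {self.spin!r}")
        if self.approximation not in ("hda", "oracle", "pure"):
            raise ValueError(
                f"approximation must be hda, oracle or pure, got {self.approximation!r}"
            )
        if self.grid_level not in ("coarse", "default", "fine"):
            raise ValueError(f"unknown grid level {self.grid_level!r}")
        if self.eigensolver not in ("davidson", "dense"):
            raise ValueError(f"eigensolver must be davidson or dense")
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if self.fixture is None and (self.xyz is None or self.basis is None or self.aux_basis is None):
            raise ValueError("either 'fixture' or all of xyz/basis/aux_basis must be set")
        return self

    def echo(self) -> str:
        """Full effective configuration, for reproducible logs."""
        lines = [f"{k}: {v}" for k, v in sorted(asdict(self).items())]
        return "\n".join(lines)


def load_config(source) -> RunConfig:
    """Load a RunConfig from YAML text or a file path; unknown keys are errors."""
    text = source
    p = Path(str(source))
    if p.exists() and p.is_file():
        text = p.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat YAML mapping")
    unknown = set(data) - _ALLOWED
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    return cfg.validate()
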