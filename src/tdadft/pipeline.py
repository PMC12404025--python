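"""End-to-end driver: parse -> SCF -> kernel -> response -> results table."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import (
    assign_aux_basis,
    assign_shells,
    build_ao_basis,
    parse_aux_basis,
    parse_basis,
)
from .config import RunConfig
from .fixtures import generate_fixture
from .molecule import parse_xyz
from .response import ExcitationResult, ResponseEngine
from .scf import SCFOptions, SCFResult, run_scf

log = logging.getLogger("tdadft")


@dataclass
class PipelineResult:
    config: RunConfig
    scf: SCFResult
    excitations: ExcitationResult
    table: pd.DataFrame
    engine: ResponseEngine


def _load_system(config: RunConfig):
    if config.fixture is not None:
        fx = generate_fixture(config.fixture, config.fixture_basis)
        return fx.molecule, fx.ao_basis(), fx.aux_basis()
    xyz_text = Path(config.xyz).read_text() if Path(config.xyz).exists() else config.xyz
    mol = parse_xyz(xyz_text, charge=config.charge)
    basis_text = (
        Path(config.basis).read_text() if Path(config.basis).exists() else config.basis
    )
    aux_text = (
        Path(config.aux_basis).read_text()
        if Path(config.aux_basis).exists()
        else config.aux_basis
    )
    shells = assign_shells(mol, {s: parse_basis(basis_text, s) for s in set(mol.symbols)})
    aux = assign_aux_basis(mol, {s: parse_aux_basis(aux_text, s) for s in set(mol.symbols)})
    return mol, build_ao_basis(mol, shells), aux


def results_table(result: ExcitationResult) -> pd.DataFrame:
    rows = []
    for r in range(len(result.omega)):
        i, a, weight = result.dominant_pair(r)
        rows.append(
            {
                "root": r + 1,
                "spin": result.spin,
                "omega_ev": result.omega_ev[r],
                "f": result.oscillator_strengths[r],
                "dominant": f"{i + 1}->{a + 1}",
                "weight": weight,
            }
        )
    return pd.DataFrame(rows)


def table_to_tsv(table: pd.DataFrame) -> str:
    return table.to_csv(sep="\t", index=False, float_format="%.8f")


def broadened_spectrum(
    result: ExcitationResult,
    fwhm_ev: float = 0.3,
    e_min: float | None = None,
    e_max: float | None = None,
    n_points: int = 1000,
) -> str:
    """Gaussian-broadened absorption spectrum as two-column text (eV, intensity)."""
    omega = result.omega_ev
    f = result.oscillator_strengths
    if e_min is None:
        e_min = max(0.0, omega.min() - 2.0 * fwhm_ev)
    if e_max is None:
        e_max = omega.max() + 2.0 * fwhm_ev
    grid = np.linspace(e_min, e_max, n_points)
    sigma = fwhm_ev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    spec = np.zeros_like(grid)
    for w, fi in zip(omega, f):
        spec += fi * np.exp(-0.5 * ((grid - w) / sigma) ** 2)
    lines = [f"{e:.6f}\t{s:.8e}" for e, s in zip(grid, spec)]
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Validate config, run SCF, build the response engine, solve excitations."""
    config.validate()
    level = logging.DEBUG if config.log_level == "debug" else logging.INFO
    log.setLevel(level)
    log.info("effective configuration:\n%s", config.echo())
    functional = config.functional_spec()
    mol, basis, aux = _load_system(config)
    log.info(
        "system: %d atoms, %d electrons, %d AOs, %d auxiliary functions",
        mol.n_atoms, mol.n_electrons, len(basis), len(aux),
    )
    opts = SCFOptions(
        energy_tol=config.scf_energy_tol,
        density_tol=config.scf_density_tol,
        grid_level=config.grid_level,
    )
    need_4c = functional.is_hybrid or config.approximation == "oracle"
    from .scf import build_environment

    env = build_environment(mol, basis, aux, functional, config.grid_level, need_4c)
    scf_result, env = run_scf(mol, basis, aux, functional, opts, environment=env)
    log.info(
        "SCF converged in %d iterations: E = %.10f Ha",
        scf_result.n_iterations, scf_result.energy,
    )
    engine = ResponseEngine(scf_result, env)
    if config.approximation == "oracle":
        exc = engine.reference_full_hybrid(config.n_roots, spin=config.spin, mode=config.mode)
    else:
        exc = engine.excitations(
            n_roots=config.n_roots,
            spin=config.spin,
            mode=config.mode,
            method=config.eigensolver,
            approximation=config.approximation,
            tol=config.davidson_tol,
        )
    for r in range(len(exc.omega)):
        log.debug(
            "root %d: omega = %.6f eV, f = %.6f", r + 1, exc.omega_ev[r],
            exc.oscillator_strengths[r],
        )
    table = results_table(exc)
    return PipelineResult(config, scf_result, exc, table, engine)
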