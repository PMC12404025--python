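"""Molecular geometry container and XYZ parsing.

Geometries enter in Angstrom (standard XYZ) and are stored in bohr.
Only closed-shell (even electron count) molecules are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM, SYMBOL_TO_Z, Z_TO_SYMBOL


class ParseError(ValueError):
    """Malformed input text (XYZ or basis file)."""


@dataclass
class Atom:
    symbol: str
    atomic_number: int
    position: np.ndarray  # bohr, shape (3,)


@dataclass
class Molecule:
    atoms: list[Atom]
    charge: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        if self.n_electrons <= 0:
            raise ValueError("molecule has no electrons")
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"odd electron count {self.n_electrons}: only closed shells supported"
            )
        coords = self.coordinates
        for i in range(len(self.atoms)):
            for j in range(i + 1, len(self.atoms)):
                if np.linalg.norm(coords[i] - coords[j]) < 1e-6:
                    raise ValueError(f"atoms {i} and {j} coincide")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_electrons(self) -> int:
        return sum(a.atomic_number for a in self.atoms) - self.charge

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def symbols(self) -> list[str]:
        return [a.symbol for a in self.atoms]

    def nuclear_repulsion(self) -> float:
        e = 0.0
        coords = self.coordinates
        for i, ai in enumerate(self.atoms):
            for j in range(i + 1, len(self.atoms)):
                r = np.linalg.norm(coords[i] - coords[j])
                e += ai.atomic_number * self.atoms[j].atomic_number / r
        return e

    def translated(self, shift) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        atoms = [Atom(a.symbol, a.atomic_number, a.position + shift) for a in self.atoms]
        return Molecule(atoms, charge=self.charge, comment=self.comment)

    def rotated(self, rotation) -> "Molecule":
        rot = np.asarray(rotation, dtype=float)
        atoms = [Atom(a.symbol, a.atomic_number, rot @ a.position) for a in self.atoms]
        return Molecule(atoms, charge=self.charge, comment=self.comment)


def parse_xyz(text: str, charge: int = 0) -> Molecule:
    """Parse standard XYZ text (count line, comment line, ``El x y z`` rows, Angstrom)."""
    lines = text.splitlines()
    stripped = [ln for ln in lines]
    if not stripped:
        raise ParseError("empty XYZ input")
    try:
        count = int(stripped[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"line 1: expected atom count, got {stripped[0]!r}") from exc
    comment = stripped[1] if len(stripped) > 1 else ""
    body = [ln for ln in stripped[2:] if ln.strip()]
    if len(body) != count:
        raise ParseError(
            f"declared {count} atoms but found {len(body)} atom lines"
        )
    atoms = []
    for k, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"line {k + 3}: expected 'El x y z', got {line!r}")
        sym = parts[0].capitalize()
        if sym not in SYMBOL_TO_Z:
            raise ParseError(f"line {k + 3}: unknown element symbol {parts[0]!r}")
        try:
            pos = np.array([float(p) for p in parts[1:4]])
        except ValueError as exc:
            raise ParseError(f"line {k + 3}: non-numeric coordinate in {line!r}") from exc
        atoms.append(Atom(sym, SYMBOL_TO_Z[sym], pos * BOHR_PER_ANGSTROM))
    return Molecule(atoms, charge=charge, comment=comment)


def write_xyz(molecule: Molecule) -> str:
    """Serialize back to XYZ text (Angstrom); inverse of :func:`parse_xyz`."""
    lines = [str(molecule.n_atoms), molecule.comment]
    for a in molecule.atoms:
        x, y, z = a.position / BOHR_PER_ANGSTROM
        lines.append(f"{a.symbol:<3s} {x: .12f} {y: .12f} {z: .12f}")
    return "\n".join(lines) + "\n"


def atom_symbol(z: int) -> str:
    return Z_TO_SYMBOL[z]
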