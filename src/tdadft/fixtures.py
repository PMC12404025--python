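"""Self-contained fixture molecules with embedded basis and auxiliary sets.

Everything the pipeline needs for the toy systems (H2, HeH+, LiH, H2O and
the linear-alkane series) is generated here: XYZ geometry text, a minimal
(STO-3G) orbital basis, an optional split-valence (6-31G) set for H and O,
and even-tempered spd Hermite auxiliary sets.

The auxiliary sets are explicit even-tempered series chosen to span the
exponent range of the orbital product densities of each element (s sets
bracketing [~0.2, ~2 zeta_max], plus diffuse spd sets for polarization of
the fitted density).  They are explicit shipped sets; automatic
auxiliary-set generation is not part of this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .basis import (
    AuxiliaryFunction,
    ContractedShell,
    assign_aux_basis,
    assign_shells,
    build_ao_basis,
    parse_aux_basis,
    parse_basis,
)
from .molecule import Molecule, parse_xyz

STO3G = """\
****
H 0
S   3   1.00
      3.42525091         0.15432897
      0.62391373         0.53532814
      0.16885540         0.44463454
****
He 0
S   3   1.00
      6.36242139         0.15432897
      1.15892300         0.53532814
      0.31364979         0.44463454
****
Li 0
S   3   1.00
     16.11957500         0.15432897
      2.93620070         0.53532814
      0.79465050         0.44463454
SP   3   1.00
      0.63628970        -0.09996723         0.15591627
      0.14786010         0.39951283         0.60768372
      0.04808870         0.70011547         0.39195739
****
C 0
S   3   1.00
     71.61683700         0.15432897
     13.04509600         0.53532814
      3.53051220         0.44463454
SP   3   1.00
      2.94124940        -0.09996723         0.15591627
      0.68348310         0.39951283         0.60768372
      0.22228990         0.70011547         0.39195739
****
O 0
S   3   1.00
    130.70932000         0.15432897
     23.80886100         0.53532814
      6.44360830         0.44463454
SP   3   1.00
      5.03315130        -0.09996723         0.15591627
      1.16959610         0.39951283         0.60768372
      0.38038900         0.70011547         0.39195739
****
"""

G631 = """\
****
H 0
S   3   1.00
     18.73113700         0.03349460
      2.82539370         0.23472695
      0.64012170         0.81375733
S   1   1.00
      0.16127780         1.00000000
****
O 0
S   6   1.00
   5484.67170000         0.00183110
    825.23495000         0.01395010
    188.04696000         0.06844510
     52.96450000         0.23271430
     16.89757000         0.47019300
      5.79963530         0.35852090
SP   3   1.00
     15.53961600        -0.11077750         0.07087430
      3.59993360        -0.14802630         0.33975280
      1.01376180         1.13076700         0.72715860
SP   1   1.00
      0.27000580         1.00000000         1.00000000
****
"""


def _even_tempered_block(element: str, s_exps, spd_exps) -> str:
    lines = ["****", f"{element} 0"]
    for z in s_exps:
        lines += ["S   1   1.00", f"      {z:.8f}         1.00000000"]
    for z in spd_exps:
        lines += ["D   1   1.00", f"      {z:.8f}         1.00000000"]
    lines.append("****")
    return "\n".join(lines)


def _even_tempered(zmin: float, zmax: float, n: int) -> list[float]:
    if n == 1:
        return [math.sqrt(zmin * zmax)]
    ratio = (zmax / zmin) ** (1.0 / (n - 1))
    return [zmax / ratio**i for i in range(n)]


# s exponents span ~[0.2, 2 zeta_max of the orbital set]; the two spd sets
# polarize the fitted density in the bond region.
AUX_SETS = "\n".join(
    [
        _even_tempered_block("H", _even_tempered(0.22, 9.0, 5), [1.0, 0.3]),
        _even_tempered_block("He", _even_tempered(0.5, 14.0, 4), [2.0]),
        _even_tempered_block("Li", _even_tempered(0.07, 40.0, 6), [0.4, 0.12]),
        _even_tempered_block("C", _even_tempered(0.25, 170.0, 7), [1.5, 0.45]),
        _even_tempered_block("O", _even_tempered(0.3, 280.0, 7), [1.7, 0.5]),
    ]
)

_GEOMETRIES = {
    # bond lengths: H2 0.7408 A (1.4 bohr), HeH+ 0.7743 A (1.4632 bohr),
    # LiH 1.5949 A, water experimental-ish geometry
    "h2": ("""2
hydrogen molecule, R = 1.4 bohr
H 0.0 0.0 0.0
H 0.0 0.0 0.7408481
""", 0),
    "heh+": ("""2
helium hydride cation, R = 1.4632 bohr
He 0.0 0.0 0.0
H 0.0 0.0 0.7743
""", 1),
    "lih": ("""2
lithium hydride
Li 0.0 0.0 0.0
H 0.0 0.0 1.5949
""", 0),
    "h2o": ("""3
water
O 0.0000000 0.0000000 0.1173000
H 0.0000000 0.7572000 -0.4692000
H 0.0000000 -0.7572000 -0.4692000
""", 0),
}


def _alkane_xyz(n: int) -> str:
    """Staggered all-anti linear alkane C_n H_{2n+2} (idealized geometry)."""
    if n < 1:
        raise ValueError("alkane length must be >= 1")
    import numpy as np

    rcc, rch = 1.526, 1.090
    theta = math.radians(109.47)
    atoms: list[tuple[str, np.ndarray]] = []
    # carbon backbone zig-zag in the xz plane
    dz = rcc * math.sin(theta / 2.0)
    dx = rcc * math.cos(theta / 2.0)
    carbons = [np.array([dx * (i % 2), 0.0, dz * i]) for i in range(n)]
    atoms += [("C", c) for c in carbons]

    def h_dirs(sign):
        # two out-of-plane C-H directions for a CH2 unit
        a = math.radians(109.47)
        return [
            np.array([sign * math.cos(a / 2.0), math.sin(a / 2.0), 0.0]),
            np.array([sign * math.cos(a / 2.0), -math.sin(a / 2.0), 0.0]),
        ]

    for i, c in enumerate(carbons):
        sign = 1.0 if i % 2 == 0 else -1.0
        for d in h_dirs(sign):
            atoms.append(("H", c + rch * d / np.linalg.norm(d)))
        if i == 0:
            atoms.append(("H", c + rch * np.array([0.0, 0.0, -1.0])))
        if i == n - 1:
            atoms.append(("H", c + rch * np.array([0.0, 0.0, 1.0])))
    if n == 1:  # methane needs 4 H total; the two caps + two side H suffice
        pass
    lines = [str(len(atoms)), f"linear alkane C{n}H{2 * n + 2}"]
    for sym, pos in atoms:
        lines.append(f"{sym} {pos[0]: .6f} {pos[1]: .6f} {pos[2]: .6f}")
    return "\n".join(lines) + "\n"


@dataclass
class Fixture:
    name: str
    xyz: str
    charge: int
    basis_text: str
    aux_text: str

    @property
    def molecule(self) -> Molecule:
        return parse_xyz(self.xyz, charge=self.charge)

    def shells(self) -> list[ContractedShell]:
        mol = self.molecule
        elements = {s: parse_basis(self.basis_text, s) for s in set(mol.symbols)}
        return assign_shells(mol, elements)

    def ao_basis(self):
        return build_ao_basis(self.molecule, self.shells())

    def aux_basis(self) -> list[AuxiliaryFunction]:
        mol = self.molecule
        elements = {s: parse_aux_basis(self.aux_text, s) for s in set(mol.symbols)}
        return assign_aux_basis(mol, elements)


FIXTURE_NAMES = ("h2", "heh+", "lih", "h2o")


def generate_fixture(name: str, basis: str = "sto-3g") -> Fixture:
    """Return a self-consistent (geometry, basis, auxiliary set) triple.

    ``name``: one of h2, heh+, lih, h2o, or ``linear_alkane(n)``.
    ``basis``: "sto-3g" for all fixtures; "6-31g" additionally for h2/h2o.
    """
    basis_text = {"sto-3g": STO3G, "6-31g": G631}.get(basis.lower())
    if basis_text is None:
        raise ValueError(f"unknown fixture basis {basis!r}")
    lname = name.lower()
    if lname.startswith("linear_alkane"):
        try:
            n = int(lname.split("(")[1].rstrip(")"))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"bad alkane fixture name {name!r}") from exc
        return Fixture(lname, _alkane_xyz(n), 0, STO3G, AUX_SETS)
    if lname not in _GEOMETRIES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    xyz, charge = _GEOMETRIES[lname]
    return Fixture(lname, xyz, charge, basis_text, AUX_SETS)


def write_fixture_files(name: str, directory, basis: str = "sto-3g") -> dict[str, str]:
    """Emit the xyz / basis / auxiliary files for a fixture; returns the paths."""
    from pathlib import Path

    fx = generate_fixture(name, basis)
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    stem = fx.name.replace("(", "_").replace(")", "")
    paths = {
        "xyz": d / f"{stem}.xyz",
        "basis": d / f"{stem}.basis",
        "aux": d / f"{stem}.auxbasis",
    }
    paths["xyz"].write_text(fx.xyz)
    paths["basis"].write_text(fx.basis_text)
    paths["aux"].write_text(fx.aux_text)
    return {k: str(v) for k, v in paths.items()}
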