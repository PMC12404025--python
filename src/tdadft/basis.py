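"""Orbital and auxiliary basis sets.

Orbital basis functions are contracted *Cartesian* Gaussians; no spherical
transformation is applied, so for L >= 2 the function counts differ from
spherical-harmonic codes (6 d components, 10 f components, ...).

Auxiliary functions are primitive *Hermite* Gaussians

    Lambda_kbar(r; zeta, C) = (d/dC)^kbar exp(-zeta (r - C)^2),

the natural expansion set for variational Coulomb fitting: the interaction
of two Hermite distributions carries a (-1)^|kbar| phase that the integral
code applies explicitly.

Both sets are read from Gaussian94-style text blocks.  For an auxiliary set
a shell of letter X expands into all Hermite indices with |kbar| <= L(X)
("s" set: 1 function, "spd" set: 10 functions per exponent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .molecule import Molecule, ParseError

_SHELL_LETTERS = {"S": 0, "P": 1, "D": 2, "F": 3, "G": 4}
_LETTER_OF_L = {v: k for k, v in _SHELL_LETTERS.items()}


def double_factorial(n: int) -> int:
    if n <= 0:
        return 1
    out = 1
    while n > 0:
        out *= n
        n -= 2
    return out


@dataclass
class ContractedShell:
    """One contracted Cartesian shell: shared exponents, all components of L."""

    center: int  # atom index; -1 for an element template
    L: int
    exponents: np.ndarray
    coefficients: np.ndarray  # raw contraction coefficients from the file

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.L < 0:
            raise ValueError("negative angular momentum")
        if np.any(self.exponents <= 0):
            raise ValueError("non-positive primitive exponent")
        if self.exponents.shape != self.coefficients.shape:
            raise ValueError("exponent/coefficient length mismatch")

    @property
    def n_primitives(self) -> int:
        return len(self.exponents)

    def cartesian_components(self) -> list[tuple[int, int, int]]:
        L = self.L
        return [
            (lx, ly, lz)
            for lx in range(L, -1, -1)
            for ly in range(L - lx, -1, -1)
            for lz in [L - lx - ly]
        ]

    def at_center(self, center: int) -> "ContractedShell":
        return ContractedShell(center, self.L, self.exponents.copy(), self.coefficients.copy())


@dataclass(frozen=True)
class AuxiliaryFunction:
    """A single primitive Hermite Gaussian auxiliary function."""

    center: int
    exponent: float
    index: tuple[int, int, int]  # Hermite index kbar

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("auxiliary exponent must be positive")
        if any(k < 0 for k in self.index):
            raise ValueError("negative Hermite index")

    @property
    def total_index(self) -> int:
        return sum(self.index)


@dataclass
class BasisFunction:
    """One normalized contracted Cartesian AO (a single shell component)."""

    center: int
    origin: np.ndarray  # bohr
    lmn: tuple[int, int, int]
    exponents: np.ndarray
    coefficients: np.ndarray  # include all normalization factors

    @property
    def L(self) -> int:
        return sum(self.lmn)


def primitive_norm(zeta: float, lmn: tuple[int, int, int]) -> float:
    """Norm constant of a primitive Cartesian Gaussian x^l y^m z^n e^{-zeta r^2}."""
    l, m, n = lmn
    L = l + m + n
    num = (2.0 * zeta / math.pi) ** 0.75 * (4.0 * zeta) ** (L / 2.0)
    den = math.sqrt(
        double_factorial(2 * l - 1) * double_factorial(2 * m - 1) * double_factorial(2 * n - 1)
    )
    return num / den


def _contracted_self_overlap(exps, coefs, lmn) -> float:
    l, m, n = lmn
    L = l + m + n
    dfac = (
        double_factorial(2 * l - 1) * double_factorial(2 * m - 1) * double_factorial(2 * n - 1)
    )
    zsum = exps[:, None] + exps[None, :]
    s = (math.pi / zsum) ** 1.5 * dfac / (2.0 * zsum) ** L
    return float(np.einsum("k,l,kl->", coefs, coefs, s))


def normalized_basis_function(shell: ContractedShell, origin, lmn) -> BasisFunction:
    """Build one unit-normalized AO component from a contracted shell."""
    prim_norms = np.array([primitive_norm(z, lmn) for z in shell.exponents])
    coefs = shell.coefficients * prim_norms
    s = _contracted_self_overlap(shell.exponents, coefs, lmn)
    coefs = coefs / math.sqrt(s)
    return BasisFunction(
        center=shell.center,
        origin=np.asarray(origin, dtype=float),
        lmn=tuple(lmn),
        exponents=shell.exponents.copy(),
        coefficients=coefs,
    )


def build_ao_basis(molecule: Molecule, shells: list[ContractedShell]) -> list[BasisFunction]:
    """Expand shells (with assigned centers) into an ordered list of normalized AOs.

    Ordering: input shell order, then Cartesian components in descending
    lexicographic (lx, ly, lz).  Shell order follows atom order when shells
    come from :func:`assign_shells`, so permuting atoms permutes AOs
    consistently.
    """
    coords = molecule.coordinates
    aos = []
    for shell in shells:
        if shell.center < 0 or shell.center >= molecule.n_atoms:
            raise ValueError("shell has no valid center assignment")
        for lmn in shell.cartesian_components():
            aos.append(normalized_basis_function(shell, coords[shell.center], lmn))
    return aos


def assign_shells(
    molecule: Molecule, element_shells: dict[str, list[ContractedShell]]
) -> list[ContractedShell]:
    """Attach element shell templates to every atom of the molecule, in atom order."""
    shells = []
    for i, sym in enumerate(molecule.symbols):
        if sym not in element_shells:
            raise KeyError(f"no basis for element {sym}")
        shells.extend(tpl.at_center(i) for tpl in element_shells[sym])
    return shells


# ---------------------------------------------------------------------------
# Gaussian94 text parsing


def _element_blocks(text: str) -> dict[str, list[list[str]]]:
    blocks: dict[str, list[list[str]]] = {}
    current: list[str] = []
    for raw in text.splitlines():
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.startswith("****"):
            current = []
            continue
        current.append(line)
        if len(current) == 1:
            parts = line.split()
            sym = parts[0].capitalize()
            blocks.setdefault(sym, []).append(current)
    return blocks


def _parse_element_block(lines: list[str], element: str) -> list[ContractedShell]:
    shells: list[ContractedShell] = []
    i = 1  # skip "El 0" header
    while i < len(lines):
        header = lines[i].split()
        letter = header[0].upper()
        if letter != "SP" and letter not in _SHELL_LETTERS:
            raise ParseError(f"{element}: unknown shell type {header[0]!r}")
        try:
            nprim = int(header[1])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{element}: bad shell header {lines[i]!r}") from exc
        scale = float(header[2]) if len(header) > 2 else 1.0
        rows = lines[i + 1 : i + 1 + nprim]
        if len(rows) < nprim:
            raise ParseError(f"{element}: truncated shell block {lines[i]!r}")
        try:
            table = np.array(
                [[float(x.replace("D", "E").replace("d", "e")) for x in r.split()] for r in rows]
            )
        except ValueError as exc:
            raise ParseError(f"{element}: non-numeric primitive entry in shell {lines[i]!r}") from exc
        exps = table[:, 0] * scale**2
        if letter == "SP":
            if table.shape[1] < 3:
                raise ParseError(f"{element}: SP shell needs two coefficient columns")
            shells.append(ContractedShell(-1, 0, exps, table[:, 1]))
            shells.append(ContractedShell(-1, 1, exps, table[:, 2]))
        else:
            shells.append(ContractedShell(-1, _SHELL_LETTERS[letter], exps, table[:, 1]))
        i += 1 + nprim
    return shells


def parse_basis(text: str, element: str) -> list[ContractedShell]:
    """Parse a Gaussian94 basis block for ``element``; SP shells split into S and P."""
    element = element.capitalize()
    blocks = _element_blocks(text)
    if element not in blocks:
        raise ParseError(f"element {element} not found in basis file")
    return _parse_element_block(blocks[element][0], element)


def hermite_indices(max_l: int) -> list[tuple[int, int, int]]:
    """All Hermite indices with |kbar| <= max_l, in ascending lexicographic order."""
    idx = [
        (kx, ky, kz)
        for kx in range(max_l + 1)
        for ky in range(max_l + 1 - kx)
        for kz in range(max_l + 1 - kx - ky)
    ]
    return sorted(idx)


def parse_aux_basis(text: str, element: str) -> list[AuxiliaryFunction]:
    """Parse an auxiliary set block: every primitive becomes an uncontracted
    Hermite function set; shell letter X gives all |kbar| <= L(X).

    Returned templates carry center -1; attach with :func:`assign_aux_basis`.
    """
    element = element.capitalize()
    blocks = _element_blocks(text)
    if element not in blocks:
        raise ParseError(f"element {element} not found in auxiliary basis file")
    shells = _parse_element_block(blocks[element][0], element)
    funcs: list[AuxiliaryFunction] = []
    for shell in shells:
        if shell.n_primitives != 1:
            raise ParseError(
                f"{element}: auxiliary shells must be primitive "
                f"(contraction depth {shell.n_primitives} found)"
            )
        zeta = float(shell.exponents[0])
        for kbar in hermite_indices(shell.L):
            funcs.append(AuxiliaryFunction(-1, zeta, kbar))
    return _sort_aux(funcs)


def _sort_aux(funcs: list[AuxiliaryFunction]) -> list[AuxiliaryFunction]:
    out = sorted(funcs, key=lambda f: (f.center, -f.exponent, f.index))
    seen = set()
    for f in out:
        key = (f.center, f.exponent, f.index)
        if key in seen:
            raise ValueError(f"duplicate auxiliary function {key}")
        seen.add(key)
    return out


def assign_aux_basis(
    molecule: Molecule, element_aux: dict[str, list[AuxiliaryFunction]]
) -> list[AuxiliaryFunction]:
    """Attach auxiliary templates to atoms; deterministic global ordering
    (center, exponent descending, lexicographic kbar)."""
    funcs: list[AuxiliaryFunction] = []
    for i, sym in enumerate(molecule.symbols):
        if sym not in element_aux:
            raise KeyError(f"no auxiliary basis for element {sym}")
        for tpl in element_aux[sym]:
            funcs.append(AuxiliaryFunction(i, tpl.exponent, tpl.index))
    return _sort_aux(funcs)


# ---------------------------------------------------------------------------
# Serialization (round-trip partners of the parsers)


def write_basis(element: str, shells: list[ContractedShell]) -> str:
    lines = ["****", f"{element} 0"]
    for sh in shells:
        lines.append(f"{_LETTER_OF_L[sh.L]}   {sh.n_primitives}   1.00")
        for z, d in zip(sh.exponents, sh.coefficients):
            lines.append(f"  {z: .10E}  {d: .10E}")
    lines.append("****")
    return "\n".join(lines) + "\n"


def write_aux_basis(element: str, funcs: list[AuxiliaryFunction]) -> str:
    """Write an auxiliary set grouped back into (exponent, max-L) blocks."""
    by_exp: dict[float, int] = {}
    for f in funcs:
        by_exp[f.exponent] = max(by_exp.get(f.exponent, 0), f.total_index)
    lines = ["****", f"{element} 0"]
    for zeta in sorted(by_exp, reverse=True):
        lines.append(f"{_LETTER_OF_L[by_exp[zeta]]}   1   1.00")
        lines.append(f"  {zeta: .10E}   1.0000000000E+00")
    lines.append("****")
    return "\n".join(lines) + "\n"
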