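"""Physical constants and per-element data used throughout the package.

Internal unit system is atomic units (bohr, hartree) everywhere past the
input parsers.
"""

BOHR_PER_ANGSTROM = 1.8897261254578281
HARTREE_EV = 27.211386245988

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

SYMBOL_TO_Z = {sym: z for z, sym in enumerate(ELEMENTS) if z > 0}
Z_TO_SYMBOL = {z: sym for sym, z in SYMBOL_TO_Z.items()}

# Bragg-Slater covalent radii (Angstrom); used only to shape the radial
# quadrature mapping, so modest accuracy is fine.
BRAGG_RADII_ANGSTROM = {
    "H": 0.35, "He": 0.28, "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70,
    "N": 0.65, "O": 0.60, "F": 0.50, "Ne": 0.45, "Na": 1.80, "Mg": 1.50,
    "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00, "Cl": 1.00, "Ar": 0.95,
}


def bragg_radius_bohr(symbol: str) -> float:
    return BRAGG_RADII_ANGSTROM.get(symbol, 1.0) * BOHR_PER_ANGSTROM
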