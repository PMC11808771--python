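"""Physical constants and element data (Hartree atomic units internally)."""

from __future__ import annotations

# 1 angstrom in bohr (CODATA)
BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

# Boltzmann constant in hartree/kelvin
KB_HARTREE = 3.166811563e-6

# atomic mass unit (dalton) in electron masses
AMU_TO_ME = 1822.888486

# elements H..Ar
ELEMENTS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(ELEMENTS)}
Z_TO_SYMBOL = {i + 1: s for i, s in enumerate(ELEMENTS)}

# standard atomic weights (dalton), H..Ar
ATOMIC_WEIGHTS = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831,
    "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998403163, "Ne": 20.1797, "Na": 22.98976928,
    "Mg": 24.305, "Al": 26.9815385, "Si": 28.085, "P": 30.973761998,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
}


def normalize_symbol(symbol: str) -> str:
    """Case-normalize an element symbol ('h' -> 'H', 'CL' -> 'Cl')."""
    s = symbol.strip()
    if not s:
        raise ValueError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def mass_au(symbol: str) -> float:
    """Atomic mass in electron-mass units (a.u.)."""
    sym = normalize_symbol(symbol)
    try:
        return ATOMIC_WEIGHTS[sym] * AMU_TO_ME
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {sym!r}") from None
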