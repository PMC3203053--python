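"""Per-element van der Waals radii and element inference from PDB atom names.

The radii are the Bondi set commonly used for surface-area and pore
calculations.  Ions use element (not charge-state) radii.  Elements absent
from the table fall back to ``DEFAULT_VDW_RADIUS`` (carbon-like, 1.70 A).
"""

from __future__ import annotations

# Bondi (1964) van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Na": 2.27,
    "K": 2.75,
    "Mg": 1.73,
    "Ca": 2.31,
    "Zn": 1.39,
}

DEFAULT_VDW_RADIUS = 1.70

# Residue names recognised as water / monoatomic ions in common force fields.
WATER_RES_NAMES = {"HOH", "WAT", "TIP3", "TIP4", "SPC", "SOL", "H2O"}
ION_RES_NAMES = {"NA", "SOD", "CL", "CLA", "K", "POT", "MG", "CA", "ZN", "CAL"}

_ION_ELEMENTS = {"NA": "Na", "SOD": "Na", "CL": "Cl", "CLA": "Cl",
                 "K": "K", "POT": "K", "MG": "Mg", "CA": "Ca",
                 "ZN": "Zn", "CAL": "Ca"}

_TWO_LETTER = {"NA", "CL", "MG", "ZN", "BR", "FE", "CA", "MN", "CU", "SE"}


def infer_element(atom_name: str, res_name: str) -> str:
    """Infer the chemical element from a PDB atom name.

    Monoatomic-ion residues map through their residue name; otherwise the
    first alphabetic character of the atom name is used, which is the PDB
    convention for protein and water atoms (CA -> C, OE1 -> O, ...).
    """
    res = res_name.strip().upper()
    if res in _ION_ELEMENTS:
        return _ION_ELEMENTS[res]
    name = atom_name.strip().upper()
    if name in _TWO_LETTER and res == name:
        return name.capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def vdw_radius(element: str) -> float:
    """Return the bundled vdW radius for ``element`` (default 1.70 A)."""
    key = element.strip()
    if len(key) > 1:
        key = key[0].upper() + key[1:].lower()
    else:
        key = key.upper()
    return VDW_RADII.get(key, DEFAULT_VDW_RADIUS)
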