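"""Physical constants and element data tables.

All public interfaces of :mod:`pcmresp` take coordinates in Angstrom (Å),
charges in elementary charge units (e), and polarizabilities in Å³.
Electrostatics are evaluated internally in Hartree atomic units
(Bohr, e, Hartree/e); the conversion constants below are the single
source of truth for the unit system.
"""

from __future__ import annotations

#: 1 Å expressed in Bohr (CODATA).
ANGSTROM_TO_BOHR: float = 1.889726124565062

#: 1 Bohr expressed in Å.
BOHR_TO_ANGSTROM: float = 1.0 / ANGSTROM_TO_BOHR

#: 1 e·Å expressed in Debye.
EANGSTROM_TO_DEBYE: float = 4.803204

#: Bondi van der Waals radii in Å (A. Bondi, J. Phys. Chem. 68, 441 (1964)),
#: used by the synthetic grid/surface generators.  ``X`` is the fallback
#: radius for elements not in the table.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "Br": 1.85,
    "I": 1.98,
    "X": 1.50,
}


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Look up a van der Waals radius (Å), falling back to the generic entry."""
    tab = BONDI_VDW_RADII if table is None else table
    return tab.get(element, tab.get("X", 1.50))
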