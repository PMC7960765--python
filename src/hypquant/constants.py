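"""Physical constants used throughout the package.

All masses are monoisotopic and given in Da. Isotope masses and natural
abundances are loaded from a single machine-readable table shipped with the
package (``data/isotopes.csv``, IUPAC representative values), so that every
mass and envelope computation draws on one authority.
"""

from __future__ import annotations

import csv
from importlib import resources

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "AMMONIA_MASS",
    "C13_C12_DELTA",
    "OXIDATION_MASS",
    "CARBAMIDOMETHYL_MASS",
    "ATOMIC_MASS",
    "ISOTOPES",
    "RESIDUE_COMPOSITIONS",
    "isotope_table",
]

PROTON_MASS = 1.00727646688

# residue (i.e. water-free) elemental compositions of the 20 amino acids
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def isotope_table() -> list[dict]:
    """Return the shipped isotope table as a list of row dicts.

    Columns: ``element`` (symbol), ``mass_number`` (int), ``mass`` (Da),
    ``abundance`` (unit fraction). This is the machine-readable form of the
    constants table; :data:`ISOTOPES` and :data:`ATOMIC_MASS` are derived
    from it at import time.
    """
    text = resources.files("hypquant.data").joinpath("isotopes.csv").read_text()
    rows = []
    for row in csv.DictReader(text.splitlines()):
        rows.append(
            {
                "element": row["element"],
                "mass_number": int(row["mass_number"]),
                "mass": float(row["mass"]),
                "abundance": float(row["abundance"]),
            }
        )
    return rows


def _build_tables() -> tuple[dict[str, list[tuple[int, float, float]]], dict[str, float]]:
    isotopes: dict[str, list[tuple[int, float, float]]] = {}
    for row in isotope_table():
        isotopes.setdefault(row["element"], []).append(
            (row["mass_number"], row["mass"], row["abundance"])
        )
    atomic: dict[str, float] = {}
    for element, rows in isotopes.items():
        rows.sort()
        base = rows[0][0]
        # re-key on nominal offset from the lightest isotope
        isotopes[element] = [(n - base, m, a) for n, m, a in rows]
        atomic[element] = rows[0][1]
    return isotopes, atomic


#: per element: list of (nominal offset, isotope mass, abundance), offset 0 first
ISOTOPES, ATOMIC_MASS = _build_tables()

WATER_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
AMMONIA_MASS = ATOMIC_MASS["N"] + 3 * ATOMIC_MASS["H"]  # [M+NH4]+ vs [M+H]+ shift
C13_C12_DELTA = ISOTOPES["C"][1][1] - ISOTOPES["C"][0][1]  # aggregated peak spacing
OXIDATION_MASS = ATOMIC_MASS["O"]
CARBAMIDOMETHYL_MASS = (
    2 * ATOMIC_MASS["C"] + 3 * ATOMIC_MASS["H"] + ATOMIC_MASS["N"] + ATOMIC_MASS["O"]
)
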