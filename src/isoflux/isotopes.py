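"""Natural-abundance isotope table used to build correction matrices.

Abundances are the standard terrestrial values (IUPAC representative
compositions), expressed per element as ``(mass shift, probability)`` pairs
where the mass shift is the number of extra neutrons relative to the lightest
stable isotope.  The table is versioned so that corrections performed with a
given release can be reproduced later even if the defaults are revised.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

IsotopeTable = Dict[str, List[Tuple[int, float]]]

#: Version tag recorded in run manifests alongside corrected data.
NATURAL_ABUNDANCE_VERSION = "2026.1"

#: Default natural-abundance table.  Each entry lists (mass shift, abundance);
#: abundances per element sum to 1.
NATURAL_ABUNDANCE: IsotopeTable = {
    "C": [(0, 0.9893), (1, 0.0107)],
    "H": [(0, 0.999885), (1, 0.000115)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "Si": [(0, 0.922296), (1, 0.046832), (2, 0.030872)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
    "P": [(0, 1.0)],
}


def validate_isotope_table(table: IsotopeTable, tol: float = 1e-9) -> None:
    """Check that every element's abundances are probabilities summing to 1."""
    for element, isotopes in table.items():
        total = 0.0
        for shift, abundance in isotopes:
            if shift < 0 or not isinstance(shift, int):
                raise ValueError(f"{element}: mass shift must be a non-negative integer")
            if not 0.0 <= abundance <= 1.0:
                raise ValueError(f"{element}: abundance {abundance} outside [0, 1]")
            total += abundance
        if abs(total - 1.0) > tol:
            raise ValueError(f"{element}: abundances sum to {total}, expected 1 +/- {tol}")


validate_isotope_table(NATURAL_ABUNDANCE)
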