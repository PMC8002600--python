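"""Theoretical protein masses from sequence.

Biotyping assigns intact-cell MALDI peaks to proteins by comparing the
measured m/z (singly protonated, [M+H]+) with theoretical masses computed
from the proteome sequence.  Two mass scales matter:

* **average** — isotope-abundance-weighted atomic weights; this is the
  scale on which peaks above ~1 kDa are matched, because an unresolved
  isotope envelope centroids near the average mass;
* **monoisotopic** — lightest-isotope masses, relevant only for small,
  isotopically resolved species.

Residue masses are derived at import time from elemental compositions and
a single table of atomic masses, so the two scales cannot drift
independently.  A peptide chain of residues R1..Rn has mass
``sum(residue_mass) + mass(H2O)`` (the condensation water restored at the
termini).  No post-translational modifications are applied; the mass is
that of the full-length deposited chain.  Optionally the N-terminal
Met-excised variant can be emitted as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "MassPair",
    "AVERAGE_ATOMIC_MASS",
    "MONOISOTOPIC_ATOMIC_MASS",
    "RESIDUE_FORMULA",
    "WATER",
    "PROTON_MASS",
    "H_ATOMIC_WEIGHT",
    "protein_mass",
    "protonated_mass",
    "composition_of",
]

Scale = Literal["monoisotopic", "average"]

# standard isotope masses (Da) and abundances per element; the lightest
# isotope is listed first.  Both mass scales derive from this one table:
# monoisotopic = lightest-isotope mass, average = abundance-weighted mean
# (the IUPAC standard atomic weight).
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.0141017778, 0.000115)),
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "N": ((14.0030740048, 0.99636), (15.0001088982, 0.00364)),
    "O": ((15.99491461956, 0.99757), (16.99913170, 0.00038), (17.9991610, 0.00205)),
    "S": ((31.97207100, 0.9499), (32.97145876, 0.0075), (33.96786690, 0.0425), (35.96708076, 0.0001)),
}

AVERAGE_ATOMIC_MASS = {
    el: sum(m * a for m, a in isos) / sum(a for _, a in isos) for el, isos in ISOTOPES.items()
}
MONOISOTOPIC_ATOMIC_MASS = {el: isos[0][0] for el, isos in ISOTOPES.items()}

#: mass of the proton, used for [M+H]+ on the monoisotopic scale
PROTON_MASS = 1.007276466
#: H atomic weight, used for [M+H]+ on the average scale (the electron
#: mass is immaterial at the Da-level tolerances of biotyping, but the
#: convention is fixed here)
H_ATOMIC_WEIGHT = AVERAGE_ATOMIC_MASS["H"]

# elemental composition of amino-acid *residues* (chain units, water removed)
RESIDUE_FORMULA: dict[str, dict[str, int]] = {
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


@dataclass(frozen=True)
class MassPair:
    """Monoisotopic and average molecular mass of one molecule, in Da."""

    monoisotopic: float
    average: float


def _mass_of_formula(formula: dict[str, int], table: dict[str, float]) -> float:
    return sum(n * table[el] for el, n in formula.items())


# residue mass tables, precomputed once from the elemental compositions
_RESIDUE_MASS: dict[str, dict[str, MassPair]] = {
    aa: MassPair(
        monoisotopic=_mass_of_formula(f, MONOISOTOPIC_ATOMIC_MASS),
        average=_mass_of_formula(f, AVERAGE_ATOMIC_MASS),
    )
    for aa, f in RESIDUE_FORMULA.items()
}

WATER = MassPair(
    monoisotopic=_mass_of_formula({"H": 2, "O": 1}, MONOISOTOPIC_ATOMIC_MASS),
    average=_mass_of_formula({"H": 2, "O": 1}, AVERAGE_ATOMIC_MASS),
)


def composition_of(sequence: str) -> dict[str, int]:
    """Molecular formula (element -> count) of the intact peptide chain,
    including the terminal water."""
    counts = {"H": 2, "O": 1}
    for pos, aa in enumerate(sequence):
        formula = RESIDUE_FORMULA.get(aa)
        if formula is None:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
        for el, n in formula.items():
            counts[el] = counts.get(el, 0) + n
    return counts


def protein_mass(sequence: str) -> MassPair:
    """Molecular mass of an unmodified peptide/protein chain.

    Returns both scales.  Raises ``ValueError`` on an empty sequence or on
    any residue outside the 20-letter alphabet (the error names the
    offending character and its 0-based position).
    """
    if not sequence:
        raise ValueError("empty sequence has no defined mass")
    mono = WATER.monoisotopic
    avg = WATER.average
    for pos, aa in enumerate(sequence):
        pair = _RESIDUE_MASS.get(aa)
        if pair is None:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
        mono += pair.monoisotopic
        avg += pair.average
    return MassPair(monoisotopic=mono, average=avg)


def protonated_mass(mass: float, scale: Scale = "average") -> float:
    """m/z of the singly protonated ion [M+H]+.

    On the average scale the H atomic weight is added; on the
    monoisotopic scale the proton mass.
    """
    if not mass > 0:
        raise ValueError(f"mass must be > 0, got {mass}")
    if scale == "average":
        return mass + H_ATOMIC_WEIGHT
    if scale == "monoisotopic":
        return mass + PROTON_MASS
    raise ValueError(f"unknown mass scale {scale!r}")
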