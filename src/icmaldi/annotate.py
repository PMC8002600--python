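"""Peak annotation by theoretical protein mass.

Intact-cell MALDI peaks (assumed singly charged) are assigned to proteome
entries whose theoretical mass — by default the average-scale [M+H]+ —
lies within a tolerance window of the measured m/z (default ±2 Da).  The
assignment is deliberately many-to-many: one peak can fall within the
window of several proteins and one protein can explain several peaks, so
*all* candidates are reported, ranked by |Δ|.  Peaks matching more than a
handful of proteins carry a low-specificity flag; mass-only assignment
cannot substitute for sequencing and should be read as a hypothesis.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .mass_calc import protein_mass, protonated_mass
from .spectra_io import ProteinRecord

__all__ = [
    "IndexEntry",
    "MassIndex",
    "Annotation",
    "build_index",
    "annotate_peaks",
    "annotations_to_frame",
]

logger = logging.getLogger(__name__)

#: more candidates than this within the window -> "low-specificity" flag
LOW_SPECIFICITY_THRESHOLD = 5

Scale = Literal["average", "monoisotopic"]
Adduct = Literal["neutral", "MH"]


@dataclass(frozen=True)
class IndexEntry:
    mass: float
    accession: str
    description: str


@dataclass(frozen=True)
class MassIndex:
    """Theoretical masses of proteome entries, sorted ascending, on one
    (scale, adduct) convention."""

    entries: tuple[IndexEntry, ...]
    scale: Scale
    adduct: Adduct

    def __post_init__(self) -> None:
        masses = [e.mass for e in self.entries]
        if any(b < a for a, b in zip(masses, masses[1:])):
            raise ValueError("index entries must be sorted ascending by mass")

    def __len__(self) -> int:
        return len(self.entries)

    def window(self, mz: float, tol: float) -> list[IndexEntry]:
        """All entries with |mass - mz| <= tol (binary search)."""
        masses = [e.mass for e in self.entries]
        lo = bisect.bisect_left(masses, mz - tol)
        hi = bisect.bisect_right(masses, mz + tol)
        return list(self.entries[lo:hi])


@dataclass(frozen=True)
class Annotation:
    """One candidate assignment of a peak to a protein."""

    peak_mz: float
    accession: str
    description: str
    theoretical_mass: float
    delta: float  # peak_mz - theoretical_mass
    rank: int  # 1 = closest candidate for this peak
    n_candidates: int

    @property
    def low_specificity(self) -> bool:
        return self.n_candidates > LOW_SPECIFICITY_THRESHOLD

    @property
    def unassigned(self) -> bool:
        return self.accession == ""


def unassigned_marker(mz: float) -> Annotation:
    """Explicit marker emitted for peaks with no candidate in the window."""
    return Annotation(
        peak_mz=mz, accession="", description="unassigned", theoretical_mass=float("nan"),
        delta=float("nan"), rank=0, n_candidates=0,
    )


def build_index(
    records: Sequence[ProteinRecord],
    scale: Scale = "average",
    adduct: Adduct = "MH",
    met_excision: bool = False,
) -> MassIndex:
    """Compute the theoretical mass of every record and sort.

    Records with residues outside the 20-letter alphabet have no defined
    mass; they are skipped and their count logged.  Raises ``ValueError``
    if no record is computable.  With ``met_excision`` an additional
    entry is emitted for every Met-initiated chain with the N-terminal
    methionine removed (a common co-translational processing of the
    mature protein); off by default.
    """

    def entry_mass(sequence: str) -> float:
        pair = protein_mass(sequence)
        mass = pair.average if scale == "average" else pair.monoisotopic
        return protonated_mass(mass, scale) if adduct == "MH" else mass

    entries = []
    skipped = 0
    for rec in records:
        if not rec.mass_computable:
            skipped += 1
            continue
        entries.append(
            IndexEntry(mass=entry_mass(rec.sequence), accession=rec.accession,
                       description=rec.description)
        )
        if met_excision and rec.sequence.startswith("M") and len(rec.sequence) > 1:
            entries.append(
                IndexEntry(
                    mass=entry_mass(rec.sequence[1:]),
                    accession=rec.accession,
                    description=(rec.description + " (Met-excised)").strip(),
                )
            )
    if skipped:
        logger.warning("skipped %d record(s) with non-computable mass", skipped)
    if not entries:
        raise ValueError("no records with computable mass")
    entries.sort(key=lambda e: (e.mass, e.accession))
    return MassIndex(entries=tuple(entries), scale=scale, adduct=adduct)


def annotate_peaks(peaks, index: MassIndex, tol: float = 2.0) -> list[Annotation]:
    """Annotate every peak of a PeakList or ConsensusProfile.

    For each peak all index entries within ±``tol`` are returned as
    :class:`Annotation` rows ranked by |Δ| (rank 1 = closest; ties broken
    by accession).  Peaks without any candidate yield a single
    ``unassigned`` marker row.
    """
    if not tol > 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if len(index) == 0:
        raise ValueError("empty mass index")
    out: list[Annotation] = []
    for mz in peaks.mz:
        cands = index.window(mz, tol)
        if not cands:
            out.append(unassigned_marker(mz))
            continue
        cands.sort(key=lambda e: (abs(mz - e.mass), e.accession))
        n = len(cands)
        for rank, e in enumerate(cands, start=1):
            out.append(
                Annotation(
                    peak_mz=mz, accession=e.accession, description=e.description,
                    theoretical_mass=e.mass, delta=mz - e.mass, rank=rank, n_candidates=n,
                )
            )
    return out


def annotations_to_frame(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Flat table ready for CSV export (byte-stable for fixed input)."""
    return pd.DataFrame(
        [
            {
                "peak_mz": round(a.peak_mz, 6),
                "accession": a.accession,
                "description": a.description,
                "theoretical_mass": round(a.theoretical_mass, 6),
                "delta": round(a.delta, 6),
                "rank": a.rank,
                "n_candidates": a.n_candidates,
                "low_specificity": a.low_specificity,
            }
            for a in annotations
        ]
    )
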