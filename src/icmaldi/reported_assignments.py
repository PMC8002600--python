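"""Reported intact-cell peak assignments for *Synechococcus* sp. UPOC S4.

Differential peaks observed in intact-cell MALDI-TOF spectra of this
cyanobacterium after inhibitor/antibiotic treatments have been assigned
to UniProtKB entries of *Synechococcus* reference proteomes by average
[M+H]+ mass within ±2 Da.  The table below records those reported
(measured m/z, accession) pairs so that the assignment can be re-verified
against any UniProt-derived FASTA of the corresponding proteomes:
:func:`check_reported_assignments` recomputes the theoretical masses with
this package's mass engine and checks each pair against the window.

The protein *sequences* are not bundled — they must come from UniProtKB
(the entry names below are standard UniProtKB identifiers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotate import build_index
from .spectra_io import ProteinRecord

__all__ = ["ReportedAssignment", "REPORTED_ASSIGNMENTS", "check_reported_assignments"]


@dataclass(frozen=True)
class ReportedAssignment:
    mz: float
    accession: str
    description: str


#: (measured m/z, UniProtKB entry name) pairs reported for treated
#: Synechococcus sp. UPOC S4 cultures; annotated entries only.
REPORTED_ASSIGNMENTS: tuple[ReportedAssignment, ...] = (
    ReportedAssignment(3443.74, "PSBT_SYNR3", "photosystem II reaction center protein T"),
    ReportedAssignment(4361.43, "Q05XI0_9SYNE", "cytochrome b6-f complex subunit 7"),
    ReportedAssignment(6370.62, "Q05WR3_9SYNE", "possible high light inducible protein"),
    ReportedAssignment(8677.30, "K9RU07_SYNP3", "ferredoxin"),
    ReportedAssignment(9067.28, "Q0IBQ1_SYNS3", "Nif11 domain-containing protein"),
    ReportedAssignment(9128.53, "NDHO_SYNPW", "NAD(P)H-quinone oxidoreductase subunit O"),
    ReportedAssignment(12576.10, "K9SR95_9SYNE", "photosystem II reaction center Psb28 protein"),
    ReportedAssignment(4429.12, "A0A1J0PAG3_9SYNE", "photosystem II reaction center protein I"),
    ReportedAssignment(4858.50, "Q3AY61_SYNS9", "possible high light inducible protein"),
    ReportedAssignment(6680.04, "K9SUE7_9SYNE", "copper chaperone"),
    ReportedAssignment(7084.66, "B1XKL5_SYNP2", "chaperone protein domain protein"),
    ReportedAssignment(7193.64, "K9RSN2_SYNP3", "photosystem II reaction center protein K"),
    ReportedAssignment(9142.47, "NDHL_SYNPW", "NAD(P)H-quinone oxidoreductase subunit L"),
    ReportedAssignment(5224.27, "PSBK_SYNPW", "photosystem II reaction center protein K"),
    ReportedAssignment(6454.65, "A5GI63_SYNPW", "redox enzyme"),
    ReportedAssignment(8724.39, "A0A2P7EFI8_9SYNE", "translocase"),
    ReportedAssignment(8764.02, "Q3AYN7_SYNS9", "high light inducible protein"),
    ReportedAssignment(8764.02, "Q05TX2_9SYNE", "antitoxin"),
    ReportedAssignment(3594.45, "PETN_SYNPW", "cytochrome b6-f complex subunit 8"),
    ReportedAssignment(3812.22, "PSBM_SYNR3", "photosystem II reaction center protein M"),
    ReportedAssignment(7963.73, "NDHO_SYNJB", "NAD(P)H-quinone oxidoreductase subunit O"),
    ReportedAssignment(7663.31, "K9RVM2_SYNP3", "NAD(P)H dehydrogenase subunit S"),
    ReportedAssignment(4432.62, "PSAJ_SYNR3", "photosystem I reaction center subunit IX"),
    ReportedAssignment(4505.66, "PSBL_SYNS3", "photosystem II reaction center protein L"),
    ReportedAssignment(6408.23, "K9SVD1_9SYNE", "Sec-independent protein translocase protein TatA"),
    ReportedAssignment(8714.28, "A5GPD7_SYNPW", "protein translocase subunit SecE"),
    ReportedAssignment(9013.85, "Q05TX6_9SYNE", "antitoxin"),
    ReportedAssignment(4043.25, "PSBJ_SYNJB", "photosystem II reaction center protein J"),
    ReportedAssignment(9146.22, "Q3AVY9_SYNS9", "glutaredoxin"),
    ReportedAssignment(9106.97, "PSBE_SYNS3", "cytochrome b559 subunit alpha"),
)


def check_reported_assignments(
    records: Sequence[ProteinRecord],
    tol: float = 2.0,
    assignments: Sequence[ReportedAssignment] = REPORTED_ASSIGNMENTS,
) -> pd.DataFrame:
    """Verify reported (m/z, accession) pairs against a proteome FASTA.

    For every assignment whose accession occurs in ``records``, the
    average [M+H]+ mass is computed and compared with the reported m/z.
    Returns a table with columns mz, accession, found, theoretical_mass,
    delta, within_tol.  Assignments whose accession is absent from the
    supplied records are marked ``found=False``.
    """
    index = build_index(records, scale="average", adduct="MH")
    by_acc = {e.accession: e for e in index.entries}
    rows = []
    for a in assignments:
        entry = by_acc.get(a.accession)
        if entry is None:
            rows.append((a.mz, a.accession, False, float("nan"), float("nan"), False))
        else:
            delta = a.mz - entry.mass
            rows.append((a.mz, a.accession, True, entry.mass, delta, abs(delta) <= tol))
    return pd.DataFrame(
        rows, columns=["mz", "accession", "found", "theoretical_mass", "delta", "within_tol"]
    )
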