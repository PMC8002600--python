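"""Reading and writing of peak lists and protein FASTA files.

Peak lists are the already-picked (m/z, intensity) pairs exported by
instrument software from profile spectra of intact microbial cells.  Two
dialects are accepted: plain two-column text (tab or whitespace separated,
the usual flexAnalysis-style TXT export) and CSV with an ``mz,intensity``
header.  Proteomes come as standard multi-record FASTA; UniProt
``db|ACC|NAME description`` headers are recognised.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "Peak",
    "SampleMeta",
    "PeakList",
    "ProteinRecord",
    "PeakListParseError",
    "read_peaklist",
    "write_peaklist",
    "read_fasta",
    "write_fasta",
]

#: residues with defined elemental composition; anything else is flagged
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class PeakListParseError(ValueError):
    """Raised when a peak-list file cannot be parsed."""


@dataclass(frozen=True, order=True)
class Peak:
    """A single picked peak: m/z in Da (singly-charged assumption) and
    intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class SampleMeta:
    """Sample metadata carried alongside a spectrum or profile."""

    treatment: str = ""
    concentration_uM: float = 0.0
    time_days: float = 0.0
    replicate: int = 0
    is_control: bool = False

    def condition_key(self) -> tuple[str, float, float]:
        return (self.treatment, self.concentration_uM, self.time_days)


@dataclass(frozen=True)
class PeakList:
    """One spectrum's peaks, strictly sorted by ascending m/z."""

    spectrum_id: str
    peaks: tuple[Peak, ...]
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        if not self.spectrum_id:
            raise ValueError("spectrum_id must be non-empty")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peaks must be strictly sorted by m/z with no duplicates")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    @property
    def intensity(self) -> tuple[float, ...]:
        return tuple(p.intensity for p in self.peaks)

    def with_meta(self, **kwargs) -> "PeakList":
        return replace(self, meta=replace(self.meta, **kwargs))


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA record.

    ``mass_computable`` is False when the sequence contains residues
    outside the 20-letter alphabet (B, Z, X, U, O, ...); mass operations
    skip such records.
    """

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession!r} has an empty sequence")

    @property
    def mass_computable(self) -> bool:
        return set(self.sequence) <= STANDARD_AA


def merge_duplicate_mz(rows: Iterable[tuple[float, float]]) -> list[Peak]:
    """Sort rows by m/z and merge exact-duplicate m/z values by summing
    intensity (preserves total ion signal)."""
    acc: dict[float, float] = {}
    for mz, inten in rows:
        acc[mz] = acc.get(mz, 0.0) + inten
    return [Peak(mz, acc[mz]) for mz in sorted(acc)]


def _parse_two_column(text: str, path: str) -> list[tuple[float, float]]:
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PeakListParseError(
                f"{path}:{lineno}: expected two columns, got {len(parts)}: {raw!r}"
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise PeakListParseError(f"{path}:{lineno}: non-numeric value in {raw!r}") from exc
    return rows


def _parse_csv(text: str, path: str) -> list[tuple[float, float]]:
    reader = csv.reader(io.StringIO(text))
    rows = []
    for lineno, parts in enumerate(reader, start=1):
        if not parts or (parts[0].strip().startswith("#")):
            continue
        if lineno == 1 and parts[0].strip().lower() in {"mz", "m/z"}:
            continue  # header
        if len(parts) < 2:
            raise PeakListParseError(f"{path}:{lineno}: expected mz,intensity columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise PeakListParseError(f"{path}:{lineno}: non-numeric value {parts!r}") from exc
    return rows


def read_peaklist(
    path: str | Path,
    dialect: str = "two-column-text",
    spectrum_id: str | None = None,
    meta: SampleMeta | None = None,
) -> PeakList:
    """Read a peak list from ``path``.

    Parameters
    ----------
    path
        Input file.  Comment lines (``#``) and blank lines are skipped.
    dialect
        ``"two-column-text"`` (default; whitespace- or tab-separated) or
        ``"csv"`` (``mz,intensity`` header accepted).
    spectrum_id
        Defaults to the file stem.
    meta
        Optional sample metadata to attach.

    Duplicate m/z rows are merged by summing their intensities.  Raises
    :class:`PeakListParseError` on malformed lines (with line number) and
    on files containing no peaks.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "two-column-text":
        rows = _parse_two_column(text, str(path))
    elif dialect == "csv":
        rows = _parse_csv(text, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not rows:
        raise PeakListParseError(f"{path}: no peaks found (empty input)")
    return PeakList(
        spectrum_id=spectrum_id or path.stem,
        peaks=tuple(merge_duplicate_mz(rows)),
        meta=meta or SampleMeta(),
    )


def write_peaklist(peaklist: PeakList, path: str | Path, dialect: str = "two-column-text") -> Path:
    """Write a peak list as two-column text (or CSV with header)."""
    path = Path(path)
    if dialect == "two-column-text":
        lines = [f"{p.mz:.6f}\t{p.intensity:.6f}" for p in peaklist]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "csv":
        lines = ["mz,intensity"] + [f"{p.mz:.6f},{p.intensity:.6f}" for p in peaklist]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _split_header(header: str) -> tuple[str, str]:
    """UniProt 'db|ACC|NAME desc' headers -> (NAME, desc); plain headers
    are kept verbatim as the accession."""
    first, _, desc = header.partition(" ")
    parts = first.split("|")
    if len(parts) == 3 and parts[0] in {"sp", "tr"}:
        return parts[2], desc
    return first, desc


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA into :class:`ProteinRecord` list,
    order preserved.  Raises ``ValueError`` on an empty file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, desc = _split_header(rec.description)
        records.append(
            ProteinRecord(accession=accession, description=desc, sequence=str(rec.seq).upper())
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> Path:
    """Write records as wrapped FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path
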