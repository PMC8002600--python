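"""Consensus profile (main spectra projection, MSP) construction.

Replicate intact-cell spectra of one sample are merged into a single
consensus peak profile: peaks from all replicates are grouped by
single-linkage chaining within a mass tolerance, groups present in at
least a minimum fraction of the replicates become consensus peaks, and
the profile is optionally capped to the most intense peaks (intact-cell
fingerprints of cyanobacteria typically carry on the order of 100
species-characteristic peaks).

The grouping rule is deliberately simple and fully specified: on the
sorted union of all replicate peaks, a new group starts wherever the gap
to the previous peak exceeds ``tol``; a pathological chain spanning more
than ``2*tol`` is split at its largest internal gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .spectra_io import Peak, PeakList, SampleMeta

__all__ = [
    "ConsensusPeak",
    "ConsensusProfile",
    "build_msp",
    "normalize_intensities",
    "write_msp",
    "read_msp",
]


@dataclass(frozen=True)
class ConsensusPeak:
    """A merged peak: intensity-weighted mean m/z, mean intensity over the
    replicates that contain it, and the fraction of replicates containing
    it (``frequency``)."""

    mz: float
    mean_intensity: float
    frequency: float

    def __post_init__(self) -> None:
        if not 0 < self.frequency <= 1:
            raise ValueError(f"frequency must be in (0, 1], got {self.frequency}")


@dataclass(frozen=True)
class ConsensusProfile:
    """A consensus peak profile built from ``n_source_spectra`` replicates."""

    profile_id: str
    peaks: tuple[ConsensusPeak, ...]
    n_source_spectra: int
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if self.n_source_spectra < 1:
            raise ValueError("n_source_spectra must be >= 1")
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("consensus peaks must be strictly sorted by m/z")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    @property
    def intensity(self) -> tuple[float, ...]:
        return tuple(p.mean_intensity for p in self.peaks)


def _split_pathological(group: list[tuple[float, float, int]], tol: float) -> list[list[tuple[float, float, int]]]:
    """Split a single-linkage chain spanning > 2*tol at its largest
    internal gap, recursively, to bound consensus peak width."""
    if group[-1][0] - group[0][0] <= 2 * tol or len(group) < 2:
        return [group]
    gaps = [group[i + 1][0] - group[i][0] for i in range(len(group) - 1)]
    cut = int(np.argmax(gaps)) + 1
    return _split_pathological(group[:cut], tol) + _split_pathological(group[cut:], tol)


def build_msp(
    spectra: Sequence[PeakList],
    tol: float = 2.0,
    min_frequency: float = 0.25,
    max_peaks: int | None = 100,
    profile_id: str | None = None,
) -> ConsensusProfile:
    """Merge replicate peak lists into a consensus profile.

    Parameters
    ----------
    spectra
        Replicate spectra of one sample (>= 1).
    tol
        Grouping tolerance in Da; peaks closer than this across replicates
        are considered the same species (default 2.0 Da, the annotation
        window of the downstream assignment step).
    min_frequency
        Minimum fraction of replicates a group must appear in to survive
        (default 0.25, i.e. 5 of 20 replicates).
    max_peaks
        If more groups survive, keep the ``max_peaks`` highest by mean
        intensity (``None`` disables the cap).
    """
    if not spectra:
        raise ValueError("build_msp requires at least one spectrum")
    if not tol > 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if not 0 < min_frequency <= 1:
        raise ValueError(f"min_frequency must be in (0, 1], got {min_frequency}")

    n = len(spectra)
    # pooled (mz, intensity, replicate index), sorted by mz
    pooled = sorted(
        (p.mz, p.intensity, k) for k, s in enumerate(spectra) for p in s
    )
    groups: list[list[tuple[float, float, int]]] = []
    for item in pooled:
        if groups and item[0] - groups[-1][-1][0] <= tol:
            groups[-1].append(item)
        else:
            groups.append([item])
    groups = [g for chain in groups for g in _split_pathological(chain, tol)]

    consensus: list[ConsensusPeak] = []
    for g in groups:
        # a replicate contributing several peaks to one group counts once;
        # its intensities are summed first
        per_rep: dict[int, float] = {}
        for _, inten, k in g:
            per_rep[k] = per_rep.get(k, 0.0) + inten
        freq = len(per_rep) / n
        if freq < min_frequency:
            continue
        mzs = np.array([mz for mz, _, _ in g])
        weights = np.array([inten for _, inten, _ in g])
        if weights.sum() > 0:
            mz = float(np.average(mzs, weights=weights))
        else:
            mz = float(mzs.mean())
        consensus.append(
            ConsensusPeak(mz=mz, mean_intensity=float(np.mean(list(per_rep.values()))), frequency=freq)
        )

    if max_peaks is not None and len(consensus) > max_peaks:
        keep = sorted(consensus, key=lambda p: -p.mean_intensity)[:max_peaks]
        consensus = sorted(keep, key=lambda p: p.mz)

    return ConsensusProfile(
        profile_id=profile_id or spectra[0].meta.treatment or spectra[0].spectrum_id,
        peaks=tuple(consensus),
        n_source_spectra=n,
        meta=spectra[0].meta,
    )


def normalize_intensities(profile, mode: str = "base-peak"):
    """Rescale intensities: ``base-peak`` sets the maximum to 100, ``tic``
    makes intensities sum to 1.  Works on :class:`~icmaldi.spectra_io.PeakList`
    and :class:`ConsensusProfile` alike; raises on all-zero intensities."""
    intens = np.asarray(profile.intensity, dtype=float)
    if intens.size == 0 or np.all(intens == 0):
        raise ValueError("cannot normalize a profile with no positive intensity")
    if mode == "base-peak":
        scaled = intens * (100.0 / intens.max())
    elif mode == "tic":
        scaled = intens / intens.sum()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")

    if isinstance(profile, PeakList):
        peaks = tuple(Peak(p.mz, s) for p, s in zip(profile.peaks, scaled))
        return replace(profile, peaks=peaks)
    if isinstance(profile, ConsensusProfile):
        peaks = tuple(
            ConsensusPeak(p.mz, float(s), p.frequency) for p, s in zip(profile.peaks, scaled)
        )
        return replace(profile, peaks=peaks)
    raise TypeError(f"unsupported profile type {type(profile).__name__}")


def write_msp(profile: ConsensusProfile, path) -> None:
    """Serialize a consensus profile as CSV (mz, mean_intensity,
    frequency) plus a ``.meta.json`` sidecar with metadata."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    lines = ["mz,mean_intensity,frequency"] + [
        f"{p.mz:.6f},{p.mean_intensity:.6f},{p.frequency:.6f}" for p in profile
    ]
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "profile_id": profile.profile_id,
        "n_source_spectra": profile.n_source_spectra,
        "meta": asdict(profile.meta),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
    )


def read_msp(path) -> ConsensusProfile:
    """Read a profile written by :func:`write_msp`."""
    import json
    from pathlib import Path

    path = Path(path)
    peaks = []
    for line in path.read_text().splitlines()[1:]:
        mz, inten, freq = (float(x) for x in line.split(","))
        peaks.append(ConsensusPeak(mz, inten, freq))
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        meta = SampleMeta(**sidecar["meta"])
        return ConsensusProfile(
            profile_id=sidecar["profile_id"],
            peaks=tuple(peaks),
            n_source_spectra=sidecar["n_source_spectra"],
            meta=meta,
        )
    return ConsensusProfile(profile_id=path.stem, peaks=tuple(peaks), n_source_spectra=1)
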