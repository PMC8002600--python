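"""Differential peak detection between treated and control profiles.

A treated sample is compared with its untreated control by one-to-one
matching of consensus peaks within a mass tolerance.  Sample peaks with
no counterpart in the control are *newly appeared*; control peaks with no
counterpart in the sample are *missing*.  Presence/absence only —
intensity plays no role in the call (differential peaks in intact-cell
fingerprints are typically low-intensity, and no intensity test is
defined here).

Matching is greedy by ascending |Δm/z| over all cross pairs within the
tolerance, each peak used at most once, ties broken toward the lower
control m/z (then lower sample m/z): deterministic and order-independent
for sorted inputs, and equal to the minimum-total-|Δ| assignment whenever
the within-tolerance candidates are unambiguous.

Counts per (treatment, concentration, time) condition aggregate into a
matrix rendered as the familiar biotyping heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .msp_builder import ConsensusPeak, ConsensusProfile

__all__ = ["MatchedPair", "DiffReport", "DiffMatrix", "diff", "diff_matrix"]


@dataclass(frozen=True)
class MatchedPair:
    sample_peak: ConsensusPeak
    control_peak: ConsensusPeak

    @property
    def delta(self) -> float:
        """sample m/z - control m/z, Da."""
        return self.sample_peak.mz - self.control_peak.mz


@dataclass(frozen=True)
class DiffReport:
    """Outcome of one sample-vs-control comparison."""

    new_peaks: tuple[ConsensusPeak, ...]
    missing_peaks: tuple[ConsensusPeak, ...]
    shared: tuple[MatchedPair, ...]
    tol: float

    @property
    def n_new(self) -> int:
        return len(self.new_peaks)

    @property
    def n_missing(self) -> int:
        return len(self.missing_peaks)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: category, mz, intensity, frequency, matched_mz, delta."""
        rows = []
        for p in self.new_peaks:
            rows.append(("new", p.mz, p.mean_intensity, p.frequency, np.nan, np.nan))
        for p in self.missing_peaks:
            rows.append(("missing", p.mz, p.mean_intensity, p.frequency, np.nan, np.nan))
        for pair in self.shared:
            rows.append(
                (
                    "shared",
                    pair.sample_peak.mz,
                    pair.sample_peak.mean_intensity,
                    pair.sample_peak.frequency,
                    pair.control_peak.mz,
                    pair.delta,
                )
            )
        df = pd.DataFrame(
            rows, columns=["category", "mz", "intensity", "frequency", "matched_mz", "delta"]
        )
        return df.sort_values(["category", "mz"], kind="stable").reset_index(drop=True)


def diff(sample: ConsensusProfile, control: ConsensusProfile, tol: float = 2.0) -> DiffReport:
    """Match sample against control peaks within ``tol`` Da and classify.

    Guarantees |new| + |shared| = |sample| and |missing| + |shared| =
    |control| exactly, and |Δ| <= tol for every shared pair.
    """
    if not tol > 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if len(sample) == 0 or len(control) == 0:
        raise ValueError("diff requires non-empty profiles")

    candidates = []
    for i, sp in enumerate(sample.peaks):
        for j, cp in enumerate(control.peaks):
            d = abs(sp.mz - cp.mz)
            if d <= tol:
                candidates.append((d, cp.mz, sp.mz, i, j))
    candidates.sort()

    used_s: set[int] = set()
    used_c: set[int] = set()
    pairs: list[MatchedPair] = []
    for _, _, _, i, j in candidates:
        if i in used_s or j in used_c:
            continue
        used_s.add(i)
        used_c.add(j)
        pairs.append(MatchedPair(sample.peaks[i], control.peaks[j]))

    new = tuple(p for i, p in enumerate(sample.peaks) if i not in used_s)
    missing = tuple(p for j, p in enumerate(control.peaks) if j not in used_c)
    pairs.sort(key=lambda pr: pr.sample_peak.mz)
    return DiffReport(new_peaks=new, missing_peaks=missing, shared=tuple(pairs), tol=tol)


ConditionKey = tuple[str, float, float]  # (treatment, concentration µM, time days)


@dataclass(frozen=True)
class DiffMatrix:
    """Counts of (newly appeared, missing) peaks per condition, rows =
    treatments, columns = (concentration, time) pairs."""

    new_counts: pd.DataFrame
    missing_counts: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-form table with one row per condition."""
        rows = []
        for treatment in self.new_counts.index:
            for col in self.new_counts.columns:
                conc, time = col
                rows.append(
                    (
                        treatment,
                        conc,
                        time,
                        int(self.new_counts.loc[treatment, col]),
                        int(self.missing_counts.loc[treatment, col]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["treatment", "concentration_uM", "time_days", "n_new", "n_missing"]
        )


def diff_matrix(reports: Mapping[ConditionKey, DiffReport]) -> DiffMatrix:
    """Tabulate per-condition differential-peak counts.

    ``reports`` maps (treatment, concentration µM, time days) to the
    corresponding :class:`DiffReport`.  Duplicate keys cannot occur in a
    mapping by construction; an empty mapping is rejected.
    """
    if not reports:
        raise ValueError("diff_matrix requires at least one report")
    treatments = sorted({k[0] for k in reports})
    cols = sorted({(k[1], k[2]) for k in reports})
    index = pd.Index(treatments, name="treatment")
    columns = pd.MultiIndex.from_tuples(cols, names=["concentration_uM", "time_days"])
    new = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    missing = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for (treatment, conc, time), rep in reports.items():
        new.loc[treatment, (conc, time)] = rep.n_new
        missing.loc[treatment, (conc, time)] = rep.n_missing
    return DiffMatrix(new_counts=new, missing_counts=missing)


def plot_heatmap(matrix: DiffMatrix, path: str | Path, title: str = "Differential peaks") -> Path:
    """Render the (new, missing) count matrices side by side as heat maps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, 2, figsize=(2 + 0.6 * len(matrix.new_counts.columns) * 2, 1.5 + 0.5 * len(matrix.new_counts))
    )
    for ax, frame, label in (
        (axes[0], matrix.new_counts, "newly appeared"),
        (axes[1], matrix.missing_counts, "missing"),
    ):
        im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(frame.columns)))
        ax.set_xticklabels([f"{c} µM\n{t:g} d" for c, t in frame.columns], fontsize=7)
        ax.set_yticks(range(len(frame.index)))
        ax.set_yticklabels(frame.index, fontsize=8)
        ax.set_title(label, fontsize=9)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
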