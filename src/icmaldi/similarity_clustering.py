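"""Spectral similarity, hierarchical clustering, and library identification.

Profiles are compared on aligned intensity vectors: the union of their
peaks is matched within a mass tolerance (same one-to-one matching as the
differential-peak step), base-peak-normalized and square-root-transformed
intensities are paired position-wise with zeros for absences, and the
distance is 1 - Pearson correlation (Spearman optionally).  Pairwise
distances feed standard average-linkage (UPGMA) agglomeration; node
heights are half the merge distance, which makes the tree exactly
ultrametric, and ties are broken by lexicographic label order so the tree
is reproducible.

Identification against a reference library uses a transparent composite
score on a 0-3 scale:

    score = (f_qr * f_rq * max(r, 0)) ** (1/3) * 3

where ``f_qr`` is the fraction of query peaks matched in the reference,
``f_rq`` the reverse fraction, and ``r`` the Pearson correlation of the
aligned intensities.  The range imitates the familiar commercial
biotyping scale, but the score is NOT comparable to proprietary scores or
their >= 2.0 species-level convention — it is defined entirely by the
formula above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr
from skbio.tree import TreeNode

from .diff_peaks import diff
from .msp_builder import ConsensusProfile, normalize_intensities

__all__ = [
    "DistanceMatrix",
    "IdentificationResult",
    "align_profiles",
    "correlation_distance",
    "distance_matrix",
    "upgma",
    "identify",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(d, d.T, atol=1e-12) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    best_reference: str
    score: float
    peak_match_query_to_ref: float
    peak_match_ref_to_query: float
    intensity_correlation: float


def align_profiles(
    a: ConsensusProfile, b: ConsensusProfile, tol: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired intensity vectors over the matched peak union of two profiles.

    Intensities are base-peak normalized first; each union position holds
    (intensity in a, intensity in b) with 0 for absence.  Vector length
    equals |only-a| + |only-b| + |shared| of the same matching used by
    :func:`~icmaldi.diff_peaks.diff`.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty profile")
    an = normalize_intensities(a, "base-peak")
    bn = normalize_intensities(b, "base-peak")
    report = diff(an, bn, tol=tol)
    va, vb = [], []
    for pair in report.shared:
        va.append(pair.sample_peak.mean_intensity)
        vb.append(pair.control_peak.mean_intensity)
    for p in report.new_peaks:  # only in a
        va.append(p.mean_intensity)
        vb.append(0.0)
    for p in report.missing_peaks:  # only in b
        va.append(0.0)
        vb.append(p.mean_intensity)
    return np.asarray(va), np.asarray(vb)


def correlation_distance(
    a: ConsensusProfile,
    b: ConsensusProfile,
    tol: float = 2.0,
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """1 - correlation of aligned, sqrt-transformed intensity vectors.

    Square-root transformation stabilizes the variance of the highly
    skewed MALDI intensities.  Raises on degenerate (zero-variance)
    alignments or fewer than 3 aligned positions.
    """
    va, vb = align_profiles(a, b, tol=tol)
    if len(va) < 3:
        raise ValueError("need >= 3 aligned positions for a correlation distance")
    va, vb = np.sqrt(va), np.sqrt(vb)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero-variance aligned vector (degenerate profile)")
    if method == "pearson":
        r = pearsonr(va, vb).statistic
    elif method == "spearman":
        r = spearmanr(va, vb).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(1.0 - r)


def distance_matrix(
    profiles: Sequence[ConsensusProfile],
    tol: float = 2.0,
    method: Literal["pearson", "spearman"] = "pearson",
) -> DistanceMatrix:
    """All pairwise correlation distances; symmetric, zero diagonal."""
    labels = tuple(p.profile_id for p in profiles)
    if len(set(labels)) != len(labels):
        raise ValueError("profile ids must be unique")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = correlation_distance(profiles[i], profiles[j], tol, method)
    return DistanceMatrix(labels=labels, d=d)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) tree from a distance matrix.

    Leaves are reordered lexicographically before agglomeration so ties
    resolve deterministically.  Each internal node sits at height = half
    its merge distance; branch lengths are height differences, so every
    root-to-leaf path has identical length (ultrametric).  Export with
    ``tree.write(path)`` (Newick).
    """
    if len(dm.labels) < 2:
        raise ValueError("upgma requires at least 2 profiles")
    order = np.argsort(np.asarray(dm.labels, dtype=object))
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)]
    Z = linkage(squareform(d, checks=False), method="average")

    nodes: list[TreeNode] = [TreeNode(name=str(lb)) for lb in labels]
    heights: list[float] = [0.0] * len(labels)
    for left, right, dist, _ in Z:
        h = dist / 2.0
        a, b = nodes[int(left)], nodes[int(right)]
        a.length = h - heights[int(left)]
        b.length = h - heights[int(right)]
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


def _match_stats(query: ConsensusProfile, ref: ConsensusProfile, tol: float):
    report = diff(query, ref, tol=tol)
    n_shared = len(report.shared)
    f_qr = n_shared / len(query)
    f_rq = n_shared / len(ref)
    if n_shared >= 3:
        qv = np.sqrt([p.sample_peak.mean_intensity for p in report.shared])
        rv = np.sqrt([p.control_peak.mean_intensity for p in report.shared])
        if np.ptp(qv) > 0 and np.ptp(rv) > 0:
            r = float(pearsonr(qv, rv).statistic)
        else:
            r = 1.0 if np.allclose(qv, rv) else 0.0
    else:
        r = 0.0
    return f_qr, f_rq, r


def score_pair(query: ConsensusProfile, ref: ConsensusProfile, tol: float = 2.0) -> IdentificationResult:
    """Composite 0-3 identification score of a query against one reference."""
    qn = normalize_intensities(query, "base-peak")
    rn = normalize_intensities(ref, "base-peak")
    f_qr, f_rq, r = _match_stats(qn, rn, tol)
    score = (f_qr * f_rq * max(r, 0.0)) ** (1.0 / 3.0) * 3.0
    return IdentificationResult(
        query_id=query.profile_id,
        best_reference=ref.profile_id,
        score=float(score),
        peak_match_query_to_ref=f_qr,
        peak_match_ref_to_query=f_rq,
        intensity_correlation=r,
    )


def identify(
    query: ConsensusProfile, library: Sequence[ConsensusProfile], tol: float = 2.0
) -> IdentificationResult:
    """Best-scoring library entry for a query profile.

    Ties are broken by lexicographic reference id, so the result does not
    depend on library order.
    """
    if not library:
        raise ValueError("identify requires a non-empty library")
    results = [score_pair(query, ref, tol=tol) for ref in library]
    results.sort(key=lambda r: (-r.score, r.best_reference))
    return results[0]
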