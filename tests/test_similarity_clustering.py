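"""Alignment, correlation distance, UPGMA trees, and identification."""

import math

import numpy as np
import pytest

from conftest import profile_from_pairs
from icmaldi.diff_peaks import diff
from icmaldi.similarity_clustering import (
    DistanceMatrix,
    align_profiles,
    correlation_distance,
    distance_matrix,
    identify,
    score_pair,
    upgma,
)


class TestAlignProfiles:
    def test_identical_profiles_give_identical_vectors(self):
        p = profile_from_pairs([(1000, 10), (2000, 20), (3000, 5)])
        va, vb = align_profiles(p, p, tol=2.0)
        assert np.allclose(va, vb)
        assert len(va) == 3

    def test_disjoint_profiles_have_disjoint_support(self):
        a = profile_from_pairs([(1000, 10), (2000, 20)])
        b = profile_from_pairs([(5000, 10), (6000, 20)])
        va, vb = align_profiles(a, b, tol=2.0)
        assert len(va) == 4
        assert np.all((va == 0) | (vb == 0))

    def test_vector_length_matches_diff_categories(self, rng):
        for _ in range(20):
            a = profile_from_pairs(
                [(m, rng.uniform(1, 100)) for m in np.sort(rng.uniform(1000, 9000, 15))]
            )
            b = profile_from_pairs(
                [(m, rng.uniform(1, 100)) for m in np.sort(rng.uniform(1000, 9000, 12))]
            )
            va, _ = align_profiles(a, b, tol=2.0)
            r = diff(a, b, tol=2.0)
            assert len(va) == r.n_new + r.n_missing + len(r.shared)

    def test_empty_profile_rejected(self):
        p = profile_from_pairs([(1000, 1)])
        with pytest.raises(ValueError):
            align_profiles(p, p.__class__(profile_id="e", peaks=(), n_source_spectra=1), 2.0)


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        p = profile_from_pairs([(1000, 10), (2000, 20), (3000, 5), (4000, 40)])
        assert correlation_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        a = profile_from_pairs([(m, rng.uniform(1, 100)) for m in range(1000, 1500, 50)])
        b = profile_from_pairs([(m + 1, rng.uniform(1, 100)) for m in range(1000, 1700, 50)])
        assert correlation_distance(a, b) == pytest.approx(correlation_distance(b, a), abs=1e-12)

    def test_hand_computed_four_position_example(self):
        # all peaks shared; base-peak norm then sqrt, then textbook Pearson
        ia = [10.0, 40.0, 90.0, 160.0]
        ib = [160.0, 90.0, 40.0, 10.0]
        a = profile_from_pairs(list(zip([1000, 2000, 3000, 4000], ia)))
        b = profile_from_pairs(list(zip([1000, 2000, 3000, 4000], ib)))
        x = np.sqrt(np.array(ia) / 160.0 * 100.0)
        y = np.sqrt(np.array(ib) / 160.0 * 100.0)
        xm, ym = x - x.mean(), y - y.mean()
        r = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
        assert correlation_distance(a, b) == pytest.approx(1 - r, abs=1e-12)

    def test_spearman_option(self):
        ia = [10.0, 40.0, 90.0, 160.0]
        ib = [1.0, 2.0, 3.0, 4.0]  # same ranks as ia
        a = profile_from_pairs(list(zip([1000, 2000, 3000, 4000], ia)))
        b = profile_from_pairs(list(zip([1000, 2000, 3000, 4000], ib)))
        assert correlation_distance(a, b, method="spearman") == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_profile_rejected(self):
        a = profile_from_pairs([(1000, 5), (2000, 5), (3000, 5)])
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_distance(a, a)


def leaf_depths(tree):
    return {tip.name: tree.distance(tip) for tip in tree.tips()}


class TestUpgma:
    def test_two_leaves_cherry(self):
        dm = DistanceMatrix(labels=("A", "B"), d=np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(dm)
        depths = leaf_depths(tree)
        assert depths == pytest.approx({"A": 0.2, "B": 0.2})

    def test_three_leaf_topology(self):
        d = np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]])
        tree = upgma(DistanceMatrix(labels=("A", "B", "C"), d=d))
        # A and B must be siblings
        lca = tree.lca(["A", "B"])
        assert {t.name for t in lca.tips()} == {"A", "B"}

    def test_ultrametric_on_random_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 9))
            x = rng.uniform(0.1, 1.5, size=(n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = tuple(f"L{i}" for i in range(n))
            tree = upgma(DistanceMatrix(labels=labels, d=d))
            depths = list(leaf_depths(tree).values())
            assert max(depths) - min(depths) < 1e-9

    def test_equal_distances_resolved_by_label_order_deterministically(self):
        d = np.full((4, 4), 0.6)
        np.fill_diagonal(d, 0.0)
        labels = ("d", "b", "a", "c")
        t1 = upgma(DistanceMatrix(labels=labels, d=d)).__str__()
        t2 = upgma(DistanceMatrix(labels=("a", "c", "b", "d"), d=d)).__str__()
        assert t1 == t2

    def test_leaves_equal_matrix_labels(self, rng):
        x = rng.uniform(0.1, 1.0, size=(5, 5))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        labels = ("q3", "q1", "q5", "q2", "q4")
        tree = upgma(DistanceMatrix(labels=labels, d=d))
        assert {t.name for t in tree.tips()} == set(labels)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("A", "B"), d=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("A", "B"), d=np.array([[0, np.nan], [np.nan, 0]]))

    def test_newick_export(self, tmp_path):
        dm = DistanceMatrix(labels=("A", "B"), d=np.array([[0, 0.4], [0.4, 0]]))
        path = tmp_path / "t.nwk"
        upgma(dm).write(str(path))
        assert "A" in path.read_text() and ";" in path.read_text()


class TestIdentify:
    def test_identical_query_scores_three(self):
        p = profile_from_pairs([(1000, 10), (2000, 20), (3000, 5), (4000, 40)])
        res = score_pair(p, p)
        assert res.score == pytest.approx(3.0, abs=1e-9)

    def test_disjoint_query_scores_zero(self):
        q = profile_from_pairs([(1000, 10), (2000, 20), (3000, 3)])
        r = profile_from_pairs([(9000, 10), (9500, 20), (9900, 4)])
        assert score_pair(q, r).score == 0.0

    def test_library_order_invariance(self, rng):
        refs = []
        for i in range(5):
            mz = np.sort(rng.uniform(1000, 9000, 20))
            refs.append(
                profile_from_pairs(
                    [(m, rng.uniform(1, 100)) for m in mz], profile_id=f"ref{i}"
                )
            )
        query = refs[2]
        fwd = identify(query, refs)
        rev = identify(query, refs[::-1])
        assert fwd.best_reference == rev.best_reference == "ref2"
        assert fwd.score == pytest.approx(rev.score)

    def test_empty_library_rejected(self):
        p = profile_from_pairs([(1000, 1)])
        with pytest.raises(ValueError):
            identify(p, [])


def test_high_dose_profiles_form_separate_clade(small_template, default_cfg):
    """Harsh-treatment profiles cluster apart from controls, the pattern
    seen for strong respiration inhibitors at the highest dose."""
    from icmaldi.synthetic_data import apply_treatment, emit_replicates, make_treatment_instance
    from icmaldi.msp_builder import build_msp

    profiles = []
    for name, seed in (("control_1", 11), ("control_2", 12)):
        reps = emit_replicates(small_template.profile, 6, default_cfg, seed=seed)
        msp = build_msp(reps, profile_id=name)
        profiles.append(msp)
    instance = make_treatment_instance(small_template, seed=21)
    for name, (dose, time), seed in (
        ("high_2wk", (10.0, 14.0), 13),
        ("high_3wk", (10.0, 21.0), 14),
    ):
        perturbed, _ = apply_treatment(
            small_template, dose, time, default_cfg, seed=seed, instance=instance
        )
        msp = build_msp(emit_replicates(perturbed, 6, default_cfg, seed=seed + 100), profile_id=name)
        profiles.append(msp)
    tree = upgma(distance_matrix(profiles, tol=2.0))
    lca = tree.lca(["high_2wk", "high_3wk"])
    clade = {t.name for t in lca.tips()}
    assert clade == {"high_2wk", "high_3wk"}
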