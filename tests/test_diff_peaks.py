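"""Differential peak detection and its matching guarantees."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from conftest import profile_from_pairs
from icmaldi.diff_peaks import diff, diff_matrix, plot_heatmap


def random_profile(rng, n, lo=1000, hi=10000, min_gap=5.0):
    mzs = np.sort(rng.uniform(lo, hi, size=n * 3))
    chosen = [mzs[0]]
    for m in mzs[1:]:
        if m - chosen[-1] >= min_gap:
            chosen.append(m)
        if len(chosen) == n:
            break
    return profile_from_pairs([(m, float(rng.uniform(1, 100))) for m in chosen])


def oracle_match_count(sample_mz, control_mz, tol):
    """Maximum-cardinality, minimum-total-|Δ| one-to-one matching via the
    Hungarian algorithm on a padded cost matrix (independent of the
    greedy implementation)."""
    ns, nc = len(sample_mz), len(control_mz)
    big = 1e9
    cost = np.full((ns, nc), big)
    for i, s in enumerate(sample_mz):
        for j, c in enumerate(control_mz):
            if abs(s - c) <= tol:
                cost[i, j] = abs(s - c)
    # pad to allow leaving peaks unmatched at a cost just below one real match
    n = ns + nc
    padded = np.full((n, n), 0.0)
    padded[:ns, :nc] = cost
    padded[:ns, nc:] = 1e8  # leave a sample peak unmatched
    padded[ns:, :nc] = 1e8  # leave a control peak unmatched
    rows, cols = linear_sum_assignment(padded)
    pairs = [(i, j) for i, j in zip(rows, cols) if i < ns and j < nc and cost[i, j] < big]
    total = sum(cost[i, j] for i, j in pairs)
    return len(pairs), total


class TestDiff:
    def test_identical_profiles_all_shared_at_zero_delta(self):
        p = profile_from_pairs([(1000, 1), (2000, 2), (3000, 3)])
        r = diff(p, p, tol=2.0)
        assert r.n_new == 0 and r.n_missing == 0
        assert len(r.shared) == 3
        assert all(pair.delta == 0 for pair in r.shared)

    def test_worked_six_peak_instance(self):
        control = profile_from_pairs([(1000.0, 1), (2000.0, 1), (3000.0, 1)])
        sample = profile_from_pairs([(1001.0, 1), (2500.0, 1), (3000.5, 1)])
        r = diff(sample, control, tol=2.0)
        shared = {(p.sample_peak.mz, p.control_peak.mz) for p in r.shared}
        assert shared == {(1001.0, 1000.0), (3000.5, 3000.0)}
        assert [p.mz for p in r.new_peaks] == [2500.0]
        assert [p.mz for p in r.missing_peaks] == [2000.0]

    def test_shared_pairs_within_tolerance(self, rng):
        for _ in range(20):
            s = random_profile(rng, 15)
            c = random_profile(rng, 12)
            r = diff(s, c, tol=2.0)
            assert all(abs(p.delta) <= 2.0 for p in r.shared)

    def test_conservation_exact(self, rng):
        for _ in range(50):
            s = random_profile(rng, int(rng.integers(1, 25)))
            c = random_profile(rng, int(rng.integers(1, 25)))
            r = diff(s, c, tol=2.0)
            assert r.n_new + len(r.shared) == len(s)
            assert r.n_missing + len(r.shared) == len(c)

    def test_symmetry_new_equals_reversed_missing(self, rng):
        for _ in range(50):
            s = random_profile(rng, int(rng.integers(1, 20)), min_gap=1.0)
            c = random_profile(rng, int(rng.integers(1, 20)), min_gap=1.0)
            fwd = diff(s, c, tol=2.0)
            rev = diff(c, s, tol=2.0)
            assert sorted(p.mz for p in fwd.new_peaks) == sorted(p.mz for p in rev.missing_peaks)
            assert sorted(p.mz for p in fwd.missing_peaks) == sorted(p.mz for p in rev.new_peaks)

    def test_greedy_matches_assignment_oracle_on_unambiguous_instances(self, rng):
        """On instances whose within-tol groups are separated by > 2*tol,
        greedy matching attains the optimal assignment."""
        tol = 2.0
        for _ in range(100):
            s = random_profile(rng, int(rng.integers(2, 15)), min_gap=2 * tol + 0.5)
            jitter = rng.uniform(-tol, tol, size=len(s))
            keep = rng.random(len(s)) > 0.3
            c_mz = [m + j for m, j, k in zip(s.mz, jitter, keep) if k]
            if not c_mz:
                continue
            c = profile_from_pairs([(m, 1.0) for m in c_mz])
            r = diff(s, c, tol=tol)
            n_opt, total_opt = oracle_match_count(s.mz, c.mz, tol)
            assert len(r.shared) == n_opt
            assert sum(abs(p.delta) for p in r.shared) == pytest.approx(total_opt)

    def test_synthetic_deletions_and_additions_counted_exactly(self, small_template, default_cfg):
        from icmaldi.synthetic_data import apply_treatment

        perturbed, truth = apply_treatment(small_template, dose=10.0, time=21.0, cfg=default_cfg)
        r = diff(perturbed, small_template.profile, tol=2.0)
        assert r.n_new == len(truth.added_mz)
        assert r.n_missing == len(truth.deleted_mz)

    def test_tol_validation(self):
        p = profile_from_pairs([(1000, 1)])
        with pytest.raises(ValueError):
            diff(p, p, tol=0.0)


class TestDiffMatrix:
    def test_single_report_cell(self):
        c = profile_from_pairs([(1000, 1), (2000, 1), (3000, 1), (4000, 1), (5000, 1), (6000, 1)])
        s = profile_from_pairs([(1000, 1), (7000, 1), (8000, 1), (9000, 1)])
        r = diff(s, c, tol=2.0)
        m = diff_matrix({("azide", 10.0, 21.0): r})
        frame = m.to_frame()
        assert len(frame) == 1
        assert frame.loc[0, "n_new"] == 3 and frame.loc[0, "n_missing"] == 5

    def test_cell_sums_conserved_over_grid(self, rng):
        reports = {}
        for t in ("azide", "streptomycin"):
            for dose in (1.0, 10.0):
                for time in (7.0, 21.0):
                    s = random_profile(rng, 10)
                    c = random_profile(rng, 10)
                    reports[(t, dose, time)] = diff(s, c, tol=2.0)
        frame = diff_matrix(reports).to_frame()
        assert len(frame) == 8
        for _, row in frame.iterrows():
            rep = reports[(row.treatment, row.concentration_uM, row.time_days)]
            assert row.n_new == rep.n_new and row.n_missing == rep.n_missing

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diff_matrix({})

    def test_heatmap_renders(self, tmp_path, rng):
        reports = {
            ("azide", d, t): diff(random_profile(rng, 8), random_profile(rng, 8), tol=2.0)
            for d in (1.0, 10.0)
            for t in (7.0, 21.0)
        }
        out = plot_heatmap(diff_matrix(reports), tmp_path / "hm.png")
        assert out.exists() and out.stat().st_size > 0
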