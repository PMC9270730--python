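"""Pooling, neighborhood geometry, rank-sum testing, and the full pipeline."""

from itertools import combinations

import numpy as np
import pytest

from nbloop import LoopCallingConfig
from nbloop.candidate_selection import Candidate
from nbloop.peak_calling import (
    call_loops,
    evaluate_neighborhood,
    extract_neighborhood,
    pool_candidates,
    rank_sum_greater,
)
from nbloop.matrix_io import BandedContactMatrix
from nbloop.synthetic import SyntheticSpec, generate_dataset, score_recovery
from conftest import make_banded


def cand(i, j, obs_exp, raw=20.0, p=0.01):
    return Candidate(i=i, j=j, d=j - i, obs_exp=obs_exp, raw_count=raw, p_preselect=p)


class TestPooling:
    def test_highest_obs_exp_wins_within_window(self):
        survivors = pool_candidates([cand(10, 20, 2.0), cand(11, 21, 3.0)], 5)
        assert [(c.i, c.j) for c in survivors] == [(11, 21)]

    def test_distant_candidates_both_survive(self):
        survivors = pool_candidates([cand(10, 20, 2.0), cand(30, 40, 3.0)], 5)
        assert len(survivors) == 2

    def test_tie_breaks_toward_smaller_distance_then_i(self):
        survivors = pool_candidates([cand(11, 21, 3.0), cand(10, 20, 3.0)], 5)
        assert [(c.i, c.j) for c in survivors] == [(10, 20)]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        cands = [
            cand(int(i), int(i + d), float(v))
            for i, d, v in zip(
                rng.integers(0, 300, 150),
                rng.integers(5, 60, 150),
                rng.uniform(1.5, 9.0, 150),
            )
        ]
        once = pool_candidates(cands, 5)
        twice = pool_candidates(once, 5)
        assert once == twice

    def test_pairwise_chebyshev_separation(self):
        rng = np.random.default_rng(3)
        cands = [
            cand(int(i), int(i + d), float(v))
            for i, d, v in zip(
                rng.integers(0, 100, 200),
                rng.integers(5, 40, 200),
                rng.uniform(1.5, 9.0, 200),
            )
        ]
        surv = pool_candidates(cands, 5)
        for a, b in combinations(surv, 2):
            assert max(abs(a.i - b.i), abs(a.j - b.j)) > 5


class TestNeighborhoodGeometry:
    def interior_matrix(self, n=60):
        rng = np.random.default_rng(4)
        dense = np.zeros((n, n))
        ii, jj = np.triu_indices(n)
        dense[ii, jj] = rng.uniform(0.5, 2.0, len(ii))
        return make_banded(dense)

    def test_interior_counts_with_defaults(self):
        m = self.interior_matrix()
        nb = extract_neighborhood(m, (20, 40), peak_width=2, window_size=5)
        assert len(nb.peak) == 25
        assert len(nb.all_background) == 96
        assert len(nb.horizontal) == 30 and len(nb.vertical) == 30
        assert len(nb.corner) == 9
        # peak + named backgrounds + 3 unclassified window corners = 121
        assert 25 + 30 + 30 + 9 + 27 == 121

    def test_regions_are_disjoint_by_construction(self):
        from nbloop.peak_calling import _region_masks

        di, dj, peak, hor, ver, cor = _region_masks(2, 5)
        stack = np.array([peak, hor, ver, cor], dtype=int)
        assert stack.sum(axis=0).max() == 1

    def test_edge_truncation_matches_brute_force_count(self):
        n, w = 60, 5
        m = self.interior_matrix(n)
        center = (2, 10)  # 2 bins from the top edge
        nb = extract_neighborhood(m, center, 2, w)
        valid = sum(
            1
            for a in range(center[0] - w, center[0] + w + 1)
            for b in range(center[1] - w, center[1] + w + 1)
            if 0 <= min(a, b) and max(a, b) < n
        )
        assert len(nb.peak) + len(nb.all_background) == valid

    def test_unstored_in_band_positions_are_zero(self):
        n = 40
        dense = np.zeros((n, n))
        dense[20, 30] = 5.0
        m = make_banded(dense)
        nb = extract_neighborhood(m, (20, 30), 2, 5)
        assert nb.peak.max() == 5.0
        assert (nb.all_background == 0).all()
        assert len(nb.all_background) == 96  # in-band unstored cells count as 0

    def test_band_cells_outside_distance_band_are_absent(self):
        n = 60
        dense = np.zeros((n, n))
        ii, jj = np.triu_indices(n)
        sel = (jj - ii >= 3) & (jj - ii <= 12)
        dense[ii[sel], jj[sel]] = 1.0
        m = make_banded(dense, min_d=3, band_width=12)
        nb = extract_neighborhood(m, (20, 28), 2, 5)  # d=8, band edges nearby
        # window spans distances 8 +- 10; cells outside [3, 12] are truncated
        assert len(nb.peak) + len(nb.all_background) < 121

    def test_truncated_background_flagged_untestable(self):
        n = 20
        dense = np.zeros((n, n))
        ii, jj = np.triu_indices(n, k=1)
        dense[ii, jj] = 1.0
        m = make_banded(dense, min_d=1, band_width=3)
        nb = extract_neighborhood(m, (10, 12), 2, 5, min_background_elements=25)
        assert not nb.testable


class TestRankSum:
    def exact_one_sided_p(self, peak, bg):
        """Enumeration oracle: P(rank sum of a random subset >= observed)."""
        pooled = np.concatenate([peak, bg])
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        k = len(peak)
        obs = ranks[:k].sum()
        total = 0
        ge = 0
        for subset in combinations(range(len(pooled)), k):
            total += 1
            if ranks[list(subset)].sum() >= obs:
                ge += 1
        return ge / total

    def test_documented_example_1_over_84(self):
        p = rank_sum_greater(np.array([10.0, 11, 12]), np.arange(1.0, 7))
        assert p == pytest.approx(1 / 84)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_for_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9), rng.integers(2, 9)
        # distinct values so the exact path is exercised
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
        peak, bg = vals[:n1], vals[n1:]
        assert rank_sum_greater(peak, bg) == pytest.approx(
            self.exact_one_sided_p(peak, bg), abs=1e-12
        )

    def test_all_equal_values_not_significant(self):
        p = rank_sum_greater(np.full(25, 1.0), np.full(30, 1.0))
        assert p >= 0.5


class TestEvaluateNeighborhood:
    def make_nb(self, peak, hor, ver, cor):
        from nbloop.peak_calling import Neighborhood

        return Neighborhood(
            center=(0, 0),
            peak=np.asarray(peak, float),
            horizontal=np.asarray(hor, float),
            vertical=np.asarray(ver, float),
            corner=np.asarray(cor, float),
            all_background=np.concatenate([hor, ver, cor]).astype(float),
        )

    def test_mean_filter_rejects_before_testing(self):
        nb = self.make_nb([1.0] * 25, [2.0] * 30, [2.0] * 30, [2.0] * 9)
        accepted, ph, pv, pc = evaluate_neighborhood(nb, 0.025)
        assert not accepted and ph == pv == pc == 1.0

    def test_strong_peak_accepted(self):
        rng = np.random.default_rng(9)
        bg = rng.uniform(0.5, 1.5, 30)
        nb = self.make_nb(rng.uniform(5.0, 6.0, 25), bg, bg + 0.01, bg[:9])
        accepted, ph, pv, pc = evaluate_neighborhood(nb, 0.025)
        assert accepted and max(ph, pv, pc) < 0.025

    def test_flat_neighborhood_rejected(self):
        nb = self.make_nb([1.0] * 25, [1.0] * 30, [1.0] * 30, [1.0] * 9)
        accepted, *ps = evaluate_neighborhood(nb, 0.025)
        assert not accepted and min(ps) >= 0.5


class TestCallLoops:
    def test_empty_matrix_returns_empty(self):
        m = BandedContactMatrix("c", 10_000, 100, [], [], [], [], band_width=50)
        assert call_loops(m, LoopCallingConfig()) == []

    def test_unfittable_matrix_returns_empty_with_warning(self, caplog):
        n = 30
        dense = np.zeros((n, n))
        ii, jj = np.triu_indices(n, k=1)
        dense[ii, jj] = 2.0  # constant: every distance degenerate
        m = make_banded(dense)
        with caplog.at_level("WARNING", logger="nbloop.peak_calling"):
            assert call_loops(m, LoopCallingConfig(min_distance=0)) == []
        assert any("usable fit" in r.message for r in caplog.records)

    def test_small_planted_chromosome_recovers_loops(self):
        loops = [(100, 160, 8.0, 2), (300, 420, 8.0, 2), (600, 680, 8.0, 2)]
        matrix, truth = generate_dataset(
            SyntheticSpec(n_bins=800, loops=loops, seed=11)
        )
        calls = call_loops(matrix, LoopCallingConfig())
        precision, recall, _ = score_recovery(calls, truth, tol_bins=2)
        assert recall == 1.0 and precision == 1.0

    def test_accepted_loops_beat_background_mean(self, planted_dataset, planted_calls):
        from nbloop.expected_model import compute_expected, transform_obs_exp

        matrix, _ = planted_dataset
        calls, _ = planted_calls
        oe = transform_obs_exp(matrix, compute_expected(matrix, "nonzero"))
        assert calls
        for lp in calls:
            nb = extract_neighborhood(oe, (lp.bin_i, lp.bin_j), 2, 5)
            assert nb.peak.mean() > nb.all_background.mean()

    def test_output_sorted_by_bins(self, planted_calls):
        calls, _ = planted_calls
        keys = [(lp.bin_i, lp.bin_j) for lp in calls]
        assert keys == sorted(keys)
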