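"""Spike-train dissimilarity measures."""

import numpy as np
import pytest

from spiketopo import (DissimilarityMatrix, SpikeTrainSet, bin_spike_counts,
                       compute_dissimilarity, make_poisson_trains,
                       make_synchronous_trains, pearson_dissimilarity,
                       spike_distance_matrix, spike_distance_value,
                       spike_sync_dissimilarity, spike_sync_value)
from spiketopo.dissimilarity import select_vertices

from oracles import brute_sync_fraction, dense_spike_distance


class TestBinning:
    def test_hand_binned(self):
        ts = SpikeTrainSet(trains=[np.array([0.0, 3.0, 4.0, 9.0])],
                           t_start=0.0, t_end=12.0)
        np.testing.assert_array_equal(bin_spike_counts(ts, 4.0), [[2, 1, 1]])

    def test_partial_bin_dropped(self):
        ts = SpikeTrainSet(trains=[np.array([0.0, 13.0])], t_start=0.0, t_end=14.0)
        counts = bin_spike_counts(ts, 4.0)
        assert counts.shape == (1, 3)
        np.testing.assert_array_equal(counts, [[1, 0, 0]])

    def test_empty_train_zero_row(self):
        ts = SpikeTrainSet(trains=[np.array([]), np.array([1.0, 2.0])],
                           t_start=0.0, t_end=8.0)
        counts = bin_spike_counts(ts, 4.0)
        np.testing.assert_array_equal(counts[0], 0)

    def test_unit_bins_reproduce_raster(self):
        ts = SpikeTrainSet(trains=[np.array([0.0, 2.0, 5.0])], t_start=0.0, t_end=6.0)
        np.testing.assert_array_equal(bin_spike_counts(ts, 1.0),
                                      [[1, 0, 1, 0, 0, 1]])

    def test_rejects_tiny_window(self):
        ts = SpikeTrainSet(trains=[np.array([0.5])], t_start=0.0, t_end=2.0)
        with pytest.raises(ValueError):
            bin_spike_counts(ts, 4.0)


class TestPearson:
    def test_identical_rows_zero(self):
        counts = np.array([[1, 0, 2, 1], [1, 0, 2, 1]])
        D = pearson_dissimilarity(counts)
        assert D.M[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_clipped_to_one(self):
        counts = np.array([[1, 0, 1, 0], [0, 1, 0, 1]])
        D = pearson_dissimilarity(counts)
        assert D.M[0, 1] == pytest.approx(1.0)

    def test_independent_rows_near_one(self, rng):
        counts = (rng.random((2, 10_000)) < 0.2).astype(int)
        D = pearson_dissimilarity(counts)
        assert abs(D.M[0, 1] - 1.0) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_dissimilarity(np.array([[1, 1, 1], [0, 1, 2]]))


class TestSpikeSync:
    def test_identical_trains(self):
        a = np.array([10.0, 50.0, 90.0])
        assert spike_sync_value(a, a, 0, 100) == 1.0

    def test_no_coincidences(self):
        a = np.array([100.0, 200.0, 300.0])
        b = np.array([150.0, 250.0, 350.0])  # gaps 50 = tau, strict < fails
        assert spike_sync_value(a, b, 0, 400) == 0.0

    def test_matches_brute_force_on_poisson_pairs(self):
        for seed in range(20):
            ts = make_poisson_trains(2, rate=15.0, duration=2000.0, seed=seed)
            a, b = ts.trains
            if a.size == 0 or b.size == 0:
                continue
            mine = spike_sync_value(a, b, 0.0, 2000.0)
            brute = brute_sync_fraction(a, b, 0.0, 2000.0)
            assert mine == pytest.approx(brute, abs=1e-12)


class TestSpikeDistance:
    def test_identical_trains_zero(self):
        a = np.array([10.0, 400.0, 900.0])
        assert spike_distance_value(a, a, 0, 1000) == 0.0

    def test_symmetry(self, rng):
        a = np.sort(rng.uniform(0, 500, 12))
        b = np.sort(rng.uniform(0, 500, 9))
        assert spike_distance_value(a, b, 0, 500) == pytest.approx(
            spike_distance_value(b, a, 0, 500), abs=1e-12)

    def test_matches_dense_numerical_integration(self):
        # exact trapezoid over profile breakpoints vs midpoint rule on a
        # dense grid (grid error ~ 1e-5 at this resolution)
        for seed in (0, 1, 2, 3, 4):
            ts = make_poisson_trains(2, rate=20.0, duration=1000.0, seed=seed)
            a, b = ts.trains
            exact = spike_distance_value(a, b, 0.0, 1000.0)
            dense = dense_spike_distance(a, b, 0.0, 1000.0, n_points=100_001)
            assert exact == pytest.approx(dense, abs=5e-5)

    def test_two_singleton_trains_closed_form(self):
        # one spike per train at the window midpoint offset d: the profile
        # is piecewise linear and integrable by hand
        T = 100.0
        a, b = np.array([40.0]), np.array([60.0])
        exact = spike_distance_value(a, b, 0.0, T)
        dense = dense_spike_distance(a, b, 0.0, T, n_points=400_001)
        assert exact == pytest.approx(dense, abs=2e-5)


class TestMatrices:
    @pytest.mark.parametrize("measure", ["pearson", "spike_sync", "spike_distance"])
    def test_invariants_on_random_trains(self, measure):
        ts = make_poisson_trains(8, rate=25.0, duration=2000.0, seed=3)
        D = compute_dissimilarity(ts, measure, bin_ms=4.0)
        M = D.M
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0.0)
        assert M.min() >= 0.0 and M.max() <= 1.0
        assert D.measure == measure

    def test_vertex_selection_drops_sparse_trains(self):
        ts = SpikeTrainSet(
            trains=[np.array([5.0]), np.array([]),
                    np.sort(np.linspace(1, 99, 20)), np.sort(np.linspace(2, 98, 15))],
            t_start=0.0, t_end=100.0)
        idx = select_vertices(ts, bin_ms=4.0)
        assert set(idx) == {2, 3}

    def test_vertex_cap_subsample_is_seeded(self):
        ts = make_poisson_trains(20, rate=20.0, duration=1000.0, seed=1)
        i1 = select_vertices(ts, 4.0, cap=10, rng=np.random.default_rng(5))
        i2 = select_vertices(ts, 4.0, cap=10, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(i1, i2)
        assert i1.size == 10

    def test_measures_can_disagree_on_jittered_synchrony(self):
        # children of one mother train, 2 ms jitter, 4 ms bins: adaptive
        # coincidence windows still match spikes while binned counts
        # decorrelate, so SPIKE-sync sees less dissimilarity than Pearson
        ts = make_synchronous_trains(6, base_rate=10.0, jitter_ms=2.0,
                                     duration=20_000.0, seed=2)
        D_sync = compute_dissimilarity(ts, "spike_sync", bin_ms=4.0)
        D_pear = compute_dissimilarity(ts, "pearson", bin_ms=4.0)
        iu = np.triu_indices(D_sync.n, k=1)
        assert D_sync.M[iu].mean() < D_pear.M[iu].mean()

    def test_round_trip(self, tmp_path):
        ts = make_poisson_trains(5, rate=20.0, duration=1000.0, seed=4)
        D = compute_dissimilarity(ts, "spike_distance", bin_ms=4.0)
        path = tmp_path / "d.csv"
        D.save(path)
        D2 = DissimilarityMatrix.load(path)
        np.testing.assert_allclose(D.M, D2.M, atol=1e-15)
        np.testing.assert_array_equal(D.vertex_ids, D2.vertex_ids)
        assert D2.measure == "spike_distance"
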