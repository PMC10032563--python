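"""Free-energy landscapes and k-means conformational clusters."""

import numpy as np
import pytest

import taur2 as t
from taur2.constants import BOLTZMANN_KCAL
from taur2.fel import FelError, representative_frame_for

KBT310 = BOLTZMANN_KCAL * 310.0


class TestBuildFel:
    def test_single_occupied_bin_is_zero_rest_undefined(self):
        x = np.full(50, 1.0)
        y = np.full(50, 2.0)
        grid = t.build_fel(x, y, bins=4)
        occupied = grid.occupied
        assert occupied.sum() == 1
        assert grid.delta_g[occupied][0] == 0.0
        assert np.isnan(grid.delta_g[~occupied]).all()

    def test_two_bin_population_ratio_closed_form(self):
        # 80/20 split over two bins: ddG = kBT ln 4
        x = np.array([0.25] * 80 + [0.75] * 20)
        y = np.zeros(100)
        grid = t.build_fel(x, y, bins=(2, 2), ranges=((0, 1), (-1, 1)))
        vals = grid.delta_g[np.isfinite(grid.delta_g)]
        ddg = vals.max() - vals.min()
        assert ddg == pytest.approx(KBT310 * np.log(4.0), rel=1e-9)

    def test_uniform_occupancy_all_zero(self):
        x = np.array([0.1, 0.9] * 10)
        y = np.array([0.1] * 10 + [0.9] * 10)
        grid = t.build_fel(x, y, bins=(2, 2), ranges=((0, 1), (0, 1)))
        assert np.allclose(grid.delta_g, 0.0)

    def test_invariant_under_frame_duplication(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 300))
        g1 = t.build_fel(x, y, bins=10,
                         ranges=((-3, 3), (-3, 3))).delta_g
        g2 = t.build_fel(np.tile(x, 2), np.tile(y, 2), bins=10,
                         ranges=((-3, 3), (-3, 3))).delta_g
        assert np.allclose(np.nan_to_num(g1), np.nan_to_num(g2), atol=1e-12)

    def test_zero_width_range_rejected(self):
        with pytest.raises(FelError):
            t.build_fel([1.0, 2.0], [1.0, 2.0], bins=4,
                        ranges=((1, 1), (0, 2)))

    def test_minimum_is_always_zero(self):
        rng = np.random.default_rng(1)
        grid = t.build_fel(rng.normal(size=500), rng.normal(size=500),
                           bins=8)
        assert np.nanmin(grid.delta_g) == 0.0


class TestKmeans:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([
            rng.normal((1.0, 1.0), 0.05, (500, 2)),
            rng.normal((2.0, 2.0), 0.05, (500, 2)),
        ])
        cs = t.kmeans_cluster(pts, 2, seed=1)
        centers = cs.centers[np.argsort(cs.centers[:, 0])]
        assert centers[0] == pytest.approx((1.0, 1.0), abs=0.05)
        assert centers[1] == pytest.approx((2.0, 2.0), abs=0.05)
        assert cs.populations == pytest.approx((0.5, 0.5), abs=0.02)

    def test_single_cluster_is_centroid(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(100, 2))
        cs = t.kmeans_cluster(pts, 1, seed=0)
        assert cs.centers[0] == pytest.approx(pts.mean(axis=0), abs=1e-9)
        assert cs.populations[0] == 1.0

    def test_k_equals_n_distinct_points_exact_fit(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [2, 2]])
        cs = t.kmeans_cluster(pts, 5, seed=0)
        assert cs.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_above_distinct_points_rejected(self):
        pts = np.array([[0.0, 0], [0.0, 0], [1.0, 1]])
        with pytest.raises(FelError):
            t.kmeans_cluster(pts, 3, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(200, 2))
        a = t.kmeans_cluster(pts, 3, seed=7)
        b = t.kmeans_cluster(pts, 3, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.representative_frames,
                              b.representative_frames)

    def test_populations_sum_to_one(self):
        rng = np.random.default_rng(4)
        cs = t.kmeans_cluster(rng.normal(size=(123, 2)), 4, seed=0)
        assert cs.populations.sum() == pytest.approx(1.0, abs=1e-9)


class TestRepresentativeFrame:
    def test_singleton_cluster_returns_its_frame(self):
        z = np.array([[0.0, 0], [5.0, 5.0]])
        labels = np.array([0, 1])
        centers = np.array([[0.0, 0], [5.0, 5.0]])
        assert representative_frame_for(z, labels, centers, 1) == 1

    def test_closest_member_wins(self):
        z = np.array([[0.1, 0], [0.2, 0], [0.3, 0]])
        labels = np.zeros(3, dtype=int)
        centers = np.array([[0.0, 0.0]])
        assert representative_frame_for(z, labels, centers, 0) == 0

    def test_tie_breaks_to_smaller_index(self):
        z = np.array([[1.0, 0], [-1.0, 0], [5.0, 0]])
        labels = np.array([0, 0, 0])
        centers = np.array([[0.0, 0.0]])
        assert representative_frame_for(z, labels, centers, 0) == 0

    def test_representative_belongs_to_its_cluster(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(150, 2))
        cs = t.kmeans_cluster(pts, 3, seed=2)
        for c in range(3):
            rep = cs.representative_frames[c]
            assert cs.labels[rep] == c
            assert t.representative_frame(pts, cs, c) == rep

    def test_empty_cluster_rejected(self):
        z = np.array([[0.0, 0]])
        with pytest.raises(FelError):
            representative_frame_for(z, np.array([0]),
                                     np.array([[0.0, 0], [1.0, 1]]), 1)


class TestTwoStateRecovery:
    def test_fel_basin_depth_matches_mixture_weights(self):
        # sample a two-state mixture and read the basin free-energy gap
        # back off the landscape: ddG = kBT ln(p/(1-p))
        rng = np.random.default_rng(6)
        p = 0.7
        n = 4000
        labels = rng.random(n) < p
        x = np.where(labels, rng.normal(1.0, 0.1, n), rng.normal(2.5, 0.1, n))
        y = np.where(labels, rng.normal(0.9, 0.05, n), rng.normal(1.2, 0.05, n))
        grid = t.build_fel(x, y, bins=40, temperature=310.0)
        # basin population = total histogram mass nearer each center
        xc = 0.5 * (grid.axis1_edges[:-1] + grid.axis1_edges[1:])
        p_grid = np.exp(-np.nan_to_num(grid.delta_g, nan=np.inf) / KBT310)
        p_grid /= p_grid.sum()
        mass1 = p_grid[xc < 1.75, :].sum()
        ddg = KBT310 * np.log(mass1 / (1 - mass1))
        want = KBT310 * np.log(p / (1 - p))
        # binomial Monte-Carlo error on ln(p/(1-p)) is ~1/sqrt(n p (1-p))
        mc_sigma = KBT310 / np.sqrt(n * p * (1 - p))
        assert abs(ddg - want) < 4 * mc_sigma
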