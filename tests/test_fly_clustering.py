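"""X-means, simplex nulls, distance/KL individuality, subsample prediction."""

import numpy as np
import pytest

from flywalk.fly_clustering import (
    ClusterModel,
    distance_and_kl,
    simplex_null,
    subsample_prediction,
    voronoi_chance,
    xmeans,
)
from flywalk.state_analysis import StateSequence


def blobs(seed=0, n_per=17, centers=((0.9, 0.1), (0.1, 0.9)), spread=0.005,
          dim=10):
    """Tight occupancy blobs: isotropic noise within the simplex plane."""
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for ci, c in enumerate(centers):
        base = np.full(dim, (1.0 - sum(c)) / (dim - len(c)))
        base[: len(c)] = c
        eps = spread * rng.standard_normal((n_per, dim))
        eps -= eps.mean(axis=1, keepdims=True)  # stay on the sum=1 plane
        p = np.clip(base + eps, 1e-9, None)
        pts.append(p / p.sum(axis=1, keepdims=True))
        labels += [ci] * n_per
    return np.vstack(pts), np.array(labels)


class TestXMeans:
    def test_two_separated_blobs(self):
        pts, truth = blobs(seed=0)
        model = xmeans(pts, seed=0)
        assert model.k == 2
        # Perfect recovery up to label permutation.
        first = model.labels[truth == 0]
        second = model.labels[truth == 1]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_identical_points_give_single_cluster(self):
        pts = np.tile(np.full(10, 0.1), (20, 1))
        assert xmeans(pts, seed=0).k == 1

    def test_t_score_follows_bic_increment(self):
        pts, _ = blobs(seed=2)
        model = xmeans(pts, seed=0)
        n = pts.shape[0]
        t_sq = model.bic_curve[0] - model.bic_curve[1] + np.log(n)
        assert model.t_scores[1] == pytest.approx(np.sqrt(max(t_sq, 0)))
        # For N=34 the acceptance rule needs a BIC drop above
        # 3.86^2 - ln(34) ~ 11.37.
        assert 3.86**2 - np.log(34) == pytest.approx(11.373, abs=5e-3)

    def test_order_invariance(self):
        pts, _ = blobs(seed=3)
        rng = np.random.default_rng(4)
        perm = rng.permutation(pts.shape[0])
        a = xmeans(pts, seed=5)
        b = xmeans(pts[perm], seed=5)
        assert a.k == b.k
        np.testing.assert_allclose(
            np.sort(a.centroids, axis=0), np.sort(b.centroids, axis=0),
            atol=1e-8,
        )


class TestSimplexNull:
    def test_sample_lies_on_simplex(self):
        sample, _ = simplex_null(n=34, dim=10, seed=0)
        assert np.all(sample >= 0)
        np.testing.assert_allclose(sample.sum(axis=1), 1.0, atol=1e-12)

    def test_flat_dirichlet_mean(self):
        rng = np.random.default_rng(1)
        draws = rng.dirichlet(np.ones(10), size=100_000)
        se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - 0.1) < 3 * se)

    def test_null_rarely_clusters(self):
        ks = [simplex_null(n=34, dim=10, seed=s, n_init=10)[1].k
              for s in range(20)]
        assert sum(k == 1 for k in ks) >= 19


class TestDistanceKL:
    def test_identical_flies(self):
        occ = np.tile(np.full(10, 0.1), (5, 1))
        res = distance_and_kl(occ, [occ])
        np.testing.assert_allclose(res.empirical_distances, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.kl_from_average, 0.0, atol=1e-12)

    def test_kl_nonnegative(self):
        rng = np.random.default_rng(2)
        occ = rng.dirichlet(np.ones(10), size=20)
        res = distance_and_kl(occ, [])
        assert np.all(res.kl_from_average >= 0)

    def test_kl_handles_zero_entries(self):
        occ = np.array([[0.5, 0.5, 0.0, 0.0], [0.25, 0.25, 0.25, 0.25]])
        res = distance_and_kl(occ, [], n_frames=1000)
        assert np.all(np.isfinite(res.kl_from_average))

    def test_clustered_flies_are_more_spread_than_shared_null(self):
        rng = np.random.default_rng(3)
        shared = rng.dirichlet(np.full(10, 50.0), size=34)
        centers = np.eye(10)[:4] * 30 + 1.0
        clustered = np.vstack(
            [rng.dirichlet(c, size=9) for c in centers]
        )[:34]
        d_shared = distance_and_kl(shared, []).empirical_distances
        d_clustered = distance_and_kl(clustered, []).empirical_distances
        assert np.median(d_shared) < np.median(d_clustered)

    def test_ranksum_detects_narrow_null(self):
        rng = np.random.default_rng(4)
        emp = rng.dirichlet(np.ones(10), size=34)
        null_sets = [rng.dirichlet(np.full(10, 200.0), size=34)
                     for _ in range(10)]
        res = distance_and_kl(emp, null_sets)
        assert res.ranksum_p < 1e-10


class TestSubsamplePrediction:
    def _clustered_seqs(self, seed=0):
        rng = np.random.default_rng(seed)
        pts, truth = blobs(seed=seed, n_per=6, spread=0.01)
        model = xmeans(pts, seed=seed)
        seqs = []
        for occ in pts:
            labels = rng.choice(10, size=3000, p=occ) + 1
            seqs.append(
                StateSequence(hl=labels, ll=np.ones_like(labels),
                              confidence=np.full(labels.size, 0.99))
            )
        return seqs, model

    def test_single_cluster_chance_and_accuracy_one(self):
        rng = np.random.default_rng(5)
        seqs, _ = self._clustered_seqs()
        single = ClusterModel(
            k=1,
            centroids=np.full((1, 10), 0.1),
            labels=np.ones(len(seqs), dtype=int),
            bic_curve=np.zeros(1),
            t_scores=np.zeros(1),
        )
        df = subsample_prediction(seqs, single, [1.0], reps=3, seed=0,
                                  chance_draws=1000)
        assert df["accuracy"].iloc[0] == 1.0
        assert df["chance"].iloc[0] == 1.0

    def test_full_duration_bin_recovers_everything(self):
        seqs, model = self._clustered_seqs(seed=1)
        df = subsample_prediction(seqs, model, [1000.0], reps=2, seed=1,
                                  chance_draws=1000)
        assert df["accuracy"].iloc[0] == 1.0
        assert bool(df["uses_full_sequence"].iloc[0])

    def test_accuracy_grows_with_bin_duration(self):
        seqs, model = self._clustered_seqs(seed=2)
        df = subsample_prediction(
            seqs, model, [0.2, 2.0, 100.0], method=2, reps=20, seed=2,
            chance_draws=2000,
        )
        acc = df["accuracy"].to_numpy()
        assert acc[-1] >= acc[0]
        assert acc[-1] > df["chance"].iloc[0]


class TestVoronoiChance:
    def test_symmetric_two_cluster_chance(self):
        # Mirror-image centroids cover equal halves of the simplex, so
        # the chance level reduces to sum x_i^2 = 0.5 for equal sizes.
        centroids = np.array(
            [[0.4, 0.1, 0.1, 0.1, 0.3], [0.3, 0.1, 0.1, 0.1, 0.4]]
        )
        model = ClusterModel(
            k=2, centroids=centroids,
            labels=np.array([1] * 10 + [2] * 10),
            bic_curve=np.zeros(2), t_scores=np.zeros(2),
        )
        chance = voronoi_chance(model, n_draws=200_000, seed=0)
        assert chance == pytest.approx(0.5, abs=0.01)
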