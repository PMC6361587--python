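"""Clustering flies by their HL-state occupancy vectors.

X-means (k-means plus a BIC-based choice of cluster count with a
t-score acceptance rule) identifies discrete locomotor types; a flat
Dirichlet null on the occupancy simplex checks that the rule does not
hallucinate clusters; pairwise distances and KL divergences quantify
how far individual flies sit from the average fly; and subsampled state
sequences measure how little data suffices to re-identify a fly's
cluster.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import ranksums
from sklearn.cluster import KMeans

from .state_analysis import StateSequence, run_length_encode

__all__ = [
    "ClusterModel",
    "xmeans",
    "simplex_null",
    "distance_and_kl",
    "DistanceKLResult",
    "voronoi_chance",
    "subsample_prediction",
]

T_MIN = 3.86  # t-score threshold (p < 0.05) for accepting an extra cluster
BIC_WINDOW = 0.05  # accepted K must be within 5% of the minimum BIC


@dataclass
class ClusterModel:
    """X-means result on occupancy vectors."""

    k: int
    centroids: np.ndarray  # (k, dim)
    labels: np.ndarray  # (n,) in [1..k]
    bic_curve: np.ndarray  # BIC for K = 1..k_max
    t_scores: np.ndarray  # t for the increment (K-1 -> K); t_scores[0] = nan

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean) labels, 1-based."""
        return cdist(np.atleast_2d(points), self.centroids).argmin(axis=1) + 1


def _kmeans_bic(points: np.ndarray, k: int, seed: int, n_init: int):
    """Spherical-Gaussian BIC = -2 log L + params ln(n) for a k-means fit."""
    n, d = points.shape
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(points)
    rss = km.inertia_
    if n <= k or rss <= 0:
        return -np.inf, km  # degenerate: perfect fit
    var = rss / (d * (n - k))
    sizes = np.bincount(labels, minlength=k).astype(float)
    sizes = sizes[sizes > 0]
    log_l = (
        np.sum(sizes * np.log(sizes)) - n * np.log(n)
        - 0.5 * n * d * np.log(2.0 * np.pi * var)
        - 0.5 * d * (n - k)
    )
    n_params = (k - 1) + k * d + 1
    return -2.0 * log_l + n_params * np.log(n), km


def xmeans(
    points: np.ndarray,
    t_min: float = T_MIN,
    bic_window: float = BIC_WINDOW,
    seed: int = 0,
    k_max: int | None = None,
    n_init: int = 50,
) -> ClusterModel:
    """Choose the cluster count by BIC with the t-score acceptance rule.

    k-means is fit for K = 1..k_max; the t statistic for each increment
    follows ``BIC_K - BIC_{K+1} = t^2 - ln(N)`` (natural log).  The
    chosen K is the largest whose incremental t exceeds ``t_min`` (3.86,
    p < 0.05) *and* whose BIC lies within ``bic_window`` (5%) of the
    minimum; if no increment qualifies, K = 1.

    The fit is made order-invariant by running k-means on a canonically
    sorted copy of the points with a seed mixed from the data bytes.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    k_max = min(k_max or 10, n - 1)
    if np.ptp(points, axis=0).max() == 0:  # all points identical
        return ClusterModel(
            k=1,
            centroids=points[:1].copy(),
            labels=np.ones(n, dtype=int),
            bic_curve=np.array([-np.inf]),
            t_scores=np.array([np.nan]),
        )
    order = np.lexsort(points.T[::-1])
    sorted_pts = points[order]
    eff_seed = (seed + zlib.crc32(np.ascontiguousarray(sorted_pts).tobytes())) % (2**31)

    bics = np.full(k_max, np.nan)
    fits = []
    for k in range(1, k_max + 1):
        bics[k - 1], km = _kmeans_bic(sorted_pts, k, eff_seed, n_init)
        fits.append(km)
    finite = np.where(np.isfinite(bics), bics, np.inf)
    t_scores = np.full(k_max, np.nan)
    for k in range(2, k_max + 1):
        t_sq = bics[k - 2] - bics[k - 1] + np.log(n)
        t_scores[k - 1] = np.sqrt(t_sq) if t_sq > 0 else 0.0
    # Growth stops at the first non-significant increment; the 5% window
    # is taken over the models still in play (K up to that point).
    reachable = 1
    for k in range(2, k_max + 1):
        if not t_scores[k - 1] > t_min:
            break
        reachable = k
    bic_min = finite[:reachable].min()
    window_hi = bic_min + bic_window * abs(bic_min)
    chosen = 1
    for k in range(2, reachable + 1):
        if t_scores[k - 1] > t_min and finite[k - 1] <= window_hi:
            chosen = k
    km = fits[chosen - 1]
    labels = cdist(points, km.cluster_centers_).argmin(axis=1) + 1
    return ClusterModel(
        k=chosen,
        centroids=km.cluster_centers_.copy(),
        labels=labels,
        bic_curve=bics,
        t_scores=t_scores,
    )


def simplex_null(
    n: int = 34, dim: int = 10, seed: int = 0, **xmeans_kwargs
):
    """X-means on a flat-Dirichlet sample from the occupancy simplex.

    Under the uniform null there is no cluster structure, so the
    expected outcome is K = 1.  Returns ``(sample, ClusterModel)``.
    """
    rng = np.random.default_rng(seed)
    sample = rng.dirichlet(np.ones(dim), size=n)
    return sample, xmeans(sample, seed=seed, **xmeans_kwargs)


@dataclass
class DistanceKLResult:
    """Fly-to-fly distances vs a synthetic null, plus per-fly KL."""

    empirical_distances: np.ndarray
    synthetic_distances: np.ndarray  # pooled over synthetic sets
    ranksum_stat: float
    ranksum_p: float
    kl_from_average: np.ndarray  # KL(average fly || individual fly)


def _kl(p: np.ndarray, q: np.ndarray, n_frames: float) -> float:
    q = q.copy()
    zero = q <= 0
    if zero.any():
        q[zero] = 1.0 / (2.0 * n_frames)
        q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def distance_and_kl(
    occ: np.ndarray,
    synthetic_sets: list,
    n_frames=None,
) -> DistanceKLResult:
    """Compare empirical fly-to-fly spread with a synthetic null.

    ``occ`` is the (n_flies, n_states) occupancy matrix; each element of
    ``synthetic_sets`` is a matrix of synthetic flies.  All pairwise
    Euclidean distances are compared with a two-sided rank-sum test, and
    the KL divergence from the average fly to each individual fly is
    reported (zero entries in the individual's distribution receive a
    pseudo-mass of 1/(2 n_frames) before renormalizing).
    """
    occ = np.asarray(occ, dtype=float)
    n_flies = occ.shape[0]
    if n_frames is None:
        n_frames = np.full(n_flies, 10_800.0)
    n_frames = np.broadcast_to(np.asarray(n_frames, dtype=float), (n_flies,))
    emp = pdist(occ)
    syn = (
        np.concatenate([pdist(np.asarray(s, dtype=float)) for s in synthetic_sets])
        if synthetic_sets
        else np.empty(0)
    )
    if syn.size:
        stat, p = ranksums(emp, syn)
    else:
        stat, p = np.nan, np.nan
    avg = occ.mean(axis=0)
    kl = np.array(
        [_kl(avg, occ[i], n_frames[i]) for i in range(n_flies)]
    )
    return DistanceKLResult(
        empirical_distances=emp,
        synthetic_distances=syn,
        ranksum_stat=float(stat),
        ranksum_p=float(p),
        kl_from_average=kl,
    )


def voronoi_chance(
    clusters: ClusterModel, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Chance level of nearest-centroid assignment: E = sum_i x_i p_i.

    ``x_i`` is the probability of a fly belonging to cluster i (cluster
    size fraction) and ``p_i`` the fraction of the uniform occupancy
    simplex falling in centroid i's Voronoi cell, estimated by Monte
    Carlo with flat-Dirichlet draws.
    """
    if clusters.k == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    dim = clusters.centroids.shape[1]
    draws = rng.dirichlet(np.ones(dim), size=n_draws)
    cell = cdist(draws, clusters.centroids).argmin(axis=1)
    p = np.bincount(cell, minlength=clusters.k) / n_draws
    x = np.bincount(clusters.labels - 1, minlength=clusters.k).astype(float)
    x /= x.sum()
    return float(np.sum(x * p))


def _sample_labels(hl: np.ndarray, n_frames: int, method: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_frames`` of HL labels by one of the four bin methods."""
    total = hl.size
    if n_frames >= total:
        return hl
    if method == 1:  # stitch randomly sampled dwell segments
        runs = run_length_encode(hl)
        out = []
        got = 0
        while got < n_frames:
            label, start, length = runs[rng.integers(0, len(runs))]
            take = min(length, n_frames - got)
            out.append(np.full(take, label))
            got += take
        return np.concatenate(out)
    if method == 2:  # one random window
        start = int(rng.integers(0, total - n_frames + 1))
        return hl[start : start + n_frames]
    if method == 3:  # from the first time point
        return hl[:n_frames]
    if method == 4:  # from the last time point, backwards
        return hl[-n_frames:]
    raise ValueError(f"unknown sampling method {method}")


def subsample_prediction(
    seqs: list,
    clusters: ClusterModel,
    bin_durations_s,
    method: int = 1,
    reps: int = 100,
    fps: float = 30.0,
    seed: int = 0,
    chance_draws: int = 100_000,
) -> pd.DataFrame:
    """How well short subsamples re-identify each fly's cluster.

    For each bin duration, HL labels are subsampled per fly (one of
    four methods), the subsample's state distribution is assigned to the
    nearest cluster centroid, and the fraction of flies recovering their
    full-data cluster is averaged over ``reps`` repetitions.  Bins
    longer than a fly's sequence use the whole sequence (flagged).
    Chance comes from the cluster-size/Voronoi-cell formula.
    """
    rng = np.random.default_rng(seed)
    n_states = clusters.centroids.shape[1]
    label_arrays = []
    for s in seqs:
        hl = s.hl[s.assigned] if isinstance(s, StateSequence) else np.asarray(s)
        hl = hl[hl > 0]
        if hl.size == 0:
            raise ValueError("a fly has no assigned frames")
        label_arrays.append(hl)
    chance = voronoi_chance(clusters, n_draws=chance_draws, seed=seed)
    rows = []
    for dur in np.atleast_1d(bin_durations_s):
        n_frames = max(1, int(round(dur * fps)))
        truncated = any(n_frames >= hl.size for hl in label_arrays)
        acc = np.empty(reps)
        for rep in range(reps):
            correct = 0
            for i, hl in enumerate(label_arrays):
                sample = _sample_labels(hl, n_frames, method, rng)
                p = np.bincount(sample, minlength=n_states + 1)[1:] / sample.size
                if clusters.assign(p)[0] == clusters.labels[i]:
                    correct += 1
            acc[rep] = correct / len(label_arrays)
        rows.append(
            {
                "bin_s": float(dur),
                "accuracy": acc.mean(),
                "accuracy_sd": acc.std(),
                "chance": chance,
                "uses_full_sequence": truncated,
            }
        )
    return pd.DataFrame(rows)
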