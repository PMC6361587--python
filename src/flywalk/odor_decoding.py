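"""Decoding odor presence from binned HL-state distributions.

The data are cut into short time bins (1 s = 30 frames by default);
each bin is summarized by its HL-state fraction vector, classes
(before vs during odor) are balanced by seeded random removal so chance
is exactly 50%, the vectors are reduced to the principal components
explaining 90% of the variance, and a logistic (logit) model predicts
whether the bin comes from the odor period.  Decoders can be fit for
the whole population, per cluster of flies, or per individual fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .odor_stats import B_I, B_O, D_I, D_O, ScenarioLabels
from .state_analysis import StateSequence, UNASSIGNED

__all__ = [
    "BinTable",
    "DecodingResult",
    "build_bins",
    "build_observable_bins",
    "fit_decoder",
    "compare_decoders",
    "reconfigure_clusters",
    "ReconfigureResult",
]

FPS = 30
ZONES = {"inside": (B_I, D_I), "outside": (B_O, D_O)}


@dataclass
class BinTable:
    """Balanced per-bin feature vectors with before/during labels."""

    x: np.ndarray  # (n_bins, n_features)
    y: np.ndarray  # 0 = before, 1 = during
    zone: str = ""
    unit: str = ""
    ok: bool = True

    @property
    def n_bins(self) -> int:
        return self.x.shape[0]

    @staticmethod
    def concatenate(tables: list) -> "BinTable":
        tables = [t for t in tables if t is not None and t.ok]
        return BinTable(
            x=np.concatenate([t.x for t in tables]),
            y=np.concatenate([t.y for t in tables]),
            zone=tables[0].zone if tables else "",
            unit="population",
        )


def _chunk_indices(idx: np.ndarray, bin_frames: int):
    n_full = idx.size // bin_frames
    for b in range(n_full):
        yield idx[b * bin_frames : (b + 1) * bin_frames]


def _balance(x_before, x_during, rng):
    n = min(len(x_before), len(x_during))
    keep_b = rng.choice(len(x_before), size=n, replace=False)
    keep_d = rng.choice(len(x_during), size=n, replace=False)
    x = np.concatenate([np.asarray(x_before)[keep_b], np.asarray(x_during)[keep_d]])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return x, y


def build_bins(
    seq: StateSequence,
    labels: ScenarioLabels,
    n_states: int,
    zone: str = "inside",
    bin_s: float = 1.0,
    seed: int = 0,
    fps: float = FPS,
    max_unassigned_frac: float = 0.5,
    unit: str = "",
) -> BinTable | None:
    """HL-state fraction vectors for before/during bins in one zone.

    Frames belonging to the zone's before (B) and during (D) scenarios
    are cut into consecutive ``bin_s``-second bins; each bin's feature
    vector is the fraction of its frames spent in each HL state
    (unassigned frames count in the denominator, so vectors sum to at
    most one).  Bins with more than ``max_unassigned_frac`` unassigned
    frames are dropped, and the two classes are balanced by seeded
    random removal.  Returns ``None`` when either class has fewer than
    two usable bins (the unit is excluded).
    """
    before_code, during_code = ZONES[zone]
    codes = labels.for_observables()
    if codes.size != len(seq):
        raise ValueError("scenario labels do not match state sequence")
    rng = np.random.default_rng(seed)
    bin_frames = max(1, int(round(bin_s * fps)))
    per_class = {}
    for name, code in (("before", before_code), ("during", during_code)):
        vecs = []
        idx = np.flatnonzero(codes == code)
        for chunk in _chunk_indices(idx, bin_frames):
            hl = seq.hl[chunk]
            frac_unassigned = np.mean(hl == UNASSIGNED)
            if frac_unassigned > max_unassigned_frac:
                continue
            counts = np.bincount(hl[hl != UNASSIGNED], minlength=n_states + 1)[1:]
            vecs.append(counts / hl.size)
        per_class[name] = vecs
    if len(per_class["before"]) < 2 or len(per_class["during"]) < 2:
        return None
    x, y = _balance(per_class["before"], per_class["during"], rng)
    return BinTable(x=x, y=y, zone=zone, unit=unit)


def build_observable_bins(
    features: np.ndarray,
    labels: ScenarioLabels,
    zone: str = "inside",
    bin_s: float = 1.0,
    seed: int = 0,
    fps: float = FPS,
    unit: str = "",
) -> BinTable | None:
    """Per-bin mean feature vectors (e.g. speed and curvature).

    The counterpart of :func:`build_bins` for decoding from raw
    kinematics instead of HL-state usage; frames with non-finite
    features are ignored within a bin.
    """
    before_code, during_code = ZONES[zone]
    codes = labels.for_observables()
    features = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    bin_frames = max(1, int(round(bin_s * fps)))
    per_class = {}
    for name, code in (("before", before_code), ("during", during_code)):
        vecs = []
        idx = np.flatnonzero(codes == code)
        for chunk in _chunk_indices(idx, bin_frames):
            vals = features[chunk]
            vals = vals[np.isfinite(vals).all(axis=1)]
            if vals.shape[0] == 0:
                continue
            vecs.append(vals.mean(axis=0))
        per_class[name] = vecs
    if len(per_class["before"]) < 2 or len(per_class["during"]) < 2:
        return None
    x, y = _balance(per_class["before"], per_class["during"], rng)
    return BinTable(x=x, y=y, zone=zone, unit=unit)


@dataclass
class DecodingResult:
    """In-sample performance of one logit decoder."""

    unit: str
    zone: str
    p_correct: float
    n_bins: int
    pcs_used: int
    separation_flagged: bool = False


def fit_decoder(
    bins: BinTable,
    var_threshold: float = 0.90,
    seed: int = 0,
    cross_validate: bool = False,
    ridge_c: float = 1e4,
) -> DecodingResult:
    """PCA-reduce the bin vectors and fit a logit model.

    The smallest number of principal components cumulatively explaining
    more than ``var_threshold`` of the variance is kept.  The reported
    ``p_correct`` is the fraction of bins whose predicted class
    probability exceeds 0.5 on the correct side; by default it is
    evaluated in sample (set ``cross_validate`` for 5-fold CV instead).
    A weak ridge penalty keeps perfectly separable problems finite; fits
    hitting effectively perfect separation are flagged.
    """
    if not bins.ok or bins.n_bins < 4:
        raise ValueError("bin table unusable for decoding")
    pca = PCA()
    scores = pca.fit_transform(bins.x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pc = int(np.searchsorted(cum, var_threshold) + 1)
    n_pc = min(n_pc, scores.shape[1])
    z = scores[:, :n_pc]
    clf = LogisticRegression(C=ridge_c, max_iter=2000, random_state=seed)
    if cross_validate:
        from sklearn.model_selection import cross_val_predict

        pred = cross_val_predict(clf, z, bins.y, cv=5)
        clf.fit(z, bins.y)
    else:
        clf.fit(z, bins.y)
        pred = clf.predict(z)
    p_correct = float(np.mean(pred == bins.y))
    margin = np.abs(clf.decision_function(z))
    return DecodingResult(
        unit=bins.unit,
        zone=bins.zone,
        p_correct=p_correct,
        n_bins=bins.n_bins,
        pcs_used=n_pc,
        separation_flagged=bool(np.min(margin) > 10.0),
    )


def compare_decoders(m1: np.ndarray, m2: np.ndarray):
    """Paired comparison of two decoders' per-fly accuracies.

    ``D_j = (M1_j - M2_j) / sqrt(2)`` is each fly's perpendicular
    distance from the unity line; a two-sided Wilcoxon signed-rank test
    on the distances gives the p-value.  Returns ``(d, p_value)``.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("decoders cover different flies")
    d = (m1 - m2) / np.sqrt(2.0)
    if np.all(d == 0):
        return d, 1.0
    _, p = wilcoxon(d, alternative="two-sided")
    return d, float(p)


@dataclass
class ReconfigureResult:
    labels: np.ndarray  # updated 1-based cluster labels
    moved: list  # indices of reassigned flies
    total_accuracy_before: float
    total_accuracy_after: float


def reconfigure_clusters(
    labels: np.ndarray,
    accuracy: np.ndarray,
    n_movers: int = 6,
    large_cluster_min: int = 11,
) -> ReconfigureResult:
    """Move poorly decoded flies out of large clusters.

    ``accuracy[i, j]`` is fly i's decoding accuracy under cluster j's
    decoder.  Up to ``n_movers`` flies are taken from clusters with more
    than ten members (``large_cluster_min`` = 11), worst own-cluster
    accuracy first, and each is greedily reassigned to the cluster that
    maximizes its accuracy — maximizing the summed predictive power
    across flies.  With no large cluster, nothing moves.
    """
    labels = np.asarray(labels, dtype=int).copy()
    accuracy = np.asarray(accuracy, dtype=float)
    n_flies, k = accuracy.shape
    own = accuracy[np.arange(n_flies), labels - 1]
    before_total = float(own.sum())
    sizes = np.bincount(labels, minlength=k + 1)
    large = np.flatnonzero(sizes >= large_cluster_min)
    candidates = [i for i in range(n_flies) if labels[i] in large]
    candidates.sort(key=lambda i: own[i])
    moved = []
    for i in candidates[:n_movers]:
        best = int(np.argmax(accuracy[i])) + 1
        if best != labels[i]:
            labels[i] = best
            moved.append(i)
    after_total = float(accuracy[np.arange(n_flies), labels - 1].sum())
    return ReconfigureResult(
        labels=labels,
        moved=moved,
        total_accuracy_before=before_total,
        total_accuracy_after=after_total,
    )
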