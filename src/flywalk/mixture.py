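"""Mixture of HHMMs: clustering flies by how well models explain them.

Every fly is first fit with its own HHMM; the per-fly models are
grouped by a Gaussian mixture on their expected low-level state usage,
giving the initial clusters.  A top-layer categorical assignment
(Dirichlet-process flavored, concentration 1 by default) then
probabilistically attaches each fly to a cluster model, the cluster
models are updated by responsibility-weighted variational EM, and a
perturbation schedule of cluster pruning, splitting and reassignment
guards against local optima before a final EM run to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .hhmm import (
    HHMMPosterior,
    HHMMPriors,
    HHMMSpec,
    _param_kl,
    e_step,
    vbem_fit,
    vbem_step,
)

__all__ = ["MixtureConfig", "MixtureState", "init_per_fly", "fit_mixture",
           "assign_flies"]


@dataclass
class MixtureConfig:
    """Schedule and fitting knobs for the HHMM mixture."""

    max_clusters: int = 8
    n_rounds: int = 10  # perturbation rounds
    em_iters: int = 10  # EM iterations after each perturbation
    concentration: float = 1.0  # Dirichlet-process concentration
    final_max_iters: int = 100
    tol: float = 1e-6
    seed: int = 0
    per_fly_restarts: int = 2
    per_fly_max_iter: int = 50
    cluster_vbem_iters: int = 1  # model-update sweeps per EM iteration
    use_schedule: bool = True
    used_threshold: float = 0.5  # responsibility defining a "used" cluster


@dataclass
class MixtureState:
    """Responsibilities, per-cluster models and the schedule history."""

    z: np.ndarray  # (n_flies, k) responsibilities, rows sum to 1
    models: list  # k HHMMPosterior
    xs: list  # per-fly (T, 2) standardized observation arrays
    usage: np.ndarray  # (n_flies, n_joint) expected LL-state usage
    schedule_log: list = field(default_factory=list)
    evidence_trace: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.models)

    @property
    def n_flies(self) -> int:
        return len(self.xs)

    def hard_labels(self) -> np.ndarray:
        """1-based argmax labels; ties break toward the lower index."""
        return self.z.argmax(axis=1) + 1


def _standardized(obs_list):
    xs = []
    for o in obs_list:
        x = o.as_matrix() if hasattr(o, "as_matrix") else np.asarray(o, float)
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        xs.append((x - mu) / sd)
    return xs


def _usage_vector(x, post: HHMMPosterior) -> np.ndarray:
    """Expected LL-state usage, in canonical (emission-sorted) state order.

    Per-fly models label their states arbitrarily; sorting joint states
    by their emission means makes usage vectors comparable across flies
    (all flies share the same feature space after z-scoring).
    """
    sp, _ = e_step(x, post)
    usage = sp.gamma.reshape(len(x), -1).mean(axis=0)
    order = np.lexsort((post.m[:, 1], post.m[:, 0]))
    return usage[order]


def _loglik_matrix(state: MixtureState) -> np.ndarray:
    ll = np.empty((state.n_flies, state.n_clusters))
    for n, x in enumerate(state.xs):
        for k, post in enumerate(state.models):
            ll[n, k] = e_step(x, post)[0].log_evidence_contrib
    return ll


def init_per_fly(
    obs_list,
    spec: HHMMSpec,
    priors: HHMMPriors | None = None,
    config: MixtureConfig | None = None,
) -> MixtureState:
    """Fit one HHMM per fly and group the models into initial clusters.

    Grouping uses a Gaussian mixture (component count chosen by BIC) on
    each fly's expected LL-state usage vector.  With a single fly the
    result is the trivial one-cluster mixture.
    """
    config = config or MixtureConfig()
    priors = priors or HHMMPriors()
    xs = _standardized(obs_list)
    n = len(xs)
    fits = [
        vbem_fit(
            x, spec, priors,
            max_iter=config.per_fly_max_iter,
            n_restarts=config.per_fly_restarts,
            seed=config.seed + 101 * i,
            standardize=False,
        )
        for i, x in enumerate(xs)
    ]
    usage = np.array([_usage_vector(x, f) for x, f in zip(xs, fits)])
    if n == 1:
        z = np.ones((1, 1))
        return MixtureState(z=z, models=[fits[0]], xs=xs, usage=usage)
    best_gm, best_bic, best_k = None, np.inf, 1
    k_cap = max(1, min(config.max_clusters, n // 2))
    # Floor the component variances at a fraction of the overall spread
    # so singleton components cannot buy arbitrary likelihood.
    reg = max(1e-6, 0.05 * float(usage.var(axis=0).mean()))
    for k in range(1, k_cap + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="diag",
            random_state=config.seed, n_init=3, reg_covar=reg,
        ).fit(usage)
        bic = gm.bic(usage)
        if bic < best_bic - 1e-9:
            best_gm, best_bic, best_k = gm, bic, k
    groups = best_gm.predict(usage)
    models = []
    z = np.zeros((n, best_k))
    for k in range(best_k):
        members = np.flatnonzero(groups == k)
        z[members, k] = 1.0
        weights = np.zeros(n)
        weights[members] = 1.0
        post = fits[members[0]]
        for _ in range(3):
            post, _, _ = vbem_step(xs, post, weights=weights)
        models.append(post)
    state = MixtureState(z=z, models=models, xs=xs, usage=usage)
    state.schedule_log.append(("init", {"k": best_k}))
    return state


def _em_iteration(state: MixtureState, config: MixtureConfig) -> float:
    """One EM sweep: responsibilities then weighted model updates.

    Returns the mixture evidence
    ``sum_n logsumexp_k (log w_k + log p(O_n | model_k))``.
    """
    ll = _loglik_matrix(state)
    k = state.n_clusters
    counts = state.z.sum(axis=0)
    w = counts + config.concentration / k
    log_w = np.log(w / w.sum())
    log_post = log_w[None, :] + ll
    evidence = float(logsumexp(log_post, axis=1).sum())
    z = np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))
    state.z = z
    for kk in range(k):
        post = state.models[kk]
        for _ in range(config.cluster_vbem_iters):
            post, _, _ = vbem_step(state.xs, post, weights=z[:, kk])
        state.models[kk] = post
    state.evidence_trace.append(evidence)
    return evidence


def _unused_clusters(state: MixtureState, config: MixtureConfig):
    argmax = state.z.argmax(axis=1)
    unused = []
    for k in range(state.n_clusters):
        if (state.z[:, k] > config.used_threshold).any():
            continue
        if (argmax == k).any():  # never prune any fly's best cluster
            continue
        unused.append(k)
    return unused


def _prune(state: MixtureState, config: MixtureConfig) -> None:
    """Remove unused clusters until at most two remain unused."""
    while state.n_clusters > 1:
        unused = _unused_clusters(state, config)
        if len(unused) <= 2:
            break
        drop = min(unused, key=lambda k: state.z[:, k].sum())
        state.models.pop(drop)
        state.z = np.delete(state.z, drop, axis=1)
        state.z = state.z / state.z.sum(axis=1, keepdims=True)
        state.schedule_log.append(("prune", {"cluster": drop}))


def _split(state: MixtureState, config: MixtureConfig,
           rng: np.random.Generator) -> None:
    """Split a size-weighted random cluster by k-means on LL-state usage."""
    if state.n_clusters >= config.max_clusters:
        return
    sizes = np.bincount(state.z.argmax(axis=1), minlength=state.n_clusters)
    if sizes.sum() == 0:
        return
    target = int(rng.choice(state.n_clusters, p=sizes / sizes.sum()))
    members = np.flatnonzero(state.z.argmax(axis=1) == target)
    if members.size < 2:
        return
    km = KMeans(n_clusters=2, n_init=10,
                random_state=int(rng.integers(2**31))).fit(
        state.usage[members]
    )
    halves = [members[km.labels_ == h] for h in (0, 1)]
    if any(h.size == 0 for h in halves):
        return
    state.z = np.hstack([state.z, np.zeros((state.n_flies, 1))])
    # Hard-assign the halves and refit both models.
    state.z[members, :] = 0.0
    state.z[halves[0], target] = 1.0
    new_idx = state.z.shape[1] - 1
    state.z[halves[1], new_idx] = 1.0
    base = state.models[target]
    for which, idxs in ((target, halves[0]), (new_idx, halves[1])):
        weights = np.zeros(state.n_flies)
        weights[idxs] = 1.0
        post = base
        for _ in range(3):
            post, _, _ = vbem_step(state.xs, post, weights=weights)
        if which == new_idx:
            state.models.append(post)
        else:
            state.models[which] = post
    state.schedule_log.append(
        ("split", {"cluster": target, "sizes": [len(h) for h in halves]})
    )


def _reassign(state: MixtureState, config: MixtureConfig) -> None:
    """Seed clusters that own no fly with the worst-fit flies."""
    ll = _loglik_matrix(state)
    argmax = state.z.argmax(axis=1)
    own_ll = ll[np.arange(state.n_flies), argmax]
    empty = [
        k for k in range(state.n_clusters) if not (argmax == k).any()
    ]
    order = np.argsort(own_ll)  # worst fit first
    for k, fly in zip(empty, order):
        state.z[fly, :] = 0.0
        state.z[fly, k] = 1.0
        weights = np.zeros(state.n_flies)
        weights[fly] = 1.0
        post = state.models[k]
        for _ in range(3):
            post, _, _ = vbem_step(state.xs, post, weights=weights)
        state.models[k] = post
        state.schedule_log.append(("reassign", {"cluster": k, "fly": int(fly)}))


def _total_objective(state: MixtureState, config: MixtureConfig) -> float:
    """Mixture evidence minus each cluster's parameter complexity.

    The per-fly log-evidences do not charge a cluster for its
    parameters; subtracting each cluster's KL(q || prior) makes
    redundant clusters strictly unprofitable.
    """
    ll = _loglik_matrix(state)
    counts = state.z.sum(axis=0)
    w = counts + config.concentration / state.n_clusters
    log_w = np.log(w / w.sum())
    evidence = float(logsumexp(log_w[None, :] + ll, axis=1).sum())
    return evidence - sum(_param_kl(m) for m in state.models)


def _merge_pass(state: MixtureState, config: MixtureConfig) -> None:
    """Greedily merge cluster pairs while the total objective improves.

    Near-duplicate clusters (e.g. produced by a split of a homogeneous
    cluster) lose little likelihood when merged but recover a full
    parameter complexity term, so they collapse; genuinely distinct
    clusters survive because the likelihood loss dominates.
    """
    improved = True
    while improved and state.n_clusters > 1:
        improved = False
        base = _total_objective(state, config)
        best = None
        for a in range(state.n_clusters):
            for b in range(a + 1, state.n_clusters):
                weights = state.z[:, a] + state.z[:, b]
                post = state.models[a]
                for _ in range(3):
                    post, _, _ = vbem_step(state.xs, post, weights=weights)
                trial_z = np.delete(state.z, b, axis=1)
                trial_z[:, a] = weights
                trial = MixtureState(
                    z=trial_z,
                    models=[
                        post if k == a else m
                        for k, m in enumerate(state.models)
                        if k != b
                    ],
                    xs=state.xs,
                    usage=state.usage,
                )
                gain = _total_objective(trial, config) - base
                if gain > 0 and (best is None or gain > best[0]):
                    best = (gain, a, b, post, trial_z)
        if best is not None:
            gain, a, b, post, trial_z = best
            state.models = [
                post if k == a else m
                for k, m in enumerate(state.models)
                if k != b
            ]
            state.z = trial_z
            state.schedule_log.append(
                ("merge", {"into": a, "from": b, "gain": float(gain)})
            )
            improved = True


def fit_mixture(
    obs_list,
    state: MixtureState,
    config: MixtureConfig | None = None,
) -> MixtureState:
    """Run the perturbation schedule and a final EM to convergence.

    Each perturbation round applies prune, split and reassignment, each
    followed by ``em_iters`` EM iterations; after ``n_rounds`` rounds a
    final EM runs until the mixture evidence stabilizes.  With
    ``use_schedule=False`` this reduces to plain weighted variational
    EM from the initial state.
    """
    config = config or MixtureConfig()
    rng = np.random.default_rng(config.seed)
    if config.use_schedule:
        for _round in range(config.n_rounds):
            for perturb in (_prune, _split, _reassign):
                if perturb is _split:
                    perturb(state, config, rng)
                else:
                    perturb(state, config)
                for _ in range(config.em_iters):
                    _em_iteration(state, config)
    if config.use_schedule:
        _merge_pass(state, config)
    prev = -np.inf
    for _ in range(config.final_max_iters):
        ev = _em_iteration(state, config)
        if np.isfinite(prev) and abs(ev - prev) <= config.tol * max(1.0, abs(prev)):
            break
        prev = ev
    return state


def assign_flies(state: MixtureState):
    """Hard cluster labels (1-based, ties to the lower index) and models.

    Returns ``(labels, models)`` where ``models[i]`` is the HHMM
    posterior of fly i's assigned cluster.
    """
    labels = state.hard_labels()
    models = [state.models[l - 1] for l in labels]
    return labels, models
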