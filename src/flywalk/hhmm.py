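"""Two-level hierarchical hidden Markov model fit by variational Bayes.

The model has ``n_hl`` high-level (HL) states, each owning ``n_ll``
low-level (LL) states.  Each LL state carries a bivariate Gaussian
emission on the observables (v_par, v_perp).  Within an HL state the LL
chain evolves by that state's transition matrix; every LL row also holds
an *exit* probability (the terminal-state mass) by which control returns
to the HL level, an HL transition is drawn from ``Q``, and the
destination HL state re-enters through its initial LL distribution.

Conjugate variational posteriors: Dirichlet rows for all transition and
initial distributions (the exit mass is an extra Dirichlet category on
each LL row) and Normal-Wishart distributions for the Gaussian
emissions.  Inference alternates forward-backward smoothing over the
flattened joint-state chain, run with the exponentiated geometric-mean
parameters ``A* = exp(E[log A])``, with conjugate parameter updates; the
evidence lower bound (ELBO) is non-decreasing across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma, gammaln, multigammaln

from .state_analysis import StateSequence

__all__ = [
    "HHMMSpec",
    "HHMMPriors",
    "HHMMPosterior",
    "StatePosterior",
    "SufficientStats",
    "flatten",
    "e_step",
    "m_step",
    "vbem_fit",
    "map_states",
    "count_parameters",
    "save_posterior",
    "load_posterior",
]

CONFIDENCE_THRESHOLD = 0.85  # minimum HL-state probability for an assignment


@dataclass(frozen=True)
class HHMMSpec:
    """Model topology.

    ``exit_mode`` controls the terminal-state mass on each LL row:
    ``"untied"`` (default) gives every LL row its own exit probability,
    ``"tied"`` pools exit counts across the LL rows of an HL state, and
    ``"none"`` removes HL transitions entirely.  A flat HMM with K
    states is the one-level special case ``HHMMSpec(n_hl=1, n_ll=K)``.
    """

    n_hl: int = 10
    n_ll: int = 5
    emission_dim: int = 2
    exit_mode: str = "untied"

    def __post_init__(self):
        if self.n_hl < 1 or self.n_ll < 1:
            raise ValueError("n_hl and n_ll must be >= 1")
        if self.exit_mode not in ("untied", "tied", "none"):
            raise ValueError(f"unknown exit_mode {self.exit_mode!r}")

    @property
    def n_joint(self) -> int:
        return self.n_hl * self.n_ll

    @property
    def has_exit(self) -> bool:
        # With a single HL state an exit merely re-enters the same state;
        # it is kept when requested so the general machinery is exercised.
        return self.exit_mode != "none"


@dataclass
class HHMMPriors:
    """Conjugate prior hyperparameters.

    Transition rows are weak Dirichlets whose total concentration is the
    equivalent of two observations, split 6:1 between the self-transition
    and the pooled cross mass (spread uniformly over the other
    destinations, including the exit category).  Initial distributions
    are symmetric Dirichlets with concentration below one, which
    discourages the use of unneeded states.  Emissions are
    Normal-Wishart favoring zero mean and unit variance, so observables
    are expected to be z-scored before fitting.
    """

    row_strength: float = 2.0
    self_cross_ratio: float = 6.0
    init_alpha: float = 0.5
    niw_kappa: float = 1.0
    niw_dof: float | None = None  # default: emission_dim + 2
    niw_scale: float = 1.0  # multiplies the identity scale matrix

    def q_rows(self, spec: HHMMSpec) -> np.ndarray:
        """Prior Dirichlet rows for the HL transition matrix Q."""
        n = spec.n_hl
        r, s = self.row_strength, self.self_cross_ratio
        if n == 1:
            return np.full((1, 1), r)
        self_mass = r * s / (s + 1.0)
        cross = (r - self_mass) / (n - 1)
        rows = np.full((n, n), cross)
        np.fill_diagonal(rows, self_mass)
        return rows

    def a_rows(self, spec: HHMMSpec) -> np.ndarray:
        """Prior rows for each LL transition matrix, exit category last."""
        n = spec.n_ll
        r, s = self.row_strength, self.self_cross_ratio
        n_other = (n - 1) + (1 if spec.has_exit else 0)
        rows = np.zeros((spec.n_hl, n, n + 1))
        if n_other == 0:
            rows[:, :, 0] = r
            return rows
        self_mass = r * s / (s + 1.0)
        other = (r - self_mass) / n_other
        for i in range(n):
            rows[:, i, :n] = other
            rows[:, i, i] = self_mass
            rows[:, i, n] = other if spec.has_exit else 0.0
        return rows

    def niw(self, spec: HHMMSpec):
        d = spec.emission_dim
        nu0 = self.niw_dof if self.niw_dof is not None else d + 2.0
        m0 = np.zeros(d)
        # Wishart parameterization: scale matrix W0 with E[Sigma^-1]=nu*W0.
        w0 = np.eye(d) / self.niw_scale
        return m0, self.niw_kappa, w0, nu0


@dataclass
class HHMMPosterior:
    """Variational posterior over all HHMM parameters.

    Array layout (K = n_hl * n_ll joint states, d = emission dim):

    - ``q_Q``: (n_hl, n_hl) Dirichlet rows over HL transitions.
    - ``q_A``: (n_hl, n_ll, n_ll + 1) Dirichlet rows over LL transitions;
      the last column is the exit (terminal-state) category and is
      structurally zero when ``exit_mode == "none"``.
    - ``q_pi0``: (n_hl,) initial HL Dirichlet.
    - ``q_pik``: (n_hl, n_ll) per-HL initial LL Dirichlet rows.
    - ``m``: (K, d) Normal-Wishart means, ``kappa``/``nu``: (K,),
      ``w``: (K, d, d) Wishart scale matrices.
    """

    spec: HHMMSpec
    priors: HHMMPriors
    q_Q: np.ndarray
    q_A: np.ndarray
    q_pi0: np.ndarray
    q_pik: np.ndarray
    m: np.ndarray
    kappa: np.ndarray
    nu: np.ndarray
    w: np.ndarray
    elbo_trace: list = field(default_factory=list)
    standardize_mean: np.ndarray | None = None
    standardize_sd: np.ndarray | None = None
    converged: bool = True

    def expected_Q(self) -> np.ndarray:
        return self.q_Q / self.q_Q.sum(axis=1, keepdims=True)

    def expected_A(self) -> np.ndarray:
        """(n_hl, n_ll, n_ll+1) expected LL rows including exit mass."""
        return self.q_A / self.q_A.sum(axis=2, keepdims=True)

    def expected_pi0(self) -> np.ndarray:
        return self.q_pi0 / self.q_pi0.sum()

    def expected_pik(self) -> np.ndarray:
        return self.q_pik / self.q_pik.sum(axis=1, keepdims=True)

    def expected_means(self) -> np.ndarray:
        return self.m.copy()

    def expected_covs(self) -> np.ndarray:
        d = self.spec.emission_dim
        psi = np.linalg.inv(self.w)
        return psi / (self.nu - d - 1.0)[:, None, None]

    @property
    def elbo(self) -> float:
        return self.elbo_trace[-1] if self.elbo_trace else -np.inf


@dataclass
class StatePosterior:
    """Smoothed per-frame posterior over the joint (HL, LL) states."""

    gamma: np.ndarray  # (T, n_hl, n_ll)
    hl_marginal: np.ndarray  # (T, n_hl)
    log_evidence_contrib: float


@dataclass
class SufficientStats:
    """Expected counts and emission moments from the E-step."""

    counts_Q: np.ndarray  # (n_hl, n_hl) expected HL transitions (via exit)
    counts_A: np.ndarray  # (n_hl, n_ll, n_ll+1) LL transitions + exit events
    counts_pi0: np.ndarray  # (n_hl,)
    counts_pik: np.ndarray  # (n_hl, n_ll) re-entry + initial LL counts
    n_emit: np.ndarray  # (K,)
    sum_x: np.ndarray  # (K, d)
    sum_xx: np.ndarray  # (K, d, d)

    def __iadd__(self, other: "SufficientStats"):
        for name in (
            "counts_Q", "counts_A", "counts_pi0", "counts_pik",
            "n_emit", "sum_x", "sum_xx",
        ):
            getattr(self, name).__iadd__(getattr(other, name))
        return self

    @classmethod
    def zeros(cls, spec: HHMMSpec) -> "SufficientStats":
        k, d = spec.n_joint, spec.emission_dim
        return cls(
            counts_Q=np.zeros((spec.n_hl, spec.n_hl)),
            counts_A=np.zeros((spec.n_hl, spec.n_ll, spec.n_ll + 1)),
            counts_pi0=np.zeros(spec.n_hl),
            counts_pik=np.zeros((spec.n_hl, spec.n_ll)),
            n_emit=np.zeros(k),
            sum_x=np.zeros((k, d)),
            sum_xx=np.zeros((k, d, d)),
        )


# ---------------------------------------------------------------------------
# parameter counting


def count_parameters(levels, np_emission: int) -> int:
    """Number of free parameters of a (hierarchical) HMM.

    ``levels`` lists state counts from the top level down; a flat HMM
    with K states and ``np_emission``-parameter emissions has
    ``K**2 + K*np_emission`` parameters, a two-level model
    ``K_hl**2 + K_hl*K_ll**2 + np*K_hl*K_ll``, and so on for deeper
    hierarchies (each level contributes its transition matrices, one per
    parent chain).
    """
    levels = list(levels)
    if not levels:
        raise ValueError("need at least one level")
    if any(int(k) < 1 for k in levels):
        raise ValueError("state counts must be positive")
    total = levels[0] ** 2
    prod = levels[0]
    for k in levels[1:]:
        total += prod * k**2
        prod *= k
    total += np_emission * prod
    return int(total)


# ---------------------------------------------------------------------------
# geometric-mean parameters and flattening


def _elog_dirichlet_rows(alpha: np.ndarray) -> np.ndarray:
    """E[log p] for Dirichlet rows (last axis); zero entries -> -inf."""
    out = np.full(alpha.shape, -np.inf)
    mask = alpha > 0
    safe = np.where(mask, alpha, 1.0)
    row_sums = np.where(mask, safe, 0.0).sum(axis=-1, keepdims=True)
    vals = digamma(safe) - digamma(row_sums)
    out[mask] = np.broadcast_to(vals, alpha.shape)[mask]
    return out


def _star_params(post: HHMMPosterior):
    """Exponentiated geometric-mean (sub-stochastic) parameters."""
    a_star = np.exp(_elog_dirichlet_rows(post.q_A))
    q_star = np.exp(_elog_dirichlet_rows(post.q_Q))
    pi0_star = np.exp(_elog_dirichlet_rows(post.q_pi0[None, :]))[0]
    pik_star = np.exp(_elog_dirichlet_rows(post.q_pik))
    return a_star, q_star, pi0_star, pik_star


def _flat_transition(a, q, pik, n_hl, n_ll):
    """Joint-state transition matrix split into stay and exit channels.

    ``stay[(k,i),(l,j)] = delta_kl * a[k,i,j]`` and
    ``exit_part[(k,i),(l,j)] = e[k,i] * q[k,l] * pik[l,j]`` where ``e``
    is the exit column of ``a``.  The full matrix is their sum; the
    cross-HL blocks are rank one by construction.
    """
    k_joint = n_hl * n_ll
    stay = np.zeros((k_joint, k_joint))
    for k in range(n_hl):
        sl = slice(k * n_ll, (k + 1) * n_ll)
        stay[sl, sl] = a[k, :, :n_ll]
    exit_vec = a[:, :, n_ll].reshape(k_joint)  # e[k,i]
    dest = (q[:, :, None] * pik[None, :, :]).reshape(n_hl, k_joint)
    exit_part = exit_vec[:, None] * np.repeat(dest, n_ll, axis=0)
    return stay, exit_part


def flatten(post: HHMMPosterior, mode: str = "expected"):
    """Represent the HHMM as an equivalent flat HMM over joint states.

    Returns ``(trans, init, emissions)`` where ``trans`` is the
    (K, K) joint-state transition matrix (row-stochastic in
    ``"expected"`` mode, sub-stochastic in ``"geometric-mean"`` mode),
    ``init`` the joint initial distribution and ``emissions`` a list of
    ``(mean, cov)`` pairs.  Joint state ``k * n_ll + i`` is (HL k, LL i).
    """
    spec = post.spec
    if mode == "expected":
        a, q, pi0, pik = (
            post.expected_A(), post.expected_Q(),
            post.expected_pi0(), post.expected_pik(),
        )
    elif mode == "geometric-mean":
        a, q, pi0, pik = _star_params(post)
        a = np.where(np.isfinite(a), a, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    stay, exit_part = _flat_transition(a, q, pik, spec.n_hl, spec.n_ll)
    trans = stay + exit_part
    init = (pi0[:, None] * pik).reshape(spec.n_joint)
    means, covs = post.expected_means(), post.expected_covs()
    emissions = [(means[s], covs[s]) for s in range(spec.n_joint)]
    return trans, init, emissions


# ---------------------------------------------------------------------------
# emission expected log-likelihood


def _expected_log_emission(post: HHMMPosterior, x: np.ndarray) -> np.ndarray:
    """E_q[log N(x | mu_s, Sigma_s)] for all frames and joint states."""
    d = post.spec.emission_dim
    t = x.shape[0]
    k = post.spec.n_joint
    out = np.empty((t, k))
    for s in range(k):
        elogdet = (
            digamma(0.5 * (post.nu[s] - np.arange(d)))
            .sum()
            + d * np.log(2.0)
            + np.linalg.slogdet(post.w[s])[1]
        )
        diff = x - post.m[s]
        maha = np.einsum("ti,ij,tj->t", diff, post.w[s], diff)
        out[:, s] = 0.5 * (
            elogdet - d * np.log(2.0 * np.pi) - d / post.kappa[s]
            - post.nu[s] * maha
        )
    return out


# ---------------------------------------------------------------------------
# forward-backward (scaled, batched over sequences of equal length)


def _forward_backward(log_b: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Scaled forward-backward on a batch of sequences.

    ``log_b``: (S, T, K) per-frame log emission weights; ``trans`` may be
    sub-stochastic (geometric-mean weights).  Returns per-sequence
    smoothed marginals ``gamma`` (S, T, K), summed two-slice marginals
    ``xi`` (S, K, K) and log normalizers (S,).
    """
    s_n, t_n, k = log_b.shape
    shift = log_b.max(axis=2)
    b = np.exp(log_b - shift[:, :, None])
    alpha = np.empty((s_n, t_n, k))
    scale = np.empty((s_n, t_n))
    a = init[None, :] * b[:, 0]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0][:, None]
    for t in range(1, t_n):
        a = (alpha[:, t - 1] @ trans) * b[:, t]
        scale[:, t] = a.sum(axis=1)
        alpha[:, t] = a / scale[:, t][:, None]
    beta = np.empty((s_n, t_n, k))
    beta[:, -1] = 1.0
    xi = np.zeros((s_n, k, k))
    for t in range(t_n - 2, -1, -1):
        bb = b[:, t + 1] * beta[:, t + 1]
        xi += np.einsum("si,ij,sj->sij", alpha[:, t], trans, bb) / scale[
            :, t + 1
        ][:, None, None]
        beta[:, t] = (bb @ trans.T) / scale[:, t + 1][:, None]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    loglik = np.log(scale).sum(axis=1) + shift.sum(axis=1)
    return gamma, xi, loglik


def _suff_from_fb(spec, gamma, xi, x, stay, exit_part) -> SufficientStats:
    """Decompose joint-state statistics into hierarchical counts.

    Each two-slice count in a within-HL cell is split between the stay
    channel and the exit(+re-entry) channel in proportion to their
    geometric-mean weights.
    """
    n_hl, n_ll = spec.n_hl, spec.n_ll
    total = stay + exit_part
    with np.errstate(invalid="ignore", divide="ignore"):
        exit_frac = np.where(total > 0, exit_part / np.where(total > 0, total, 1.0), 0.0)
    xi_exit = xi * exit_frac
    xi_stay = xi - xi_exit

    suff = SufficientStats.zeros(spec)
    # Stay channel: within-HL LL transitions.
    for k in range(n_hl):
        sl = slice(k * n_ll, (k + 1) * n_ll)
        suff.counts_A[k, :, :n_ll] += xi_stay[sl, sl]
    # Exit channel: aggregate over source LL and destination (l, j).
    exit_by_src = xi_exit.sum(axis=1)  # (K,)
    suff.counts_A[:, :, n_ll] += exit_by_src.reshape(n_hl, n_ll)
    blocks = xi_exit.reshape(n_hl, n_ll, n_hl, n_ll)
    suff.counts_Q += blocks.sum(axis=(1, 3))
    suff.counts_pik += blocks.sum(axis=(0, 1))
    # Initial-state counts.
    g0 = gamma[0].reshape(n_hl, n_ll)
    suff.counts_pi0 += g0.sum(axis=1)
    suff.counts_pik += g0
    # Emission moments.
    g = gamma  # (T, K)
    suff.n_emit += g.sum(axis=0)
    suff.sum_x += g.T @ x
    suff.sum_xx += np.einsum("tk,ti,tj->kij", g, x, x)
    return suff


def _as_obs_matrix(obs) -> np.ndarray:
    if hasattr(obs, "as_matrix"):
        return obs.as_matrix()
    x = np.asarray(obs, dtype=float)
    if x.ndim != 2:
        raise ValueError("observations must be a (T, d) array")
    return x


def e_step(obs, post: HHMMPosterior):
    """Variational E-step on a single observable series.

    Returns ``(StatePosterior, SufficientStats)``.  Responsibilities are
    computed by forward-backward smoothing over the flattened joint
    chain using the geometric-mean transition weights; all recursions
    are scaled so sequences of 10,000+ frames do not underflow.
    """
    x = _as_obs_matrix(obs)
    if not np.all(np.isfinite(x)):
        raise ValueError("observables contain non-finite values")
    spec = post.spec
    a, q, pi0, pik = _star_params(post)
    a = np.where(np.isfinite(a), a, 0.0)
    stay, exit_part = _flat_transition(a, q, pik, spec.n_hl, spec.n_ll)
    trans = stay + exit_part
    init = (pi0[:, None] * pik).reshape(spec.n_joint)
    log_b = _expected_log_emission(post, x)
    gamma, xi, loglik = _forward_backward(
        log_b[None, :, :], trans, init
    )
    gamma, xi, loglik = gamma[0], xi[0], float(loglik[0])
    suff = _suff_from_fb(spec, gamma, xi, x, stay, exit_part)
    sp = StatePosterior(
        gamma=gamma.reshape(-1, spec.n_hl, spec.n_ll),
        hl_marginal=gamma.reshape(-1, spec.n_hl, spec.n_ll).sum(axis=2),
        log_evidence_contrib=loglik,
    )
    return sp, suff


def m_step(suff: SufficientStats, priors: HHMMPriors, spec: HHMMSpec,
           template: HHMMPosterior | None = None) -> HHMMPosterior:
    """Conjugate parameter update: posterior = prior + expected counts."""
    for arr in (suff.counts_Q, suff.counts_A, suff.counts_pi0,
                suff.counts_pik, suff.n_emit):
        if np.any(arr < -1e-9):
            raise RuntimeError("negative expected counts")
    counts_a = suff.counts_A.copy()
    if spec.exit_mode == "tied":
        pooled = counts_a[:, :, spec.n_ll].sum(axis=1, keepdims=True)
        counts_a[:, :, spec.n_ll] = pooled / spec.n_ll
    q_a = priors.a_rows(spec) + counts_a
    if not spec.has_exit:
        q_a[:, :, spec.n_ll] = 0.0
    m0, kappa0, w0, nu0 = priors.niw(spec)
    k, d = spec.n_joint, spec.emission_dim
    n = suff.n_emit
    kappa = kappa0 + n
    nu = nu0 + n
    m = (kappa0 * m0[None, :] + suff.sum_x) / kappa[:, None]
    psi0 = np.linalg.inv(w0)
    w = np.empty((k, d, d))
    for s in range(k):
        if n[s] > 0:
            xbar = suff.sum_x[s] / n[s]
            scatter = suff.sum_xx[s] - np.outer(suff.sum_x[s], xbar)
            dm = xbar - m0
            psi = psi0 + scatter + (kappa0 * n[s] / kappa[s]) * np.outer(dm, dm)
        else:
            psi = psi0.copy()
        w[s] = np.linalg.inv(0.5 * (psi + psi.T))
    post = HHMMPosterior(
        spec=spec,
        priors=priors,
        q_Q=priors.q_rows(spec) + suff.counts_Q,
        q_A=q_a,
        q_pi0=np.full(spec.n_hl, priors.init_alpha) + suff.counts_pi0,
        q_pik=np.full((spec.n_hl, spec.n_ll), priors.init_alpha) + suff.counts_pik,
        m=m,
        kappa=kappa,
        nu=nu,
        w=w,
    )
    if template is not None:
        post.elbo_trace = template.elbo_trace
        post.standardize_mean = template.standardize_mean
        post.standardize_sd = template.standardize_sd
    return post


# ---------------------------------------------------------------------------
# KL divergences for the ELBO


def _kl_dirichlet_rows(alpha_q: np.ndarray, alpha_p: np.ndarray) -> float:
    aq = alpha_q.reshape(-1, alpha_q.shape[-1])
    ap = alpha_p.reshape(-1, alpha_p.shape[-1])
    total = 0.0
    for q_row, p_row in zip(aq, ap):
        mask = q_row > 0
        q, p = q_row[mask], p_row[mask]
        q0, p0 = q.sum(), p.sum()
        total += (
            gammaln(q0) - gammaln(p0)
            + np.sum(gammaln(p) - gammaln(q))
            + np.sum((q - p) * (digamma(q) - digamma(q0)))
        )
    return float(total)


def _kl_normal_wishart(post: HHMMPosterior) -> float:
    spec = post.spec
    d = spec.emission_dim
    m0, kappa0, w0, nu0 = post.priors.niw(spec)
    w0_inv = np.linalg.inv(w0)
    _, logdet_w0 = np.linalg.slogdet(w0)
    total = 0.0
    for s in range(spec.n_joint):
        nu_q, kappa_q, w_q, m_q = post.nu[s], post.kappa[s], post.w[s], post.m[s]
        _, logdet_wq = np.linalg.slogdet(w_q)
        elogdet = (
            digamma(0.5 * (nu_q - np.arange(d))).sum()
            + d * np.log(2.0)
            + logdet_wq
        )
        dm = m_q - m0
        kl_norm = 0.5 * (
            d * np.log(kappa_q / kappa0) - d + kappa0 * d / kappa_q
            + kappa0 * nu_q * dm @ w_q @ dm
        )
        kl_wish = (
            0.5 * (nu_q - nu0) * elogdet
            - 0.5 * nu_q * d
            + 0.5 * nu_q * np.trace(w0_inv @ w_q)
            - 0.5 * nu_q * d * np.log(2.0) - 0.5 * nu_q * logdet_wq
            - multigammaln(0.5 * nu_q, d)
            + 0.5 * nu0 * d * np.log(2.0) + 0.5 * nu0 * logdet_w0
            + multigammaln(0.5 * nu0, d)
        )
        total += kl_norm + kl_wish
    return float(total)


def _param_kl(post: HHMMPosterior) -> float:
    priors = post.priors
    spec = post.spec
    kl = _kl_dirichlet_rows(post.q_Q, priors.q_rows(spec))
    kl += _kl_dirichlet_rows(post.q_A, priors.a_rows(spec))
    kl += _kl_dirichlet_rows(
        post.q_pi0[None, :], np.full((1, spec.n_hl), priors.init_alpha)
    )
    kl += _kl_dirichlet_rows(
        post.q_pik, np.full((spec.n_hl, spec.n_ll), priors.init_alpha)
    )
    kl += _kl_normal_wishart(post)
    return kl


# ---------------------------------------------------------------------------
# fitting


def _prepare_sequences(obs, standardize):
    """Z-score sequences: per fly (True), with a common pooled transform
    ("global"), or not at all (False).

    Per-fly scaling suits fitting each fly its own model; a model shared
    across flies needs one common transform so that a given emission
    means the same movement for every fly.
    """
    if isinstance(obs, (list, tuple)):
        xs = [_as_obs_matrix(o) for o in obs]
    else:
        xs = [_as_obs_matrix(obs)]
    if standardize == "global":
        pooled = np.concatenate(xs, axis=0)
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        out = [(x - mu) / sd for x in xs]
        mus = np.tile(mu, (len(xs), 1))
        sds = np.tile(sd, (len(xs), 1))
        return out, mus, sds
    if standardize:
        out = []
        mus, sds = [], []
        for x in xs:
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            out.append((x - mu) / sd)
            mus.append(mu)
            sds.append(sd)
        return out, np.asarray(mus), np.asarray(sds)
    return xs, None, None


def _group_by_transition_affinity(counts: np.ndarray, n_hl: int,
                                  n_ll: int) -> np.ndarray:
    """Partition joint clusters into HL groups of size n_ll.

    Greedy agglomeration on the symmetrized empirical transition counts:
    clusters that frequently follow one another end up in the same HL
    state, which is the partition a hierarchy can represent cheaply.
    Returns an array mapping each cluster to a joint-state slot.
    """
    k = counts.shape[0]
    aff = counts + counts.T
    np.fill_diagonal(aff, 0.0)
    groups = [[i] for i in range(k)]
    while len(groups) > n_hl:
        best, best_score = None, -1.0
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if len(groups[a]) + len(groups[b]) > n_ll:
                    continue
                score = sum(aff[i, j] for i in groups[a] for j in groups[b])
                if score > best_score:
                    best, best_score = (a, b), score
        if best is None:  # size caps block further merging; force-merge
            groups.sort(key=len)
            groups[0] = groups[0] + groups[1]
            del groups[1]
            continue
        a, b = best
        groups[a] = groups[a] + groups[b]
        del groups[b]
    slot = np.empty(k, dtype=np.int64)
    flat = 0
    for g in groups:
        for member in g:
            slot[member] = flat
            flat += 1
    # Pad bookkeeping: groups smaller than n_ll leave unused slots, which
    # simply keep their random means.
    return slot


def _informed_init(spec, priors, xs, rng) -> HHMMPosterior:
    """Data-driven restart: k-means emissions grouped by transition affinity.

    A k-means labeling of the pooled observations gives candidate
    emission clusters and an empirical joint transition matrix; clusters
    are partitioned into HL groups so that frequent transitions fall
    within a group, which is the structure an HHMM represents cheaply.
    """
    from sklearn.cluster import KMeans

    post = _init_posterior(spec, priors, xs, rng)
    pooled = np.concatenate(xs, axis=0)
    k = spec.n_joint
    if pooled.shape[0] < 10 * k:
        return post
    km = KMeans(n_clusters=k, n_init=5,
                random_state=int(rng.integers(2**31))).fit(pooled)
    counts = np.zeros((k, k))
    for x in xs:
        lab = km.predict(x)
        np.add.at(counts, (lab[:-1], lab[1:]), 1.0)
    slot = _group_by_transition_affinity(counts, spec.n_hl, spec.n_ll)
    post.m[slot] = km.cluster_centers_ + 0.01 * rng.standard_normal((k, 2))
    # Seed transition posteriors with the (rearranged) empirical counts,
    # scaled down so the first E-step can still move them.
    scale = 0.1
    reordered = np.zeros_like(counts)
    reordered[np.ix_(slot, slot)] = counts
    for hl in range(spec.n_hl):
        sl = slice(hl * spec.n_ll, (hl + 1) * spec.n_ll)
        block = reordered[sl, sl]
        post.q_A[hl, :, : spec.n_ll] += scale * block
        cross = np.delete(reordered[sl, :], np.arange(sl.start, sl.stop),
                          axis=1)
        if spec.has_exit:
            post.q_A[hl, :, spec.n_ll] += scale * cross.sum(axis=1)
        dest_hl = reordered[sl, :].reshape(spec.n_ll, spec.n_hl, spec.n_ll)
        post.q_Q[hl] += scale * dest_hl.sum(axis=(0, 2))
    return post


def _init_posterior(spec, priors, xs, rng) -> HHMMPosterior:
    """Random restart: emission means seeded from random data frames."""
    pooled = np.concatenate(xs, axis=0)
    k, d = spec.n_joint, spec.emission_dim
    idx = rng.choice(pooled.shape[0], size=k, replace=pooled.shape[0] < k)
    m0, kappa0, w0, nu0 = priors.niw(spec)
    m = pooled[idx] + 0.05 * rng.standard_normal((k, d))
    post = HHMMPosterior(
        spec=spec,
        priors=priors,
        q_Q=priors.q_rows(spec) * (1.0 + 0.1 * rng.random((spec.n_hl, spec.n_hl))),
        q_A=priors.a_rows(spec) * (1.0 + 0.1 * rng.random((spec.n_hl, spec.n_ll, spec.n_ll + 1))),
        q_pi0=np.full(spec.n_hl, priors.init_alpha),
        q_pik=np.full((spec.n_hl, spec.n_ll), priors.init_alpha),
        m=m,
        kappa=np.full(k, kappa0 + 1.0),
        nu=np.full(k, nu0 + 1.0),
        w=np.repeat(w0[None, :, :], k, axis=0),
    )
    if not spec.has_exit:
        post.q_A[:, :, spec.n_ll] = 0.0
    return post


def vbem_step(xs, post: HHMMPosterior, weights=None):
    """One E+M sweep over a list of (T, d) arrays; returns (post, elbo, suff).

    ``weights`` optionally scales each sequence's sufficient statistics
    (used by the mixture model's responsibility weighting).  The
    returned ELBO is the bound evaluated *before* the M-step, i.e. with
    the incoming parameter posterior.
    """
    spec, priors = post.spec, post.priors
    if weights is None:
        weights = np.ones(len(xs))
    a, q, pi0, pik = _star_params(post)
    a = np.where(np.isfinite(a), a, 0.0)
    stay, exit_part = _flat_transition(a, q, pik, spec.n_hl, spec.n_ll)
    trans = stay + exit_part
    init = (pi0[:, None] * pik).reshape(spec.n_joint)

    total = SufficientStats.zeros(spec)
    loglik = 0.0
    by_len: dict[int, list[int]] = {}
    for i, x in enumerate(xs):
        by_len.setdefault(x.shape[0], []).append(i)
    for t_len, idxs in by_len.items():
        batch = np.stack([xs[i] for i in idxs])
        log_b = np.stack(
            [_expected_log_emission(post, xs[i]) for i in idxs]
        )
        gamma, xi, ll = _forward_backward(log_b, trans, init)
        for pos, i in enumerate(idxs):
            suff = _suff_from_fb(
                spec, gamma[pos], xi[pos], batch[pos], stay, exit_part
            )
            w_i = weights[i]
            if w_i != 1.0:
                for name in ("counts_Q", "counts_A", "counts_pi0",
                             "counts_pik", "n_emit", "sum_x", "sum_xx"):
                    getattr(suff, name).__imul__(w_i)
            total += suff
            loglik += weights[i] * ll[pos]
    elbo = loglik - _param_kl(post)
    new_post = m_step(total, priors, spec, template=post)
    return new_post, elbo, total


def vbem_fit(
    obs,
    spec: HHMMSpec,
    priors: HHMMPriors | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 5,
    standardize=True,
    weights=None,
) -> HHMMPosterior:
    """Fit the HHMM by variational Bayesian EM with random restarts.

    ``obs`` may be a single observable series / (T, d) array or a list
    of them (one per fly).  Each sequence is z-scored independently by
    default; the transforms are stored on the returned posterior.
    Returns the restart with the highest final ELBO; its
    ``elbo_trace`` is non-decreasing up to numerical tolerance.
    """
    priors = priors or HHMMPriors()
    xs, mus, sds = _prepare_sequences(obs, standardize)
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            post = _informed_init(spec, priors, xs, rng)
        else:
            post = _init_posterior(spec, priors, xs, rng)
        trace: list[float] = []
        converged = False
        for _it in range(max_iter):
            post, elbo, _ = vbem_step(xs, post, weights=weights)
            trace.append(elbo)
            post.elbo_trace = trace
            if len(trace) >= 2:
                prev = trace[-2]
                if abs(elbo - prev) <= tol * max(1.0, abs(prev)):
                    converged = True
                    break
        if not converged:
            warnings.warn(
                f"VBEM did not converge in {max_iter} iterations; "
                "returning best-so-far posterior"
            )
        post.converged = converged
        post.standardize_mean = mus
        post.standardize_sd = sds
        if best is None or post.elbo > best.elbo:
            best = post
    return best


def map_states(statepost: StatePosterior) -> StateSequence:
    """Per-frame MAP state labels with HL confidence.

    The HL label is the argmax of the HL marginal, its probability the
    confidence, and the LL label the argmax within the chosen HL state.
    Labels are 1-based; no confidence filtering is applied here.
    """
    hl_marg = statepost.hl_marginal
    hl = hl_marg.argmax(axis=1)
    confidence = hl_marg.max(axis=1)
    ll = statepost.gamma[np.arange(hl.size), hl, :].argmax(axis=1)
    return StateSequence(
        hl=hl + 1, ll=ll + 1, confidence=confidence
    )


# ---------------------------------------------------------------------------
# serialization


def save_posterior(post: HHMMPosterior, path) -> None:
    """Save a posterior to an ``.npz`` archive.

    Keys: ``spec`` (n_hl, n_ll, emission_dim), ``exit_mode``, all
    Dirichlet blocks (``q_Q``, ``q_A``, ``q_pi0``, ``q_pik``), the
    Normal-Wishart blocks (``m``, ``kappa``, ``nu``, ``w``),
    ``elbo_trace`` and the per-sequence standardization transforms.
    """
    np.savez(
        path,
        spec=np.array([post.spec.n_hl, post.spec.n_ll, post.spec.emission_dim]),
        exit_mode=np.array(post.spec.exit_mode),
        q_Q=post.q_Q, q_A=post.q_A, q_pi0=post.q_pi0, q_pik=post.q_pik,
        m=post.m, kappa=post.kappa, nu=post.nu, w=post.w,
        elbo_trace=np.asarray(post.elbo_trace, dtype=float),
        standardize_mean=(
            post.standardize_mean if post.standardize_mean is not None
            else np.empty((0, 0))
        ),
        standardize_sd=(
            post.standardize_sd if post.standardize_sd is not None
            else np.empty((0, 0))
        ),
    )


def load_posterior(path, priors: HHMMPriors | None = None) -> HHMMPosterior:
    data = np.load(path, allow_pickle=False)
    n_hl, n_ll, dim = (int(v) for v in data["spec"])
    spec = HHMMSpec(
        n_hl=n_hl, n_ll=n_ll, emission_dim=dim,
        exit_mode=str(data["exit_mode"]),
    )
    sm = data["standardize_mean"]
    ss = data["standardize_sd"]
    return HHMMPosterior(
        spec=spec,
        priors=priors or HHMMPriors(),
        q_Q=data["q_Q"], q_A=data["q_A"],
        q_pi0=data["q_pi0"], q_pik=data["q_pik"],
        m=data["m"], kappa=data["kappa"], nu=data["nu"], w=data["w"],
        elbo_trace=list(data["elbo_trace"]),
        standardize_mean=sm if sm.size else None,
        standardize_sd=ss if ss.size else None,
    )
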