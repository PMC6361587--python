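"""Synthetic flies: ground-truth HHMM streams and full arena cohorts.

Three generators of increasing scope:

- :func:`generate_hl_sequence` — the HL-only synthetic fly: a Markov
  chain over high-level states drawn from an occupancy distribution and
  a transition matrix (the construction used for fly-to-fly distance
  nulls).
- :func:`simulate_hhmm` — the full hierarchical simulator: LL chains
  nested in HL states with exit events, Gaussian emissions on
  (v_par, v_perp), plus the true labels (enables parameter-recovery
  tests).
- :func:`synthesize_cohort` — an entire experiment: 34 flies in four
  locomotor-type clusters walking a unit-circle arena for six minutes
  at 30 Hz, with an odor-onset switch of the HL transition structure
  inside (and, after first entry, outside) the odor zone.

The default emission catalog mirrors the empirically observed feature
set qualitatively: three slow states (one stop-and-go state approximated
by a wide-variance Gaussian, one slow sharp-turn state), four
medium-speed states distinguished by forward speed, and three fast
states with signed v_perp for right and left turners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import (
    DEFAULT_ARENA_RADIUS_CM,
    DEFAULT_ODOR_ON_FRAME,
    DEFAULT_ODOR_ZONE_RADIUS_CM,
    ObservableSeries,
    TrajectoryRecord,
)

__all__ = [
    "GroundTruthHHMM",
    "CohortConfig",
    "FlyTruth",
    "generate_hl_sequence",
    "simulate_hhmm",
    "synthesize_cohort",
    "sticky_transitions",
    "well_separated_hhmm",
    "default_emission_catalog",
    "default_cluster_occupancies",
    "default_odor_shifts",
    "synthetic_fly_occupancies",
]

FPS = 30

# 1 cm/s at 30 Hz in a 3.2 cm arena is 1/96 normalized units per frame.
CM_PER_S = 1.0 / (DEFAULT_ARENA_RADIUS_CM * FPS)


@dataclass
class GroundTruthHHMM:
    """Generative two-level HHMM parameters.

    ``a`` rows are the LL transition probabilities *conditional on
    staying*; ``exit`` holds the per-(HL, LL) terminal-state mass, so
    the per-frame law is: with probability ``exit[k, i]`` leave HL k
    (draw the next HL from ``q[k]`` and its LL from ``pik``), otherwise
    move within HL k by ``a[k, i]``.
    """

    q: np.ndarray  # (n_hl, n_hl)
    a: np.ndarray  # (n_hl, n_ll, n_ll)
    exit: np.ndarray  # (n_hl, n_ll)
    pi0: np.ndarray  # (n_hl,)
    pik: np.ndarray  # (n_hl, n_ll)
    means: np.ndarray  # (n_hl, n_ll, 2)
    covs: np.ndarray  # (n_hl, n_ll, 2, 2)

    @property
    def n_hl(self) -> int:
        return self.q.shape[0]

    @property
    def n_ll(self) -> int:
        return self.a.shape[1]

    def validate(self) -> None:
        for name, rows in (("q", self.q), ("a", self.a), ("pik", self.pik)):
            sums = rows.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError(f"{name} rows must be stochastic")
        if np.any((self.exit < 0) | (self.exit > 1)):
            raise ValueError("exit probabilities must lie in [0, 1]")
        np.linalg.cholesky(self.covs)  # raises if not positive-definite


def _check_stochastic(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if np.any(mat < -1e-12) or not np.allclose(mat.sum(axis=-1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must be probabilities summing to 1")
    return mat


def generate_hl_sequence(
    occupancy: np.ndarray,
    transitions: np.ndarray,
    duration_frames: int,
    seed: int = 0,
) -> np.ndarray:
    """Markov chain of 1-based HL labels.

    The first state is drawn from the occupancy (occurrence)
    distribution; subsequent states follow the transition matrix.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    transitions = _check_stochastic(transitions)
    if not np.isclose(occupancy.sum(), 1.0, atol=1e-8):
        raise ValueError("occupancy must sum to 1")
    rng = np.random.default_rng(seed)
    n = occupancy.size
    seq = np.empty(duration_frames, dtype=np.int64)
    state = rng.choice(n, p=occupancy)
    # Pre-draw uniforms and use inverse-CDF lookup per row for speed.
    cdf = np.cumsum(transitions, axis=1)
    u = rng.random(duration_frames)
    for t in range(duration_frames):
        seq[t] = state
        state = int(np.searchsorted(cdf[state], u[t]))
    return seq + 1


def simulate_hhmm(params: GroundTruthHHMM, t: int, seed: int = 0):
    """Sample an observable stream and true labels from an HHMM.

    Returns ``(obs, hl, ll)`` where ``obs`` is an
    :class:`ObservableSeries` of length ``t`` and the labels are
    1-based.  HL dwell times are geometric with mean ``1 / exit``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n_hl, n_ll = params.n_hl, params.n_ll
    hl = np.empty(t, dtype=np.int64)
    ll = np.empty(t, dtype=np.int64)
    k = rng.choice(n_hl, p=params.pi0)
    i = rng.choice(n_ll, p=params.pik[k])
    chol = np.linalg.cholesky(params.covs)
    x = np.empty((t, 2))
    for step in range(t):
        hl[step], ll[step] = k, i
        x[step] = params.means[k, i] + chol[k, i] @ rng.standard_normal(2)
        if rng.random() < params.exit[k, i]:
            k = rng.choice(n_hl, p=params.q[k])
            i = rng.choice(n_ll, p=params.pik[k])
        else:
            i = rng.choice(n_ll, p=params.a[k, i])
    obs = ObservableSeries(v_par=x[:, 0], v_perp=x[:, 1])
    return obs, hl + 1, ll + 1


def sticky_transitions(
    occupancy: np.ndarray,
    stay: float = 14.0 / 15.0,
    bandwidth: float | None = 2.0,
) -> np.ndarray:
    """Sparse, sticky transition matrix targeting an occupancy profile.

    Off-diagonal mass from state i to j is proportional to the target
    occupancy of j, damped by ``exp(-|i - j| / bandwidth)`` so that
    transitions concentrate on kinematically neighboring states
    (band-diagonal structure).  ``bandwidth=None`` removes the damping,
    making the occupancy the exact stationary distribution.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    n = occupancy.size
    trans = np.zeros((n, n))
    for i in range(n):
        w = occupancy.copy()
        if bandwidth is not None:
            w = w * np.exp(-np.abs(np.arange(n) - i) / bandwidth)
        w[i] = 0.0
        if w.sum() == 0:
            w = np.ones(n)
            w[i] = 0.0
        trans[i] = (1.0 - stay) * w / w.sum()
        trans[i, i] = stay
    return trans


def well_separated_hhmm(
    n_hl: int = 2,
    n_ll: int = 2,
    separation: float = 5.0,
    sd: float = 1.0,
    exit_prob: float = 0.05,
    stay_ll: float = 0.85,
    seed: int = 0,
) -> GroundTruthHHMM:
    """Ground truth with joint-state emission means ``separation`` SDs apart.

    Means are placed on a grid with spacing ``separation * sd``; used
    for parameter- and label-recovery checks.
    """
    rng = np.random.default_rng(seed)
    k = n_hl * n_ll
    side = int(np.ceil(np.sqrt(k)))
    grid = np.array(
        [(i % side, i // side) for i in range(k)], dtype=float
    ) * separation * sd
    grid = grid - grid.mean(axis=0)
    means = grid.reshape(n_hl, n_ll, 2)
    covs = np.tile(np.eye(2) * sd**2, (n_hl, n_ll, 1, 1))
    q = sticky_transitions(np.full(n_hl, 1.0 / n_hl), stay=0.3, bandwidth=None) \
        if n_hl > 1 else np.ones((1, 1))
    a = (
        sticky_transitions(np.full(n_ll, 1.0 / n_ll), stay=stay_ll, bandwidth=None)
        if n_ll > 1
        else np.ones((1, 1))
    )
    return GroundTruthHHMM(
        q=q,
        a=np.tile(a, (n_hl, 1, 1)),
        exit=np.full((n_hl, n_ll), exit_prob),
        pi0=np.full(n_hl, 1.0 / n_hl),
        pik=np.full((n_hl, n_ll), 1.0 / n_ll),
        means=means,
        covs=covs,
    )


# ---------------------------------------------------------------------------
# default study conditions


def default_emission_catalog(n_hl: int = 10, n_ll: int = 5):
    """Gaussian (v_par, v_perp) parameters per (HL, LL) state.

    Units are normalized arena units per frame (1 cm/s ~ 0.0104).
    States 1-3 are slow (meander, stop-and-go, sharp turn), 4-7 medium
    speeds with tightly controlled v_par, 8-10 fast with right/right/
    left turning.
    """
    # Per-HL base (v_par cm/s, v_perp cm/s, sd_par cm/s, sd_perp cm/s).
    base = np.array(
        [
            [0.10, 0.00, 0.06, 0.08],  # 1 slow meander, turn-heavy
            [0.20, 0.00, 0.22, 0.08],  # 2 stop-and-go (wide v_par spread)
            [0.15, 0.00, 0.08, 0.18],  # 3 slow sharp turns
            [0.50, 0.00, 0.08, 0.08],  # 4 medium
            [0.65, 0.00, 0.08, 0.08],  # 5 medium
            [0.80, 0.00, 0.08, 0.08],  # 6 medium
            [0.95, 0.00, 0.08, 0.08],  # 7 medium-fast
            [1.50, 0.35, 0.12, 0.10],  # 8 fast, right turn (v_perp > 0)
            [2.10, 0.55, 0.12, 0.10],  # 9 faster, right turn
            [2.10, -0.55, 0.12, 0.10],  # 10 fast, left turn (v_perp < 0)
        ]
    )[:n_hl]
    means = np.empty((n_hl, n_ll, 2))
    covs = np.empty((n_hl, n_ll, 2, 2))
    # LL states fan out around the HL base along v_par.
    offsets = np.linspace(-1.0, 1.0, n_ll)
    for k in range(n_hl):
        v_par, v_perp, sd_par, sd_perp = base[k]
        for i in range(n_ll):
            means[k, i] = (
                np.array([v_par + offsets[i] * sd_par, v_perp]) * CM_PER_S
            )
            covs[k, i] = np.diag(
                [(0.8 * sd_par * CM_PER_S) ** 2, (sd_perp * CM_PER_S) ** 2]
            )
    return means, covs


def default_cluster_occupancies(n_hl: int = 10) -> np.ndarray:
    """Baseline HL occupancy targets for the four locomotor types.

    Cluster 1 alternates medium and slow states (heavy 5 and 7),
    cluster 2 is the slow/stopping type (dominated by state 2),
    cluster 3 uses the slower medium states (4-5), and cluster 4
    circles the arena in the fast states (8-10).
    """
    occ = np.array(
        [
            [0.08, 0.10, 0.06, 0.08, 0.22, 0.08, 0.22, 0.06, 0.05, 0.05],
            [0.08, 0.62, 0.06, 0.06, 0.05, 0.04, 0.03, 0.02, 0.02, 0.02],
            [0.06, 0.10, 0.06, 0.30, 0.28, 0.08, 0.04, 0.03, 0.03, 0.02],
            [0.04, 0.06, 0.04, 0.05, 0.06, 0.06, 0.09, 0.20, 0.20, 0.20],
        ]
    )[:, :n_hl]
    return occ / occ.sum(axis=1, keepdims=True)


def default_odor_shifts(n_hl: int = 10):
    """Multiplicative occupancy shifts applied at odor onset.

    Inside the odor zone usage shifts toward the slow states 1 and 3 at
    the expense of the fast states 7-10 (local search); outside it
    shifts toward the fast states 8-10 with less stopping (state 2).
    The magnitudes are set so that the configured effect is recoverable
    from a single trial per fly: occupancy responds within typical
    odor-zone visit durations despite entry transients and the
    correlation between position and state that track integration
    induces.  Returned as per-state multiplier vectors (renormalized
    after applying).
    """
    inside = np.ones(n_hl)
    inside[[0, 2]] = 6.0
    inside[6:] = 0.1
    outside = np.ones(n_hl)
    outside[1] = 0.3
    outside[7:] = 3.0
    return inside[:n_hl], outside[:n_hl]


@dataclass
class CohortConfig:
    """Study conditions for a synthetic arena cohort."""

    n_flies: int = 34
    duration_s: float = 360.0
    fps: float = FPS
    n_clusters: int = 4
    n_hl: int = 10
    n_ll: int = 5
    seed: int = 0
    odor_on_frame: int = DEFAULT_ODOR_ON_FRAME
    arena_radius_cm: float = DEFAULT_ARENA_RADIUS_CM
    odor_zone_radius_cm: float = DEFAULT_ODOR_ZONE_RADIUS_CM
    hl_stay: float = 14.0 / 15.0  # mean HL dwell of 15 frames (0.5 s)
    ll_stay: float = 0.80
    bandwidth: float | None = 2.0
    cluster_occupancies: np.ndarray | None = None  # (n_clusters, n_hl)
    odor_shift_inside: np.ndarray | None = None
    odor_shift_outside: np.ndarray | None = None
    emission_means: np.ndarray | None = None
    emission_covs: np.ndarray | None = None

    def resolve(self):
        occ = (
            self.cluster_occupancies
            if self.cluster_occupancies is not None
            else default_cluster_occupancies(self.n_hl)[: self.n_clusters]
        )
        sh_in, sh_out = default_odor_shifts(self.n_hl)
        if self.odor_shift_inside is not None:
            sh_in = np.asarray(self.odor_shift_inside, dtype=float)
        if self.odor_shift_outside is not None:
            sh_out = np.asarray(self.odor_shift_outside, dtype=float)
        if self.emission_means is None or self.emission_covs is None:
            means, covs = default_emission_catalog(self.n_hl, self.n_ll)
        else:
            means, covs = self.emission_means, self.emission_covs
        return np.asarray(occ, dtype=float), sh_in, sh_out, means, covs


@dataclass
class FlyTruth:
    """Ground truth emitted alongside one synthetic fly."""

    rec: TrajectoryRecord
    obs: ObservableSeries  # the generating emissions (pre-integration)
    hl: np.ndarray  # true HL labels, aligned with obs
    ll: np.ndarray
    cluster: int  # 1-based cluster id
    first_entry_frame: int | None = None


def _shifted(occ: np.ndarray, mult: np.ndarray) -> np.ndarray:
    out = occ * mult
    return out / out.sum()


def synthesize_cohort(config: CohortConfig | None = None) -> list[FlyTruth]:
    """Generate a full cohort of arena trajectories with ground truth.

    Each fly belongs to a cluster that sets its baseline HL occupancy
    (hence transition matrix).  The (v_par, v_perp) emissions of a
    hierarchical state simulation are integrated into an (x, y) track by
    heading propagation, with reflection of the radial velocity
    component at the arena wall.  From odor onset, HL transitions drawn
    while the fly is inside the odor zone follow the inside-shifted
    matrix; once the fly has entered the zone after onset (first entry),
    transitions outside follow the outside-shifted matrix.
    """
    config = config or CohortConfig()
    occ, sh_in, sh_out, means, covs = config.resolve()
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration_s * config.fps))
    chol = np.linalg.cholesky(covs)
    n_hl, n_ll = config.n_hl, config.n_ll
    exit_prob = 1.0 - config.hl_stay
    a_ll = sticky_transitions(
        np.full(n_ll, 1.0 / n_ll), stay=config.ll_stay, bandwidth=None
    ) if n_ll > 1 else np.ones((1, 1))
    pik = np.full(n_ll, 1.0 / n_ll)
    zone_r = config.odor_zone_radius_cm / config.arena_radius_cm

    # Per-cluster HL transition matrices for the three regimes.
    regimes = []
    for c in range(occ.shape[0]):
        # Stickiness comes from the exit gate (mean HL dwell
        # 1/(1 - hl_stay) frames); the regime matrices are pure jump
        # kernels, so their diagonal must stay empty or dwells would be
        # gated twice.
        base = sticky_transitions(occ[c], stay=0.0,
                                  bandwidth=config.bandwidth)
        # Odor regimes target their shifted occupancy directly (no band
        # damping): the shifted occupancy is then the exact stationary
        # distribution, so short zone visits still move the needle.
        inside = sticky_transitions(_shifted(occ[c], sh_in),
                                    stay=0.0, bandwidth=None)
        outside = sticky_transitions(_shifted(occ[c], sh_out),
                                     stay=0.0, bandwidth=None)
        regimes.append((base, inside, outside))

    clusters = np.sort(
        np.arange(config.n_flies) % occ.shape[0]
    )
    flies = []
    for fly_idx in range(config.n_flies):
        c = int(clusters[fly_idx])
        base_t, inside_t, outside_t = regimes[c]
        fly_seed = int(rng.integers(0, 2**31 - 1))
        flies.append(
            _simulate_fly(
                fly_idx, c, n_frames, config, occ[c], base_t, inside_t,
                outside_t, a_ll, pik, exit_prob, means, chol, zone_r,
                np.random.default_rng(fly_seed),
            )
        )
    return flies


def _simulate_fly(
    fly_idx, cluster, n_frames, config, occ, base_t, inside_t, outside_t,
    a_ll, pik, exit_prob, means, chol, zone_r, rng,
) -> FlyTruth:
    n_hl, n_ll = config.n_hl, config.n_ll
    # Initial position away from the wall, random heading, tiny first step.
    r0 = 0.8 * np.sqrt(rng.random())
    phi0 = rng.random() * 2.0 * np.pi
    pos = np.array([r0 * np.cos(phi0), r0 * np.sin(phi0)])
    theta = rng.random() * 2.0 * np.pi
    u = np.array([np.cos(theta), np.sin(theta)])
    step0 = 0.2 * CM_PER_S
    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    xs[0], ys[0] = pos
    pos = pos + step0 * u
    pos, u = _reflect(pos, u)
    xs[1], ys[1] = pos

    n_obs = n_frames - 2
    hl = np.empty(n_obs, dtype=np.int64)
    ll = np.empty(n_obs, dtype=np.int64)
    v_par = np.empty(n_obs)
    v_perp = np.empty(n_obs)
    k = rng.choice(n_hl, p=occ)
    i = rng.choice(n_ll, p=pik)
    entered = False
    first_entry_frame = None
    for step in range(n_obs):
        frame = step + 2
        hl[step], ll[step] = k + 1, i + 1
        e = means[k, i] + chol[k, i] @ rng.standard_normal(2)
        v_par[step], v_perp[step] = e
        d = e[0] * u + e[1] * np.array([u[1], -u[0]])
        pos = pos + d
        norm = np.hypot(*d)
        if norm > 1e-14:
            u = d / norm
        pos, u = _reflect(pos, u)
        xs[frame], ys[frame] = pos
        inside = np.hypot(*pos) <= zone_r
        after_onset = frame >= config.odor_on_frame
        if after_onset and inside and not entered:
            entered = True
            first_entry_frame = frame
        # HL dynamics with the regime in force at this frame.
        if rng.random() < exit_prob:
            if after_onset and inside:
                trans = inside_t
            elif entered:
                trans = outside_t
            else:
                trans = base_t
            k = rng.choice(n_hl, p=trans[k])
            i = rng.choice(n_ll, p=pik)
        else:
            i = rng.choice(n_ll, p=a_ll[i])
    rec = TrajectoryRecord(
        fly_id=f"synthetic-fly-{fly_idx:02d}",
        t=np.arange(n_frames),
        x=xs,
        y=ys,
        arena_radius_cm=config.arena_radius_cm,
        odor_zone_radius_cm=config.odor_zone_radius_cm,
        odor_on_frame=config.odor_on_frame,
    )
    obs = ObservableSeries(
        v_par=v_par, v_perp=v_perp, frames=np.arange(2, n_frames),
        fly_id=rec.fly_id,
    )
    return FlyTruth(
        rec=rec, obs=obs, hl=hl, ll=ll, cluster=cluster + 1,
        first_entry_frame=first_entry_frame,
    )


def _reflect(pos: np.ndarray, u: np.ndarray):
    """Reflect a position (and the radial heading component) at the wall."""
    r = np.hypot(*pos)
    if r <= 1.0:
        return pos, u
    rad = pos / r
    pos = pos - 2.0 * (r - 1.0) * rad
    u = u - 2.0 * (u @ rad) * rad
    n = np.hypot(*u)
    return pos, (u / n if n > 0 else u)


def synthetic_fly_occupancies(
    occupancy: np.ndarray,
    transitions: np.ndarray,
    duration_frames: int,
    n_flies: int = 34,
    n_sets: int = 100,
    seed: int = 0,
) -> list[np.ndarray]:
    """Occupancy vectors of HL-only synthetic flies (the distance null).

    Each set holds ``n_flies`` flies simulated from the *same* occupancy
    and transition structure; their empirical occupancy vectors provide
    the null distribution of fly-to-fly distances expected from
    sampling noise alone.
    """
    n = np.asarray(occupancy).size
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        mat = np.empty((n_flies, n))
        for f in range(n_flies):
            chain = generate_hl_sequence(
                occupancy, transitions, duration_frames,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            mat[f] = np.bincount(chain, minlength=n + 1)[1:] / duration_frames
        sets.append(mat)
    return sets
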