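"""Odor-evoked changes in HL-state occupancy, with bootstrap inference.

Frames are parsed into four scenarios by position and odor history:
inside/outside the odor zone, before/after the fly's first entry into
the zone once the odor is on (B_I, B_O, D_I, D_O).  Occupancy vectors
are per-fly distributions over HL states within a scenario; cohort
means carry BCa bootstrap confidence intervals (resampling flies), and
before-vs-during differences are tested with a bootstrap test for equal
means followed by Holm-Bonferroni correction across states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import TrajectoryRecord
from .state_analysis import StateSequence, UNASSIGNED

__all__ = [
    "B_I", "B_O", "D_I", "D_O", "EXCLUDED", "SCENARIO_NAMES",
    "ScenarioLabels",
    "OccupancyVector",
    "parse_scenarios",
    "occupancy_vector",
    "occupancy_stats",
    "bootstrap_equal_means",
    "equal_means_table",
    "spatial_map",
    "SpatialMap",
]

EXCLUDED, B_I, B_O, D_I, D_O = 0, 1, 2, 3, 4
SCENARIO_NAMES = {B_I: "B_I", B_O: "B_O", D_I: "D_I", D_O: "D_O",
                  EXCLUDED: "excluded"}


@dataclass
class ScenarioLabels:
    """Per-frame scenario codes aligned with a trajectory's frames."""

    codes: np.ndarray  # int codes, one per trajectory frame
    first_entry_frame: int | None  # frame index of first entry, or None
    zone_radius: float  # normalized odor-zone radius used

    def __len__(self) -> int:
        return self.codes.size

    def for_observables(self) -> np.ndarray:
        """Codes aligned with an observable/state series (drops 2 frames)."""
        return self.codes[2:]

    def counts(self) -> dict:
        return {
            SCENARIO_NAMES[c]: int((self.codes == c).sum())
            for c in (B_I, B_O, D_I, D_O, EXCLUDED)
        }


def parse_scenarios(rec: TrajectoryRecord) -> ScenarioLabels:
    """Label every frame as B_I / B_O / D_I / D_O.

    A frame is *inside* when the radial distance is at or below the
    normalized zone radius (1.5/3.2 = 0.46875 by default; boundary
    counts as inside).  The *during* period starts at the first inside
    frame at or after the odor-onset frame; if the fly never enters the
    zone after onset, every frame stays "before" and the condition is
    flagged on the result (``first_entry_frame is None``).
    """
    r = rec.radius()
    zone = rec.zone_radius
    inside = r <= zone
    after_onset = rec.t >= rec.odor_on_frame
    entry_candidates = np.flatnonzero(inside & after_onset)
    if entry_candidates.size:
        first_entry_idx = int(entry_candidates[0])
        first_entry_frame = int(rec.t[first_entry_idx])
        during = np.arange(rec.n_frames) >= first_entry_idx
    else:
        first_entry_frame = None
        during = np.zeros(rec.n_frames, dtype=bool)
    codes = np.where(
        during,
        np.where(inside, D_I, D_O),
        np.where(inside, B_I, B_O),
    ).astype(np.int8)
    return ScenarioLabels(
        codes=codes, first_entry_frame=first_entry_frame, zone_radius=zone
    )


@dataclass
class OccupancyVector:
    """Distribution over HL states for one fly in one scenario."""

    p: np.ndarray  # (n_states,) probabilities over assigned frames
    n_frames: int  # assigned frames in the scenario
    sd: np.ndarray  # per-state SD: sqrt(p (1-p) / (N-1))

    @classmethod
    def from_labels(cls, hl: np.ndarray, n_states: int) -> "OccupancyVector":
        hl = hl[hl != UNASSIGNED]
        n = hl.size
        if n == 0:
            nan = np.full(n_states, np.nan)
            return cls(p=nan, n_frames=0, sd=nan.copy())
        p = np.bincount(hl, minlength=n_states + 1)[1:].astype(float) / n
        sd = np.sqrt(p * (1.0 - p) / max(n - 1, 1))
        return cls(p=p, n_frames=n, sd=sd)


def occupancy_vector(
    seq: StateSequence,
    labels: ScenarioLabels,
    scenario: int,
    n_states: int,
) -> OccupancyVector:
    """One fly's HL occupancy within a scenario (assigned frames only)."""
    codes = labels.for_observables()
    if codes.size != len(seq):
        raise ValueError(
            f"scenario labels ({codes.size}) do not match state sequence "
            f"({len(seq)})"
        )
    return OccupancyVector.from_labels(seq.hl[codes == scenario], n_states)


def occupancy_stats(
    seqs: list,
    labels_list: list,
    n_states: int,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Cohort occupancy per scenario with BCa intervals over flies.

    Returns ``{scenario_name: (mean_occupancy, lo, hi, per_fly_matrix)}``
    where the interval bounds are per-state BCa bootstrap confidence
    limits obtained by resampling flies.  Flies with no assigned frames
    in a scenario are dropped from that scenario (flagged as NaN rows in
    the per-fly matrix).
    """
    rng = np.random.default_rng(seed)
    results = {}
    for scenario in (B_I, B_O, D_I, D_O):
        per_fly = np.array(
            [
                occupancy_vector(s, l, scenario, n_states).p
                for s, l in zip(seqs, labels_list)
            ]
        )
        valid = per_fly[~np.isnan(per_fly).any(axis=1)]
        if valid.shape[0] == 0:
            nan = np.full(n_states, np.nan)
            results[SCENARIO_NAMES[scenario]] = (nan, nan, nan, per_fly)
            continue
        mean = valid.mean(axis=0)
        lo = np.empty(n_states)
        hi = np.empty(n_states)
        for j in range(n_states):
            col = valid[:, j]
            if np.ptp(col) == 0 or valid.shape[0] < 3:
                lo[j] = hi[j] = col.mean()
                continue
            res = stats.bootstrap(
                (col,),
                np.mean,
                n_resamples=n_boot,
                confidence_level=1.0 - alpha,
                method="BCa",
                random_state=rng,
            )
            lo[j], hi[j] = res.confidence_interval
        results[SCENARIO_NAMES[scenario]] = (mean, lo, hi, per_fly)
    return results


def _ts(a_mean, b_mean, a_var, b_var, n):
    denom = np.sqrt(a_var / n + b_var / n)
    num = a_mean - b_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        ts = np.where(
            denom > 0, num / np.where(denom > 0, denom, 1.0),
            np.where(num == 0, 0.0, np.inf * np.sign(num)),
        )
    return ts


def bootstrap_equal_means(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-tailed bootstrap test that two paired-size samples share a mean.

    Populations A and B are recentered onto their common (pooled) mean
    to build null populations F and G; bootstrap resamples of each give
    the null distribution of the Welch-type statistic
    ``TS = (mean_F' - mean_G') / sqrt(var_F'/n + var_G'/n)``.  The
    returned p-value is the add-one-smoothed fraction of null draws at
    least as extreme as TS(A, B).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must have equal length")
    n = a.size
    rng = np.random.default_rng(seed)
    pooled_var = np.var(a, ddof=1) + np.var(b, ddof=1)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 1.0
        warnings.warn("zero-variance samples with unequal means")
        return 1.0 / (n_boot + 1)
    grand = 0.5 * (a.mean() + b.mean())
    f = a - a.mean() + grand
    g = b - b.mean() + grand
    fb = f[rng.integers(0, n, size=(n_boot, n))]
    gb = g[rng.integers(0, n, size=(n_boot, n))]
    null = _ts(
        fb.mean(axis=1), gb.mean(axis=1),
        fb.var(axis=1, ddof=1), gb.var(axis=1, ddof=1), n,
    )
    observed = _ts(a.mean(), b.mean(), np.var(a, ddof=1), np.var(b, ddof=1), n)
    n_extreme = int(np.sum(np.abs(null) >= np.abs(observed)))
    return (1.0 + n_extreme) / (n_boot + 1.0)


def equal_means_table(
    before: np.ndarray,
    during: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha_corrected: float = 0.05,
    alpha_uncorrected: float = 0.01,
) -> pd.DataFrame:
    """Per-state bootstrap tests with Holm-Bonferroni correction.

    ``before`` and ``during`` are (n_flies, n_states) per-fly occupancy
    matrices.  Significance is reported two ways: at 0.05 after
    Holm-Bonferroni across the states, and at 0.01 without correction.  Flies with NaN occupancy in either
    condition are dropped pairwise per state.
    """
    from statsmodels.stats.multitest import multipletests

    n_states = before.shape[1]
    pvals = np.empty(n_states)
    for j in range(n_states):
        keep = ~(np.isnan(before[:, j]) | np.isnan(during[:, j]))
        pvals[j] = bootstrap_equal_means(
            before[keep, j], during[keep, j], n_boot=n_boot, seed=seed + j
        )
    sig_holm = multipletests(pvals, alpha=alpha_corrected, method="holm")[0]
    return pd.DataFrame(
        {
            "hl": np.arange(1, n_states + 1),
            "p_value": pvals,
            "significant_holm_05": sig_holm,
            "significant_uncorrected_01": pvals < alpha_uncorrected,
        }
    )


@dataclass
class SpatialMap:
    """Per-bin conditional HL-state occupancy before and during odor."""

    before: np.ndarray  # (grid, grid, n_states) P(state | bin), NaN-masked
    during: np.ndarray
    counts_before: np.ndarray  # (grid, grid) assigned frames per bin
    counts_during: np.ndarray
    edges: np.ndarray  # shared bin edges spanning [-1, 1]

    @property
    def difference(self) -> np.ndarray:
        return self.during - self.before

    def radial_profile(self, which: str = "difference", n_rings: int = 30):
        """Mean per-state occupancy as a function of radial distance."""
        grid = self.before.shape[0]
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        xx, yy = np.meshgrid(centers, centers, indexing="ij")
        rr = np.hypot(xx, yy)
        data = {
            "before": self.before, "during": self.during,
            "difference": self.difference,
        }[which]
        ring_edges = np.linspace(0, 1, n_rings + 1)
        prof = np.full((n_rings, data.shape[2]), np.nan)
        for i in range(n_rings):
            mask = (rr >= ring_edges[i]) & (rr < ring_edges[i + 1])
            vals = data[mask]
            if np.isfinite(vals).any():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    prof[i] = np.nanmean(vals, axis=0)
        return 0.5 * (ring_edges[:-1] + ring_edges[1:]), prof


def spatial_map(
    recs: list,
    seqs: list,
    labels_list: list,
    n_states: int,
    grid: int = 60,
    min_frames: int = 20,
) -> SpatialMap:
    """Bin the arena into ``grid x grid`` cells over [-1, 1]^2 and compute
    per-bin conditional state probabilities before vs during odor.

    Bins with fewer than ``min_frames`` assigned frames are masked NaN.
    Per bin, the probabilities over states sum to one.
    """
    edges = np.linspace(-1.0, 1.0, grid + 1)
    counts = {
        "before": np.zeros((grid, grid, n_states)),
        "during": np.zeros((grid, grid, n_states)),
    }
    for rec, seq, labels in zip(recs, seqs, labels_list):
        x = rec.x[2:]
        y = rec.y[2:]
        codes = labels.for_observables()
        assigned = seq.assigned
        for name, members in (("before", (B_I, B_O)), ("during", (D_I, D_O))):
            mask = assigned & np.isin(codes, members)
            if not mask.any():
                continue
            ix = np.clip(np.searchsorted(edges, x[mask], side="right") - 1, 0, grid - 1)
            iy = np.clip(np.searchsorted(edges, y[mask], side="right") - 1, 0, grid - 1)
            states = seq.hl[mask] - 1
            np.add.at(counts[name], (ix, iy, states), 1.0)
    out = {}
    totals = {}
    for name in ("before", "during"):
        tot = counts[name].sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts[name] / tot[:, :, None]
        p[tot < min_frames] = np.nan
        out[name] = p
        totals[name] = tot
    return SpatialMap(
        before=out["before"],
        during=out["during"],
        counts_before=totals["before"],
        counts_during=totals["during"],
        edges=edges,
    )
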