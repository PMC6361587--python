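"""End-to-end cohort analysis: trajectories to clusters and odor effects.

Chains the full workflow on a cohort of trajectories: observable
extraction and outlier clipping, pooled HHMM fitting, MAP decoding with
confidence filtering and despiking, kinematic state ordering, scenario
parsing, per-fly occupancy vectors, X-means fly clustering and the
bootstrap test for odor-evoked occupancy changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fly_clustering, hhmm, odor_stats, preprocessing, state_analysis

__all__ = ["CohortAnalysis", "analyze_cohort"]


@dataclass
class CohortAnalysis:
    """Everything the cohort workflow produces."""

    posterior: hhmm.HHMMPosterior
    seqs: list  # despiked, speed-ordered StateSequence per fly
    labels: list  # ScenarioLabels per fly
    occupancy: dict  # scenario name -> (n_flies, n_states) matrix
    clusters: fly_clustering.ClusterModel  # X-means on B_O occupancy
    state_order: np.ndarray
    assigned_fraction: np.ndarray  # per fly, after filtering

    def occupancy_table(self):
        """Tidy per-fly occupancy: one row per fly x scenario x state."""
        import pandas as pd

        rows = []
        for scenario, mat in self.occupancy.items():
            for fly, vec in enumerate(mat):
                for state, p in enumerate(vec, start=1):
                    rows.append(
                        {"fly": fly, "scenario": scenario, "hl": state,
                         "p": p}
                    )
        return pd.DataFrame(rows)


def analyze_cohort(
    recs: list,
    fit_spec: hhmm.HHMMSpec,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 80,
    tol: float = 1e-5,
    cluster_scenario: str = "B_O",
) -> CohortAnalysis:
    """Run the trajectory-to-clusters pipeline on a list of trajectories."""
    obs_list = []
    kinematics = []
    for i, rec in enumerate(recs):
        obs = preprocessing.compute_observables(rec)
        obs = preprocessing.clip_outliers(obs, seed=seed + 1000 + i)
        obs = preprocessing.speed_curvature(obs, rec)
        obs_list.append(obs)
        kinematics.append((obs.speed, obs.curvature))
    post = hhmm.vbem_fit(
        [o.as_matrix() for o in obs_list],
        fit_spec,
        seed=seed,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        standardize="global",  # one model shared across flies
    )
    raw_seqs = []
    for i, obs in enumerate(obs_list):
        x = obs.as_matrix()
        if post.standardize_mean is not None:
            x = (x - post.standardize_mean[i]) / post.standardize_sd[i]
        sp, _ = hhmm.e_step(x, post)
        raw_seqs.append(hhmm.map_states(sp))
    # Order states from slow/turning to fast/straight on pooled kinematics.
    pooled_hl = np.concatenate([s.hl for s in raw_seqs])
    pooled_conf = np.concatenate([s.confidence for s in raw_seqs])
    pooled_seq = state_analysis.StateSequence(
        hl=pooled_hl, ll=np.ones_like(pooled_hl), confidence=pooled_conf
    )
    order = state_analysis.sort_states(
        pooled_seq,
        np.concatenate([k[0] for k in kinematics]),
        np.concatenate([k[1] for k in kinematics]),
        n_states=fit_spec.n_hl,
    )
    seqs = [
        state_analysis.filter_and_despike(
            state_analysis.apply_state_order(s, order)
        )
        for s in raw_seqs
    ]
    labels = [odor_stats.parse_scenarios(rec) for rec in recs]
    occupancy = {}
    for scenario, name in ((odor_stats.B_I, "B_I"), (odor_stats.B_O, "B_O"),
                           (odor_stats.D_I, "D_I"), (odor_stats.D_O, "D_O")):
        occupancy[name] = np.array(
            [
                odor_stats.occupancy_vector(s, l, scenario, fit_spec.n_hl).p
                for s, l in zip(seqs, labels)
            ]
        )
    cluster_occ = occupancy[cluster_scenario]
    valid = ~np.isnan(cluster_occ).any(axis=1)
    clusters = fly_clustering.xmeans(cluster_occ[valid], seed=seed)
    assigned = np.array([s.assigned.mean() for s in seqs])
    return CohortAnalysis(
        posterior=post,
        seqs=seqs,
        labels=labels,
        occupancy=occupancy,
        clusters=clusters,
        state_order=order,
        assigned_fraction=assigned,
    )
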