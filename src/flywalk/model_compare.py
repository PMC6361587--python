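"""Bayesian comparison of hierarchical vs flat HMMs via ELBOs.

Evidence lower bounds approximate the marginal likelihoods
P(O|HHMM) and P(O|HMM); under a flat model prior the posterior
probability of the hierarchical model is a logistic function of the log
Bayes factor, P(HHMM|O) = 1 / (1 + exp(-log K)).  Matched comparisons
pair models with equal joint-state counts (e.g. a 6x4 HHMM against a
24-state HMM), the flat model being fit with the same variational
machinery as a one-level model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hhmm import HHMMPosterior, HHMMSpec, count_parameters

__all__ = ["ComparisonResult", "bayes_compare", "compare_posteriors"]


@dataclass
class ComparisonResult:
    """Outcome of a two-model Bayes comparison (HHMM over HMM)."""

    log_K: float
    p_hhmm: float
    n_params: tuple[int, int] | None = None  # (hhmm, hmm)

    @property
    def p_reject_hmm(self) -> float:
        """The comparison rejects the flat model at p < 1 - p_hhmm."""
        return 1.0 - self.p_hhmm

    def summary(self) -> str:
        lines = [
            f"log Bayes factor (HHMM over HMM): {self.log_K:.4f}",
            f"P(HHMM | O) = {self.p_hhmm:.6g}",
            f"reject HMM at p < {self.p_reject_hmm:.3g}",
        ]
        if self.n_params is not None:
            lines.append(
                f"parameters: HHMM {self.n_params[0]}, HMM {self.n_params[1]}"
            )
        return "\n".join(lines)


def bayes_compare(
    elbo_hhmm: float,
    elbo_hmm: float,
    n_frames_hhmm: int | None = None,
    n_frames_hmm: int | None = None,
) -> ComparisonResult:
    """Posterior probability of the hierarchical model under a flat prior.

    ``log_K = elbo_hhmm - elbo_hmm`` and
    ``p_hhmm = 1 / (1 + exp(-log_K))``.  Both bounds must come from the
    same data; pass the frame counts to have this checked.
    """
    if not (np.isfinite(elbo_hhmm) and np.isfinite(elbo_hmm)):
        raise ValueError("ELBOs must be finite")
    if (
        n_frames_hhmm is not None
        and n_frames_hmm is not None
        and n_frames_hhmm != n_frames_hmm
    ):
        raise ValueError(
            "ELBOs computed on different amounts of data "
            f"({n_frames_hhmm} vs {n_frames_hmm} frames)"
        )
    log_k = float(elbo_hhmm - elbo_hmm)
    # Numerically stable logistic.
    if log_k >= 0:
        p = 1.0 / (1.0 + np.exp(-log_k))
    else:
        e = np.exp(log_k)
        p = e / (1.0 + e)
    return ComparisonResult(log_K=log_k, p_hhmm=float(p))


def compare_posteriors(
    post_hhmm: HHMMPosterior,
    post_hmm: HHMMPosterior,
    emission_params: int = 5,
) -> ComparisonResult:
    """Compare two fitted posteriors, attaching parameter counts.

    A bivariate-Gaussian emission has five parameters
    (mu1, mu2, sigma1, sigma2, rho).
    """
    res = bayes_compare(post_hhmm.elbo, post_hmm.elbo)
    n_hhmm = count_parameters(
        [post_hhmm.spec.n_hl, post_hhmm.spec.n_ll], emission_params
    )
    flat_spec = post_hmm.spec
    if flat_spec.n_hl == 1:
        n_hmm = count_parameters([flat_spec.n_ll], emission_params)
    else:
        n_hmm = count_parameters(
            [flat_spec.n_hl, flat_spec.n_ll], emission_params
        )
    res.n_params = (n_hhmm, n_hmm)
    return res


def matched_hmm_spec(spec: HHMMSpec) -> HHMMSpec:
    """Flat one-level spec with the same joint-state count as ``spec``."""
    return HHMMSpec(
        n_hl=1,
        n_ll=spec.n_joint,
        emission_dim=spec.emission_dim,
        exit_mode="none",
    )
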