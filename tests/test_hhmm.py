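"""Core HHMM machinery: flattening, E/M steps, fitting, MAP decoding."""

import numpy as np
import pytest
from scipy.stats import chi2, multivariate_normal

from flywalk import hhmm
from flywalk.hhmm import (
    HHMMPosterior,
    HHMMPriors,
    HHMMSpec,
    StatePosterior,
    SufficientStats,
    count_parameters,
    e_step,
    flatten,
    load_posterior,
    m_step,
    map_states,
    save_posterior,
    vbem_fit,
)
from flywalk.synthetic_data import simulate_hhmm, well_separated_hhmm


def random_posterior(spec, seed=0, priors=None):
    """A valid posterior with randomized counts (for oracle checks)."""
    rng = np.random.default_rng(seed)
    priors = priors or HHMMPriors()
    suff = SufficientStats.zeros(spec)
    suff.counts_Q += rng.random((spec.n_hl, spec.n_hl)) * 10
    suff.counts_A += rng.random((spec.n_hl, spec.n_ll, spec.n_ll + 1)) * 10
    if not spec.has_exit:
        suff.counts_A[:, :, spec.n_ll] = 0.0
    suff.counts_pi0 += rng.random(spec.n_hl)
    suff.counts_pik += rng.random((spec.n_hl, spec.n_ll))
    k = spec.n_joint
    suff.n_emit += rng.random(k) * 50 + 5
    suff.sum_x += rng.standard_normal((k, 2)) * suff.n_emit[:, None]
    for s in range(k):
        a = rng.standard_normal((2, 2))
        xbar = suff.sum_x[s] / suff.n_emit[s]
        suff.sum_xx[s] = (
            (a @ a.T + 2 * np.eye(2)) * suff.n_emit[s]
            + np.outer(xbar, xbar) * suff.n_emit[s]
        )
    return m_step(suff, priors, spec)


class TestCountParameters:
    @pytest.mark.parametrize(
        "levels,expected",
        [
            ([10, 5], 600),
            ([6, 4], 252),
            ([8, 4], 352),
            ([24], 696),
            ([32], 1184),
        ],
    )
    def test_published_counts(self, levels, expected):
        assert count_parameters(levels, 5) == expected

    def test_empty_levels_rejected(self):
        with pytest.raises(ValueError):
            count_parameters([], 5)


class TestFlatten:
    def test_single_hl_renormalizes_exit_into_self_block(self):
        spec = HHMMSpec(n_hl=1, n_ll=3)
        post = random_posterior(spec, seed=1)
        trans, init, _ = flatten(post, mode="expected")
        a = post.expected_A()
        expected = a[0, :, :3] + np.outer(a[0, :, 3], post.expected_pik()[0])
        np.testing.assert_allclose(trans, expected, atol=1e-12)
        np.testing.assert_allclose(trans.sum(axis=1), 1.0, atol=1e-12)

    def test_cross_blocks_are_rank_one(self):
        spec = HHMMSpec(n_hl=2, n_ll=2)
        post = random_posterior(spec, seed=2)
        trans, _, _ = flatten(post, mode="expected")
        block = trans[0:2, 2:4]
        assert np.linalg.matrix_rank(block, tol=1e-10) == 1

    def test_flat_likelihood_matches_hierarchical_recursion(self):
        # Independent oracle: propagate the joint distribution using the
        # stay/exit branch law directly, never forming the flat matrix.
        spec = HHMMSpec(n_hl=3, n_ll=2)
        post = random_posterior(spec, seed=3)
        rng = np.random.default_rng(4)
        t_len = 50
        x = rng.standard_normal((t_len, 2))
        a = post.expected_A()
        q = post.expected_Q()
        pi0 = post.expected_pi0()
        pik = post.expected_pik()
        means, covs = post.expected_means(), post.expected_covs()
        dens = np.array(
            [
                multivariate_normal.pdf(x, means[s], covs[s])
                for s in range(spec.n_joint)
            ]
        ).T.reshape(t_len, spec.n_hl, spec.n_ll)
        p = pi0[:, None] * pik * dens[0]
        log_l_oracle = np.log(p.sum())
        p = p / p.sum()
        for t in range(1, t_len):
            nxt = np.zeros_like(p)
            for k in range(spec.n_hl):
                for i in range(spec.n_ll):
                    mass = p[k, i]
                    # stay branch
                    nxt[k, :] += mass * a[k, i, :spec.n_ll]
                    # exit branch: HL move then LL re-entry
                    nxt += mass * a[k, i, spec.n_ll] * q[k][:, None] * pik
            p = nxt * dens[t]
            s = p.sum()
            log_l_oracle += np.log(s)
            p = p / s

        trans, init, _ = flatten(post, mode="expected")
        flat_dens = dens.reshape(t_len, spec.n_joint)
        alpha = init * flat_dens[0]
        log_l_flat = np.log(alpha.sum())
        alpha = alpha / alpha.sum()
        for t in range(1, t_len):
            alpha = (alpha @ trans) * flat_dens[t]
            s = alpha.sum()
            log_l_flat += np.log(s)
            alpha = alpha / s
        assert abs(log_l_flat - log_l_oracle) < 1e-8


class TestEStep:
    def test_single_frame_marginal(self):
        spec = HHMMSpec(n_hl=2, n_ll=2)
        post = random_posterior(spec, seed=5)
        x = np.array([[0.3, -0.2]])
        sp, _ = e_step(x, post)
        from flywalk.hhmm import _expected_log_emission, _star_params

        _, _, pi0_star, pik_star = _star_params(post)
        log_b = _expected_log_emission(post, x)[0]
        expected = (pi0_star[:, None] * pik_star).reshape(-1) * np.exp(
            log_b - log_b.max()
        )
        expected /= expected.sum()
        np.testing.assert_allclose(
            sp.gamma.reshape(-1), expected, atol=1e-12
        )

    def test_symmetric_model_gives_uniform_responsibilities(self):
        spec = HHMMSpec(n_hl=2, n_ll=2)
        priors = HHMMPriors()
        suff = SufficientStats.zeros(spec)
        # Equal counts everywhere -> exchangeable states.
        suff.counts_Q += 5.0
        suff.counts_A += 5.0
        suff.counts_pi0 += 1.0
        suff.counts_pik += 1.0
        suff.n_emit += 50.0
        suff.sum_xx += 100.0 * np.eye(2)
        post = m_step(suff, priors, spec)
        rng = np.random.default_rng(6)
        sp, _ = e_step(rng.standard_normal((20, 2)), post)
        np.testing.assert_allclose(sp.gamma.reshape(20, -1), 0.25, atol=1e-10)

    def test_non_finite_observation_rejected(self):
        spec = HHMMSpec(n_hl=2, n_ll=2)
        post = random_posterior(spec, seed=7)
        x = np.array([[0.0, np.nan], [0.0, 0.0]])
        with pytest.raises(ValueError):
            e_step(x, post)


class TestMStep:
    def test_zero_counts_recover_prior(self):
        spec = HHMMSpec(n_hl=2, n_ll=3)
        priors = HHMMPriors()
        post = m_step(SufficientStats.zeros(spec), priors, spec)
        np.testing.assert_allclose(post.q_Q, priors.q_rows(spec))
        np.testing.assert_allclose(post.q_A, priors.a_rows(spec))
        np.testing.assert_allclose(post.kappa, priors.niw_kappa)

    def test_gaussian_mean_conjugate_update(self):
        rng = np.random.default_rng(8)
        spec = HHMMSpec(n_hl=1, n_ll=1, exit_mode="none")
        priors = HHMMPriors()
        m_true = np.array([1.5, -0.7])
        x = m_true + rng.standard_normal((1000, 2))
        suff = SufficientStats.zeros(spec)
        suff.counts_pi0 += 1
        suff.counts_pik += 1
        suff.n_emit += 1000.0
        suff.sum_x += x.sum(axis=0)
        suff.sum_xx[0] += x.T @ x
        post = m_step(suff, priors, spec)
        assert np.all(np.abs(post.m[0] - m_true) < 3.0 / np.sqrt(1000))

    def test_dirichlet_posterior_mean(self):
        spec = HHMMSpec(n_hl=4, n_ll=1, exit_mode="none")
        priors = HHMMPriors(init_alpha=0.5)
        suff = SufficientStats.zeros(spec)
        suff.counts_pi0 += 1.0  # one observation per category
        post = m_step(suff, priors, spec)
        k, alpha = 4, 0.5
        expected = (alpha + 1) / (k * alpha + k)
        np.testing.assert_allclose(post.expected_pi0(), expected)

    def test_negative_counts_rejected(self):
        spec = HHMMSpec(n_hl=2, n_ll=2)
        suff = SufficientStats.zeros(spec)
        suff.counts_Q -= 1.0
        with pytest.raises(RuntimeError):
            m_step(suff, HHMMPriors(), spec)


class TestVBEMFit:
    def test_single_state_recovers_gaussian_mean(self):
        rng = np.random.default_rng(9)
        m_true = np.array([0.8, -0.3])
        x = m_true + 0.5 * rng.standard_normal((2000, 2))
        spec = HHMMSpec(n_hl=1, n_ll=1, exit_mode="none")
        post = vbem_fit(x, spec, max_iter=50, n_restarts=1, seed=1,
                        standardize=False)
        cov = post.expected_covs()[0]
        sd_mean = np.sqrt(np.diag(cov) / post.kappa[0])
        assert np.all(np.abs(post.m[0] - m_true) < 2 * sd_mean + 0.05)

    def test_elbo_trace_non_decreasing(self):
        gt = well_separated_hhmm(2, 2, separation=4.0, seed=10)
        obs, _, _ = simulate_hhmm(gt, 1500, seed=11)
        post = vbem_fit(obs, HHMMSpec(2, 2), max_iter=60, n_restarts=2, seed=12)
        trace = np.array(post.elbo_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_emission_confidence_ellipse_coverage(self):
        # The 85% posterior-predictive ellipse of each joint state should
        # cover about 85% of the frames decoded into that state.
        gt = well_separated_hhmm(2, 2, separation=6.0, seed=13)
        obs, _, _ = simulate_hhmm(gt, 6000, seed=14)
        post = vbem_fit(obs, HHMMSpec(2, 2), max_iter=100, n_restarts=3, seed=15)
        sp, _ = e_step(
            (obs.as_matrix() - post.standardize_mean[0]) / post.standardize_sd[0],
            post,
        )
        seq = map_states(sp)
        joint = (seq.hl - 1) * 2 + (seq.ll - 1)
        x = (obs.as_matrix() - post.standardize_mean[0]) / post.standardize_sd[0]
        means, covs = post.expected_means(), post.expected_covs()
        cutoff = chi2.ppf(0.85, df=2)
        for s in range(4):
            mask = joint == s
            if mask.sum() < 200:
                continue
            diff = x[mask] - means[s]
            maha = np.einsum(
                "ti,ij,tj->t", diff, np.linalg.inv(covs[s]), diff
            )
            frac = np.mean(maha <= cutoff)
            assert abs(frac - 0.85) < 0.06


class TestMapStates:
    def make_sp(self, hl_marginal):
        hl_marginal = np.asarray(hl_marginal, dtype=float)
        t, n_hl = hl_marginal.shape
        gamma = np.repeat(hl_marginal[:, :, None] / 2.0, 2, axis=2)
        return StatePosterior(
            gamma=gamma, hl_marginal=hl_marginal, log_evidence_contrib=0.0
        )

    def test_one_hot_gives_full_confidence(self):
        seq = map_states(self.make_sp([[0.0, 1.0]]))
        assert seq.hl[0] == 2
        assert seq.confidence[0] == pytest.approx(1.0)

    def test_uniform_ten_state_confidence(self):
        seq = map_states(self.make_sp([np.full(10, 0.1)]))
        assert seq.confidence[0] == pytest.approx(0.1)

    def test_confidence_threshold_boundary(self):
        from flywalk.state_analysis import filter_and_despike

        seq = map_states(self.make_sp([[0.86, 0.14]] * 3 + [[0.84, 0.16]] * 3))
        out = filter_and_despike(seq)
        np.testing.assert_array_equal(out.hl, [1, 1, 1, 0, 0, 0])


class TestSerialization:
    def test_round_trip(self, tmp_path):
        spec = HHMMSpec(n_hl=2, n_ll=3)
        post = random_posterior(spec, seed=16)
        post.elbo_trace = [-10.0, -5.0]
        path = tmp_path / "model.npz"
        save_posterior(post, path)
        back = load_posterior(path)
        assert back.spec == spec
        np.testing.assert_allclose(back.q_A, post.q_A)
        np.testing.assert_allclose(back.m, post.m)
        assert back.elbo_trace == [-10.0, -5.0]
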