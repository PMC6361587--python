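"""Trajectory loading, smoothing, observable decomposition and clipping."""

import numpy as np
import pytest
from scipy.stats import norm

from flywalk.preprocessing import (
    DataQualityError,
    ObservableSeries,
    SmoothingConfig,
    TrajectoryFormatError,
    TrajectoryRecord,
    clip_outliers,
    compute_observables,
    load_trajectory,
    smooth_trajectory,
    speed_curvature,
    write_trajectory,
)


def make_record(x, y, **kwargs):
    x = np.asarray(x, dtype=float)
    return TrajectoryRecord(
        fly_id="test", t=np.arange(x.size), x=x, y=np.asarray(y, float),
        **kwargs,
    )


def record_from_displacements(disps):
    """Trajectory whose successive displacements are the given vectors."""
    pos = np.vstack([[0.0, 0.0], np.cumsum(disps, axis=0)])
    return make_record(pos[:, 0], pos[:, 1])


class TestLoad:
    def test_boundary_maps_to_unit_radius(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("frame,x,y\n0,3.2,0\n1,1.6,0\n2,0,0\n")
        rec = load_trajectory(p)
        assert rec.x[0] == pytest.approx(1.0)
        assert rec.x[1] == pytest.approx(0.5)

    def test_duplicate_frame_is_format_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("frame,x,y\n0,0,0\n0,1,1\n2,0,0\n")
        with pytest.raises(TrajectoryFormatError):
            load_trajectory(p)

    def test_missing_frames_over_threshold(self, tmp_path):
        rows = ["frame,x,y"] + [f"{i},0,0" for i in range(0, 300, 3)]
        p = tmp_path / "t.csv"
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(DataQualityError):
            load_trajectory(p)

    def test_write_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        n = 10_800
        angles = np.cumsum(rng.standard_normal(n) * 0.1)
        r = 0.5 + 0.4 * np.sin(np.linspace(0, 20, n))
        rec = make_record(r * np.cos(angles), r * np.sin(angles))
        p = tmp_path / "rt.csv"
        write_trajectory(rec, p)
        back = load_trajectory(p, fly_id="test")
        np.testing.assert_allclose(back.x, rec.x, atol=1e-12)
        np.testing.assert_allclose(back.y, rec.y, atol=1e-12)
        np.testing.assert_array_equal(back.t, rec.t)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        rec = make_record(np.full(100, 0.3), np.full(100, -0.2))
        sm = smooth_trajectory(rec)
        np.testing.assert_allclose(sm.x, rec.x, atol=1e-9)
        np.testing.assert_allclose(sm.y, rec.y, atol=1e-9)

    def test_linear_track_preserved(self):
        t = np.linspace(0, 1, 200)
        rec = make_record(0.8 * t - 0.4, -0.5 * t + 0.2)
        sm = smooth_trajectory(rec)
        np.testing.assert_allclose(sm.x, rec.x, atol=1e-6)
        np.testing.assert_allclose(sm.y, rec.y, atol=1e-6)

    def test_noise_is_reduced(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 4 * np.pi, 600)
        clean_x = 0.5 * np.cos(t)
        clean_y = 0.5 * np.sin(t)
        noisy = make_record(
            clean_x + 0.01 * rng.standard_normal(t.size),
            clean_y + 0.01 * rng.standard_normal(t.size),
        )
        sm = smooth_trajectory(noisy)
        rmse_in = np.sqrt(np.mean((noisy.x - clean_x) ** 2 + (noisy.y - clean_y) ** 2))
        rmse_out = np.sqrt(np.mean((sm.x - clean_x) ** 2 + (sm.y - clean_y) ** 2))
        assert rmse_out < rmse_in

    def test_short_track_rejected(self):
        rec = make_record(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            smooth_trajectory(rec, SmoothingConfig())


class TestObservables:
    @pytest.mark.parametrize(
        "d1,d2,v_par,v_perp",
        [
            ((0, 1), (0, 1), 1.0, 0.0),  # straight ahead
            ((0, 1), (-1, 0), 0.0, -1.0),  # left/CCW turn -> negative v_perp
            ((0, 2), (1, 0), 0.0, 1.0),  # right turn -> positive v_perp
        ],
    )
    def test_displacement_decomposition(self, d1, d2, v_par, v_perp):
        rec = record_from_displacements([d1, d2])
        obs = compute_observables(rec)
        assert obs.v_par[0] == pytest.approx(v_par, abs=1e-12)
        assert obs.v_perp[0] == pytest.approx(v_perp, abs=1e-12)

    def test_length_is_trajectory_minus_two(self):
        rec = make_record(np.linspace(0, 0.5, 57), np.zeros(57))
        assert len(compute_observables(rec)) == 55

    def test_speed_identity_preclipping(self):
        rng = np.random.default_rng(11)
        rec = record_from_displacements(rng.standard_normal((80, 2)) * 0.01)
        obs = compute_observables(rec)
        obs = speed_curvature(obs, rec)
        step = np.hypot(np.diff(rec.x), np.diff(rec.y))[1:]
        np.testing.assert_allclose(
            obs.speed, np.hypot(obs.v_par, obs.v_perp), rtol=1e-12
        )
        np.testing.assert_allclose(obs.speed, step, rtol=1e-10)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        disps = rng.standard_normal((60, 2)) * 0.01
        theta = 1.234
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        a = compute_observables(record_from_displacements(disps))
        b = compute_observables(record_from_displacements(disps @ rot.T))
        np.testing.assert_allclose(a.v_par, b.v_par, atol=1e-12)
        np.testing.assert_allclose(a.v_perp, b.v_perp, atol=1e-12)

    def test_mirror_negates_v_perp_and_curvature(self):
        rng = np.random.default_rng(6)
        disps = rng.standard_normal((60, 2)) * 0.01
        mirrored = disps * np.array([-1.0, 1.0])
        rec_a = record_from_displacements(disps)
        rec_b = record_from_displacements(mirrored)
        a = speed_curvature(compute_observables(rec_a), rec_a)
        b = speed_curvature(compute_observables(rec_b), rec_b)
        np.testing.assert_allclose(a.v_par, b.v_par, atol=1e-12)
        np.testing.assert_allclose(a.v_perp, -b.v_perp, atol=1e-12)
        np.testing.assert_allclose(a.curvature, -b.curvature, atol=1e-9)

    def test_stationary_frames_use_last_heading(self):
        # Move +y, stop for two frames, then move +x: the turn is judged
        # against the remembered +y heading (a right turn).
        rec = make_record([0, 0, 0, 0, 0.01], [0, 0.01, 0.01, 0.01, 0.01])
        obs = compute_observables(rec)
        assert obs.v_par[-1] == pytest.approx(0.0, abs=1e-12)
        assert obs.v_perp[-1] == pytest.approx(0.01, abs=1e-12)


class TestClipOutliers:
    def test_no_outliers_is_identity(self):
        rng = np.random.default_rng(0)
        obs = ObservableSeries(
            v_par=rng.uniform(-1, 1, 500), v_perp=rng.uniform(-1, 1, 500)
        )
        out = clip_outliers(obs, seed=1)
        np.testing.assert_array_equal(out.v_par, obs.v_par)
        np.testing.assert_array_equal(out.v_perp, obs.v_perp)

    def test_single_outlier_replaced_others_untouched(self):
        v = np.concatenate([np.zeros(999), [100.0]])
        obs = ObservableSeries(v_par=v.copy(), v_perp=np.zeros(1000))
        out = clip_outliers(obs, seed=2)
        np.testing.assert_array_equal(out.v_par[:999], 0.0)
        assert out.v_par[999] != 100.0
        mu, sd = v.mean(), v.std()
        assert abs(out.v_par[999] - (mu + 4 * sd)) < 5.0  # near the 4-SD mark

    def test_gaussian_replacement_fraction(self):
        rng = np.random.default_rng(42)
        n = 1_000_000
        obs = ObservableSeries(
            v_par=rng.standard_normal(n), v_perp=np.zeros(n)
        )
        out = clip_outliers(obs, seed=3)
        n_replaced = int(np.sum(out.v_par != obs.v_par))
        expected = 2 * norm.cdf(-4.0) * n  # ~63 of a million
        assert abs(n_replaced - expected) < 4 * np.sqrt(expected) + 5

    def test_zero_variance_noop(self):
        obs = ObservableSeries(v_par=np.zeros(100), v_perp=np.zeros(100))
        out = clip_outliers(obs, seed=4)
        np.testing.assert_array_equal(out.v_par, 0.0)


class TestSpeedCurvature:
    def test_three_four_five(self):
        rec = record_from_displacements([(0, 1), (0, 1)])
        obs = compute_observables(rec)
        obs.v_par = np.array([3.0])
        obs.v_perp = np.array([4.0])
        obs = speed_curvature(obs, rec)
        assert obs.speed[0] == pytest.approx(5.0)

    def test_straight_motion_zero_curvature(self):
        rec = record_from_displacements([(0.01, 0.01)] * 50)
        obs = speed_curvature(compute_observables(rec), rec)
        np.testing.assert_allclose(obs.curvature, 0.0, atol=1e-10)

    def test_circle_curvature_is_inverse_radius(self):
        r = 0.37
        theta = np.linspace(0, 2 * np.pi, 2000)
        rec = make_record(r * np.cos(theta), r * np.sin(theta))
        obs = speed_curvature(compute_observables(rec), rec)
        assert np.median(np.abs(obs.curvature)) == pytest.approx(1 / r, rel=1e-3)
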