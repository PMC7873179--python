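"""Midline geometry, diameter measurement, residual map and rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import colomap as cm
from colomap.motility_map import MidlineSamples

from conftest import make_config, make_corridor


class TestResampleMidline:
    def test_straight_segment_counts_and_normals(self):
        curve = cm.MidlineCurve(points_mm=[(0.0, 0.0), (100.0, 0.0)])
        s = cm.resample_midline(curve, 10.0)
        assert s.positions_mm.size == 11
        np.testing.assert_allclose(s.normals, [[0.0, 1.0]] * 11)
        np.testing.assert_allclose(s.tangents, [[1.0, 0.0]] * 11)

    def test_quarter_circle_normals_are_radial(self):
        # control points on the circle, uniformly in angle; sampling lands on
        # them, so centred differences give the exact tangent direction
        r, n_ctrl = 100.0, 1001
        theta = np.linspace(0.0, np.pi / 2, n_ctrl)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        curve = cm.MidlineCurve(points_mm=pts)
        ds = curve.total_length_mm / 100.0
        s = cm.resample_midline(curve, ds)
        radial = s.points_mm / np.linalg.norm(s.points_mm, axis=1, keepdims=True)
        # normal is radial up to sign; interior samples use centred
        # differences (exact on a circle), endpoints one-sided chords
        dots = np.abs(np.einsum("ij,ij->i", s.normals, radial))
        np.testing.assert_allclose(dots[1:-1], 1.0, atol=1e-6)
        np.testing.assert_allclose(dots[[0, -1]], 1.0, atol=1e-4)

    def test_chord_length_conserves_arc_length(self):
        theta = np.linspace(0.0, np.pi / 2, 2001)
        pts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta)])
        curve = cm.MidlineCurve(points_mm=pts)
        s = cm.resample_midline(curve, curve.total_length_mm / 80.0)
        chords = np.linalg.norm(np.diff(s.points_mm, axis=0), axis=1).sum()
        assert abs(chords - curve.total_length_mm) / curve.total_length_mm < 0.005

    def test_degenerate_curves_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            cm.MidlineCurve(points_mm=[(0.0, 0.0), (0.0, 0.0)])
        curve = cm.MidlineCurve(points_mm=[(0.0, 0.0), (1.0, 0.0)])
        with pytest.raises(ValueError, match="exceeds"):
            cm.resample_midline(curve, 10.0)
        with pytest.raises(ValueError):
            cm.resample_midline(curve, 0.0)


class TestMeasureDiameters:
    def test_constant_tube_measures_true_width(self):
        cfg = make_config(duration_s=5.0)
        truth = cm.simulate_diameter_field(cfg)
        frames = cm.render_frames(truth, cfg)
        curve = cm.MidlineCurve(points_mm=cfg.midline_points_mm)
        d = cm.measure_diameters(frames, curve, make_corridor(cfg), spacing_mm=2.0)
        assert d.valid.all()
        np.testing.assert_allclose(
            d.diameters_mm, cfg.baseline_diameter_mm, atol=cfg.pixel_spacing_mm
        )

    def test_phantom_rmse_within_one_pixel(self, single_wave_config, single_wave_truth,
                                           single_wave_diameters):
        d = single_wave_diameters
        idx = np.searchsorted(single_wave_truth.positions_mm, d.positions_mm)
        true = single_wave_truth.diameter_field_mm[idx, :]
        err = (d.diameters_mm - true)[d.valid]
        rmse = np.sqrt(np.mean(err**2))
        assert rmse <= single_wave_config.pixel_spacing_mm
        assert d.valid.mean() > 0.95

    def test_breathing_and_noise_stay_within_one_pixel(self, noisy_breathing_config):
        cfg = noisy_breathing_config
        truth = cm.simulate_diameter_field(cfg)
        frames = cm.render_frames(truth, cfg)
        curve = cm.MidlineCurve(points_mm=cfg.midline_points_mm)
        # corridor margin (10 mm) exceeds the breathing amplitude (3 mm)
        d = cm.measure_diameters(frames, curve, make_corridor(cfg), spacing_mm=2.0)
        idx = np.searchsorted(truth.positions_mm, d.positions_mm)
        err = (d.diameters_mm - truth.diameter_field_mm[idx, :])[d.valid]
        assert np.sqrt(np.mean(err**2)) <= cfg.pixel_spacing_mm

    def test_ray_exiting_fov_masks_cell(self):
        cfg = make_config(duration_s=3.0)
        truth = cm.simulate_diameter_field(cfg)
        frames = cm.render_frames(truth, cfg)
        # midline drawn past the proximal image edge: rays there leave the FOV
        curve = cm.MidlineCurve(points_mm=[(-60.0, 60.0), (425.0, 60.0)])
        d = cm.measure_diameters(frames, curve, make_corridor(cfg), spacing_mm=2.0)
        assert not d.valid[:20].any()  # samples off-image are masked
        assert d.valid[60:].all()  # interior unaffected
        assert np.isnan(d.diameters_mm[~d.valid]).all()  # masked, never zero


class TestActivityMap:
    def test_constant_series_gives_zero_activity(self):
        d = cm.DiameterProfileSeries(
            diameters_mm=np.full((4, 10), 20.0), valid=np.ones((4, 10), bool),
            positions_mm=np.arange(4) * 2.0, times_s=np.arange(10.0))
        act = cm.frame_to_frame_activity(d)
        np.testing.assert_array_equal(act.delta_mm, 0.0)
        assert act.delta_mm.shape == (4, 9)

    def test_sinusoid_matches_analytic_first_difference(self):
        t = np.arange(50.0)
        series = 20.0 + np.sin(0.3 * t)
        d = cm.DiameterProfileSeries(
            diameters_mm=np.tile(series, (3, 1)), valid=np.ones((3, 50), bool),
            positions_mm=np.arange(3) * 2.0, times_s=t)
        act = cm.frame_to_frame_activity(d)
        np.testing.assert_allclose(act.delta_mm, np.tile(np.diff(series), (3, 1)), atol=1e-12)

    def test_invalid_cells_propagate(self):
        valid = np.ones((2, 5), bool)
        valid[0, 2] = False
        d = cm.DiameterProfileSeries(
            diameters_mm=np.full((2, 5), 20.0), valid=valid,
            positions_mm=np.arange(2.0), times_s=np.arange(5.0))
        act = cm.frame_to_frame_activity(d)
        assert not act.valid[0, 1] and not act.valid[0, 2]
        assert act.valid[1].all()

    def test_single_frame_rejected(self):
        d = cm.DiameterProfileSeries(
            diameters_mm=np.full((2, 1), 20.0), valid=np.ones((2, 1), bool),
            positions_mm=np.arange(2.0), times_s=np.array([0.0]))
        with pytest.raises(ValueError, match="2 frames"):
            cm.frame_to_frame_activity(d)


def _explicit_ols_residuals(t, y):
    """Independent normal-equation solve used as the oracle."""
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


class TestResidualMap:
    def test_exactly_linear_series_has_zero_residuals(self):
        t = np.arange(20.0)
        d = cm.DiameterProfileSeries(
            diameters_mm=np.outer(np.ones(3), 15.0 + 0.05 * t),
            valid=np.ones((3, 20), bool), positions_mm=np.arange(3.0), times_s=t)
        r = cm.residual_map(d)
        np.testing.assert_allclose(r.residuals_mm, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_constant_and_time(self, single_wave_rmap):
        r = np.where(single_wave_rmap.valid, single_wave_rmap.residuals_mm, 0.0)
        t = single_wave_rmap.times_s
        sums = np.abs(r.sum(axis=1))
        t_sums = np.abs((r * t).sum(axis=1))
        fitted = single_wave_rmap.valid.any(axis=1)
        assert np.all(sums[fitted] < 1e-9 * 20.0)
        assert np.all(t_sums[fitted] < 1e-6 * 20.0 * t.max())

    def test_pulse_residuals_match_explicit_normal_equations(self):
        t = np.arange(100.0)
        pulse = np.where((t >= 40) & (t < 50), -5.0, 0.0)
        y = 18.0 + 0.01 * t + pulse
        d = cm.DiameterProfileSeries(
            diameters_mm=y[None, :], valid=np.ones((1, 100), bool),
            positions_mm=np.array([0.0]), times_s=t)
        r = cm.residual_map(d)
        expected = _explicit_ols_residuals(t, y)
        np.testing.assert_allclose(r.residuals_mm[0], expected, rtol=0, atol=1e-9)

    def test_masked_cells_excluded_from_fit(self):
        t = np.arange(30.0)
        y = 20.0 + 0.1 * t
        y_corrupt = y.copy()
        y_corrupt[5] = 500.0
        valid = np.ones((1, 30), bool)
        valid[0, 5] = False
        d = cm.DiameterProfileSeries(diameters_mm=y_corrupt[None, :], valid=valid,
                                     positions_mm=np.array([0.0]), times_s=t)
        r = cm.residual_map(d)
        np.testing.assert_allclose(r.residuals_mm[0, valid[0]], 0.0, atol=1e-9)
        assert not r.valid[0, 5]

    def test_positions_with_too_few_valid_frames_masked(self):
        valid = np.zeros((2, 10), bool)
        valid[0] = True
        valid[1, :2] = True  # only 2 valid frames: below the minimum of 3
        d = cm.DiameterProfileSeries(diameters_mm=np.full((2, 10), 20.0), valid=valid,
                                     positions_mm=np.arange(2.0), times_s=np.arange(10.0))
        r = cm.residual_map(d)
        assert r.valid[0].all()
        assert not r.valid[1].any()
        assert np.isnan(r.intercepts_mm[1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=5, max_size=40))
    def test_residual_mean_is_zero_for_arbitrary_series(self, values):
        y = 20.0 + np.asarray(values)
        t = np.arange(y.size, dtype=float)
        d = cm.DiameterProfileSeries(diameters_mm=y[None, :],
                                     valid=np.ones((1, y.size), bool),
                                     positions_mm=np.array([0.0]), times_s=t)
        r = cm.residual_map(d)
        assert abs(np.nansum(r.residuals_mm)) < 1e-9 * 20.0


class TestRenderAndRidge:
    def test_zero_map_renders_uniform_blue(self, tmp_path):
        rmap = cm.ResidualMap(
            residuals_mm=np.zeros((10, 20)), valid=np.ones((10, 20), bool),
            positions_mm=np.arange(10) * 2.0, times_s=np.arange(20.0),
            intercepts_mm=np.full(10, 20.0), slopes_mm_per_s=np.zeros(10))
        out = tmp_path / "zero.png"
        cm.render_motility_plot(rmap, out)
        from PIL import Image

        img = np.asarray(Image.open(out).convert("RGB"))
        # interior of the heatmap: a single colour (the near-zero blue)
        centre = img[img.shape[0] // 2 - 5 : img.shape[0] // 2 + 5,
                     img.shape[1] // 3 : img.shape[1] // 2]
        assert np.unique(centre.reshape(-1, 3), axis=0).shape[0] == 1
        b = centre[0, 0]
        assert b[2] > b[0] and b[2] > b[1]  # blue dominates

    def test_rendering_is_deterministic(self, tmp_path, single_wave_rmap):
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        cm.render_motility_plot(single_wave_rmap, p1)
        cm.render_motility_plot(single_wave_rmap, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_ridge_slope_recovers_simulated_velocity(self, single_wave_rmap):
        v = cm.estimate_ridge_velocity(single_wave_rmap, t_start_s=55.0, t_end_s=110.0)
        assert v == pytest.approx(10.0, rel=0.10)

    def test_ridge_velocity_requires_a_band(self):
        rmap = cm.ResidualMap(
            residuals_mm=np.zeros((5, 10)), valid=np.ones((5, 10), bool),
            positions_mm=np.arange(5.0), times_s=np.arange(10.0),
            intercepts_mm=np.zeros(5), slopes_mm_per_s=np.zeros(5))
        with pytest.raises(ValueError):
            cm.estimate_ridge_velocity(rmap)
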