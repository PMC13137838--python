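import numpy as np
import pytest

import junctiondyn as jd
from junctiondyn.core import borders_from_labels
from junctiondyn.synthetic import SyntheticError, render_junction_image


class TestMonolayerSpec:
    def test_degenerate_tessellation_rejected(self):
        with pytest.raises(SyntheticError, match="degenerate"):
            jd.generate_monolayer(jd.SyntheticMonolayerSpec(n_cells=1))

    def test_infeasible_density_rejected(self):
        with pytest.raises(SyntheticError, match="density infeasible"):
            jd.generate_monolayer(
                jd.SyntheticMonolayerSpec(field_size_px=(32, 32), n_cells=500)
            )

    def test_density_consistency_enforced(self):
        spec = jd.SyntheticMonolayerSpec(density_cells_per_cm2=1e3)  # ~0.2 cells
        with pytest.raises(SyntheticError, match="density"):
            spec.validate()

    def test_from_density_matches_field(self):
        spec = jd.SyntheticMonolayerSpec.from_density(9e4)
        assert abs(spec.n_cells - 9e4 * spec.field_area_cm2) <= 1
        assert spec.density == pytest.approx(9e4, rel=0.1)


class TestGenerateMonolayer:
    def test_deterministic_for_fixed_seed(self):
        spec = jd.SyntheticMonolayerSpec(
            seed=1, poisson_gain=2.0, gaussian_read_sigma=2.0
        )
        a, gta = jd.generate_monolayer(spec)
        b, gtb = jd.generate_monolayer(spec)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(gta.label_stack, gtb.label_stack)

    def test_ground_truth_construction(self, monolayer_seed1):
        spec, series, gt = monolayer_seed1
        labels = gt.label_stack[0]
        assert sorted(np.unique(labels)) == list(range(1, spec.n_cells + 1))
        # border pixels are exactly the inter-label boundary of the labels
        assert np.array_equal(gt.border_stack[0], borders_from_labels(labels))
        # every border pixel touches >= 2 labels (8-neighbourhood) or the edge
        h, w = labels.shape
        ys, xs = np.nonzero(gt.border_stack[0])
        for y, x in zip(ys, xs):
            if y in (0, h - 1) or x in (0, w - 1):
                continue
            neigh = set(labels[y - 1: y + 2, x - 1: x + 2].ravel()) - {0}
            assert len(neigh) >= 2

    def test_aligned_elongated_cells_show_high_coherency(self):
        spec = jd.SyntheticMonolayerSpec(
            seed=2, mean_aspect_ratio=3.0,
            orientation_concentration=50.0, orientation_mean_deg=0.0,
        )
        series, _ = jd.generate_monolayer(spec)
        a = jd.apparent_coherency(series.frame())
        assert a.coherency > 0.5
        assert abs(a.dominant_direction_deg - 0.0) <= 5.0

    def test_isotropic_tessellation_has_low_coherency(self):
        spec = jd.SyntheticMonolayerSpec(
            seed=2, mean_aspect_ratio=1.0, orientation_concentration=0.0
        )
        series, _ = jd.generate_monolayer(spec)
        assert jd.apparent_coherency(series.frame()).coherency < 0.15


def test_band_rendering_integrates_to_gaussian_area():
    """Per unit border length the noise-free band integrates to
    amplitude * sigma * sqrt(2 pi) (within discretisation)."""
    border = np.zeros((64, 64), bool)
    border[31, :] = True
    amp, sigma = 50.0, 2.0
    img = render_junction_image(border, amp, sigma, background=3.0)
    per_length = (img - 3.0).sum() / 64.0
    assert per_length == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.02)


class TestTimelapse:
    def test_static_program_keeps_borders_fixed(self):
        spec = jd.SyntheticMonolayerSpec(seed=1)
        series, gt = jd.generate_timelapse(
            spec, jd.MotionProgram(kind="static"), 5, 1.0
        )
        assert np.all(gt.per_frame_border_displacement_um == 0)
        # noise off: frames bit-identical
        assert np.array_equal(series.frame(0), series.frame(4))
        assert np.array_equal(gt.label_stack[0], gt.label_stack[4])

    def test_rigid_translation_truth(self):
        spec = jd.SyntheticMonolayerSpec(seed=1)
        prog = jd.MotionProgram(kind="rigid_translation", speed_um_per_min=0.5)
        _, gt = jd.generate_timelapse(spec, prog, 5, frame_interval_min=1.0)
        assert np.allclose(gt.per_frame_border_displacement_um[1:], 0.5)

    def test_intermediate_state_reduction_ratio(self):
        spec = jd.SyntheticMonolayerSpec(seed=3)
        prog = jd.MotionProgram(
            kind="intermediate_state", jitter_amplitude_um=1.0,
            intermediate_onset_frame=10, intermediate_release_frame=20,
            intermediate_reduction_fraction=0.20,
        )
        _, gt = jd.generate_timelapse(spec, prog, 30, 1.0)
        d = gt.per_frame_border_displacement_um
        inside = d[10:21].mean()
        outside = np.r_[d[1:10], d[21:]].mean()
        assert inside / outside == pytest.approx(0.80, abs=0.02)

    def test_invalid_calibration_rejected(self):
        spec = jd.SyntheticMonolayerSpec(seed=1)
        with pytest.raises(SyntheticError, match="invalid calibration"):
            jd.generate_timelapse(spec, jd.MotionProgram(), 5, 0.0)
        with pytest.raises(SyntheticError, match="insufficient frames"):
            jd.generate_timelapse(spec, jd.MotionProgram(), 2, 1.0)

    def test_cell_identity_preserved_across_frames(self):
        spec = jd.SyntheticMonolayerSpec(seed=2)
        prog = jd.MotionProgram(kind="border_jitter", jitter_amplitude_um=0.5)
        _, gt = jd.generate_timelapse(spec, prog, 5, 1.0)
        tracks = gt.track_table
        assert set(tracks.groupby("track_id").size()) == {5}


class TestRecoilCurve:
    def test_noiseless_curve_matches_model_exactly(self):
        rs = jd.RecoilSpec(D_um=2.0, tau_s=15.0, dt_s=0.2, duration_s=60.0)
        m = jd.generate_recoil_curve(rs)
        assert m.L_um[0] == 0.0
        expected = 2.0 * (1.0 - np.exp(-m.t_s / 15.0))
        assert np.allclose(m.L_um, expected, atol=0, rtol=0)
        i15 = int(np.argmin(np.abs(m.t_s - 15.0)))
        assert m.L_um[i15] == pytest.approx(2 * (1 - np.exp(-1)), abs=1e-12)

    def test_noise_residuals_are_centred(self):
        rs = jd.RecoilSpec(D_um=2.0, tau_s=15.0, noise_sigma_um=0.1, seed=7)
        m = jd.generate_recoil_curve(rs)
        resid = m.L_um - 2.0 * (1.0 - np.exp(-m.t_s / 15.0))
        assert abs(resid.mean()) <= 3 * 0.1 / np.sqrt(len(resid))

    def test_too_short_duration_rejected(self):
        with pytest.raises(SyntheticError, match="too few samples"):
            jd.generate_recoil_curve(jd.RecoilSpec(dt_s=1.0, duration_s=2.0))


class TestOrientedTexture:
    def test_pure_grating_is_coherent(self):
        tex = jd.generate_oriented_texture(30.0, 1.0, (128, 128), seed=1)
        a = jd.apparent_coherency(tex.frame())
        assert a.coherency >= 0.95
        assert abs(a.dominant_direction_deg - 30.0) <= 1.0

    def test_isotropic_noise_is_incoherent(self):
        tex = jd.generate_oriented_texture(0.0, 0.0, (256, 256), seed=1)
        assert jd.apparent_coherency(tex.frame()).coherency < 0.1

    def test_zero_amplitude_gives_constant_image(self):
        tex = jd.generate_oriented_texture(0.0, 1.0, (64, 64), seed=1, amplitude=0.0)
        a = jd.apparent_coherency(tex.frame())
        assert a.coherency == 0.0
        assert np.isnan(a.dominant_direction_deg)

    def test_too_small_field_rejected(self):
        with pytest.raises(SyntheticError):
            jd.generate_oriented_texture(0.0, 1.0, (16, 16), seed=1)


class TestTERSeries:
    def test_flat_preset_normalises_to_one(self):
        ter = jd.generate_ter_series(900.0, "flat", 50, seed=0)
        assert np.allclose(ter.normalized, 1.0)

    def test_shear_rise_plateaus_at_thirty_percent(self):
        ter = jd.generate_ter_series(900.0, "shear_rise", 150, seed=0)
        assert np.max(ter.normalized) == pytest.approx(1.30, abs=0.01)

    def test_transient_dip_minimum_position(self):
        ter = jd.generate_ter_series(900.0, "transient_dip", 150, seed=0,
                                     dip_index=40)
        assert int(np.argmin(ter.normalized)) == 40

    def test_invalid_baseline_rejected(self):
        with pytest.raises(SyntheticError, match="invalid baseline"):
            jd.generate_ter_series(0.0, "flat", 10, seed=0)
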