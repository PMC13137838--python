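import itertools

import numpy as np
import pandas as pd
import pytest

import junctiondyn as jd
from junctiondyn.dynamics import (
    DynamicsError,
    _skeleton_points,
    border_displacement,
    detect_reduced_window,
    displacement_timeseries,
    migration_metrics,
    migration_table,
    normalize_ter,
    skeleton_distance,
)
from junctiondyn.segmentation import SegmentationResult


def horizontal_border_seg(row, size=64):
    lab = np.ones((size, size), int)
    lab[row:, :] = 2
    return SegmentationResult.from_labels(lab)


class TestBorderDisplacement:
    def test_identical_frames_have_zero_rate(self, seg_from_truth):
        e = border_displacement(
            seg_from_truth, seg_from_truth, seg_from_truth, dt_min=1.0
        )
        assert e["rate_um_per_min"] == 0.0

    def test_rigid_translation_rate_is_exact(self):
        segs = [horizontal_border_seg(r) for r in (28, 30, 32)]
        e = border_displacement(*segs, dt_min=1.0, pixel_size_um=0.5)
        # delta = 2 px/frame -> rate = delta * pixel_size / dt
        assert e["rate_um_per_min"] == pytest.approx(2 * 0.5 / 1.0, abs=1e-12)
        e = border_displacement(*segs, dt_min=1.0, pixel_size_um=0.5,
                                aggregation="mean")
        assert e["rate_um_per_min"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_exhaustive_pairwise_oracle(self, seg_from_truth):
        a = _skeleton_points(seg_from_truth)[:400]
        b = a + np.array([0.0, 1.0]) + np.sin(a[:, 0] / 7.0)[:, None]
        fast = skeleton_distance(a, b)
        dists = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
        brute = (dists.min(axis=1).mean() + dists.min(axis=0).mean()) / 2
        assert fast == pytest.approx(brute, abs=1e-9)

    def test_distance_is_symmetric(self, seg_from_truth):
        rng = np.random.default_rng(0)
        a = _skeleton_points(seg_from_truth)
        b = a[rng.random(len(a)) < 0.6] + rng.normal(0, 2, size=(1, 2))
        assert skeleton_distance(a, b) == skeleton_distance(b, a)
        assert skeleton_distance(a, b, "hausdorff") == skeleton_distance(
            b, a, "hausdorff"
        )

    def test_empty_skeleton_rejected(self):
        with pytest.raises(DynamicsError, match="no borders"):
            skeleton_distance(np.zeros((0, 2)), np.ones((3, 2)))


class TestDisplacementTimeseries:
    def test_static_timelapse_is_flat_with_no_window(self):
        spec = jd.SyntheticMonolayerSpec(seed=1)
        _, gt = jd.generate_timelapse(spec, jd.MotionProgram(kind="static"), 5, 1.0)
        segs = [SegmentationResult.from_labels(l) for l in gt.label_stack]
        bds = displacement_timeseries(segs, 1.0, spec.pixel_size_um)
        rates = bds.displacement_rate_um_per_min
        assert np.isnan(rates[0]) and np.isnan(rates[-1])
        assert np.all(rates[1:-1] == 0.0)
        assert bds.reduced_window is None

    def test_time_reversal_reverses_the_series(self):
        spec = jd.SyntheticMonolayerSpec(seed=2)
        prog = jd.MotionProgram(kind="border_jitter", jitter_amplitude_um=0.8)
        _, gt = jd.generate_timelapse(spec, prog, 8, 1.0)
        segs = [SegmentationResult.from_labels(l) for l in gt.label_stack]
        fwd = displacement_timeseries(segs, 1.0, spec.pixel_size_um)
        rev = displacement_timeseries(segs[::-1], 1.0, spec.pixel_size_um)
        np.testing.assert_allclose(
            fwd.displacement_rate_um_per_min[1:-1],
            rev.displacement_rate_um_per_min[1:-1][::-1],
        )

    def test_pixel_size_scales_outputs_linearly(self):
        segs = [horizontal_border_seg(r) for r in (28, 30, 32, 34, 36)]
        a = displacement_timeseries(segs, 1.0, pixel_size_um=1.0)
        b = displacement_timeseries(segs, 1.0, pixel_size_um=3.0)
        np.testing.assert_allclose(
            3.0 * a.displacement_rate_um_per_min[1:-1],
            b.displacement_rate_um_per_min[1:-1],
        )

    def test_intermediate_window_detection(self):
        spec = jd.SyntheticMonolayerSpec(field_size_px=(384, 384), n_cells=45,
                                         seed=1)
        prog = jd.MotionProgram(
            kind="intermediate_state", jitter_amplitude_um=1.0,
            intermediate_onset_frame=10, intermediate_release_frame=20,
        )
        _, gt = jd.generate_timelapse(spec, prog, 30, 1.0)
        segs = [SegmentationResult.from_labels(l) for l in gt.label_stack]
        bds = displacement_timeseries(segs, 1.0, spec.pixel_size_um)
        assert bds.reduced_window is not None
        a, b = bds.reduced_window
        detected = set(range(a, b + 1))
        programmed = set(range(10, 21))
        jac = len(detected & programmed) / len(detected | programmed)
        assert jac >= 0.8

    def test_too_few_frames_rejected(self, seg_from_truth):
        with pytest.raises(DynamicsError, match="insufficient frames"):
            displacement_timeseries([seg_from_truth] * 2, 1.0)


def test_detector_ignores_uniform_series():
    rates = np.r_[np.nan, np.full(20, 1.0), np.nan]
    window, baseline = detect_reduced_window(rates)
    assert window is None
    assert baseline == 1.0


class TestMigrationMetrics:
    def test_three_four_five_step(self):
        m = migration_metrics(np.array([[0, 0], [3, 4]]), dt_min=1.0)
        assert m.accumulated_distance_um == 5.0
        assert m.euclidean_distance_um == 5.0
        assert m.velocity_um_per_min == 5.0

    def test_closed_square_loop(self):
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], float)
        m = migration_metrics(square, dt_min=1.0)
        assert m.accumulated_distance_um == 40.0
        assert m.euclidean_distance_um == 0.0

    def test_random_walk_accumulated_distance_is_exact(self):
        rng = np.random.default_rng(11)
        ang = rng.uniform(0, 2 * np.pi, 100)
        steps = np.column_stack([np.cos(ang), np.sin(ang)])
        pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        m = migration_metrics(pos, dt_min=0.5)
        assert m.accumulated_distance_um == pytest.approx(100.0, abs=1e-9)
        assert m.euclidean_distance_um == pytest.approx(
            np.linalg.norm(steps.sum(axis=0)), abs=1e-9
        )

    def test_accumulated_bounds_euclidean_on_enumerated_paths(self):
        # all 3-step paths over a small step alphabet
        alphabet = [(1, 0), (0, 1), (-1, 0), (2, 0)]
        for steps in itertools.product(alphabet, repeat=3):
            pos = np.vstack([[0, 0], np.cumsum(np.array(steps, float), axis=0)])
            m = migration_metrics(pos, dt_min=1.0)
            assert m.accumulated_distance_um >= m.euclidean_distance_um - 1e-12
            collinear = all(s in ((1, 0), (2, 0)) for s in steps)
            if collinear:
                assert m.accumulated_distance_um == pytest.approx(
                    m.euclidean_distance_um
                )

    def test_degenerate_track_rejected(self):
        with pytest.raises(DynamicsError, match="degenerate track"):
            migration_metrics(np.array([[1.0, 2.0]]), dt_min=1.0)

    def test_migration_table_roundtrip(self):
        df = pd.DataFrame({
            "track_id": [1, 1, 2, 2],
            "frame": [0, 1, 0, 1],
            "x_um": [0.0, 3.0, 0.0, 0.0],
            "y_um": [0.0, 4.0, 0.0, 1.0],
        })
        out = migration_table(df, dt_min=2.0).set_index("track_id")
        assert out.loc[1, "accumulated_distance_um"] == 5.0
        assert out.loc[1, "velocity_um_per_min"] == 2.5
        assert out.loc[2, "euclidean_distance_um"] == 1.0


class TestTER:
    def test_constant_series_normalises_to_one(self):
        ter = normalize_ter(np.arange(5.0), np.full(5, 700.0))
        assert np.allclose(ter.normalized, 1.0)
        assert ter.normalized[ter.t0_index] == 1.0

    def test_relative_profile_preserved(self):
        ter = normalize_ter(np.arange(3.0), 600.0 * np.array([1.0, 0.8, 1.3]))
        np.testing.assert_allclose(ter.normalized, [1.0, 0.8, 1.3])
        assert ter.min_normalized == 0.8
        assert ter.time_of_min_s == 1.0

    def test_shear_rise_preset_peak(self):
        ter = jd.generate_ter_series(500.0, "shear_rise", 120, seed=3)
        assert np.max(ter.normalized) == pytest.approx(1.30, abs=0.01)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DynamicsError, match="invalid baseline"):
            normalize_ter(np.arange(3.0), np.array([0.0, 1.0, 2.0]))
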