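"""Contour propagation, strain, strain rate and peak extraction."""

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

import rvatlas.strain as st
import rvatlas.synthetic as syn
from rvatlas.contours import ContourSequence, resample_closed


def circle(radius, n=96, center=(0.0, 0.0)):
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def masks_from_polygons(polys, shape=(80, 80), pixel_mm=1.0):
    """Rasterize closed mm-space polygons into per-frame boolean masks."""
    xs = (np.arange(shape[0]) + 0.5) * pixel_mm
    ys = (np.arange(shape[1]) + 0.5) * pixel_mm
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), -1).reshape(-1, 2)
    return np.stack([MplPath(p).contains_points(grid).reshape(shape) for p in polys])


class TestPropagate:
    def test_whole_voxel_translation_gives_zero_strain(self):
        base = circle(15.0, center=(30, 30))
        shifts = [(0, 0), (3, 0), (0, -4), (2, 2)]
        masks = masks_from_polygons([base + s for s in shifts])
        initial = base + 0.0
        seq = st.propagate_contour(initial, masks, frame_interval_s=0.04)
        res = st.compute_strain(seq, n_segments=6)
        assert np.allclose(res.segment_strain_pct, 0.0, atol=0.5)

    def test_scaled_contour_gives_similarity_strain(self):
        # pure contour scaling (no rasterization): circumferential strain -10%
        base = circle(20.0)
        seq = ContourSequence(points=np.stack([base, base * 0.9]),
                              frame_interval_s=0.04, level="mid")
        res = st.compute_strain(seq, n_segments=6)
        assert np.allclose(res.segment_strain_pct[:, 1], -10.0, atol=1e-9)

    def test_tracked_perimeter_matches_analytic(self, template):
        mesh = syn.deform_shape(template, syn.ShapeParams(dilation_scale=1.1))
        motion = syn.MotionParams(n_frames=12)
        contours, truth = syn.generate_cine(mesh, motion)
        ref = contours[("mid", "endo")]
        masks = masks_from_polygons(
            [p - p.min(axis=0) + 5.0 for p in ref.points],
            shape=(70, 70), pixel_mm=0.8)
        initial = ref.points[0] - ref.points[0].min(axis=0) + 5.0
        seq = st.propagate_contour(initial, masks, motion.rr_interval_s / 12,
                                   pixel_mm=0.8)
        per_tracked = seq.arc_lengths()
        per_true = ref.arc_lengths()
        assert np.allclose(per_tracked / per_tracked[0],
                           per_true / per_true[0], rtol=0.01)

    def test_empty_frame_rejected_with_frame_number(self):
        masks = masks_from_polygons([circle(15, center=(30, 30))] * 2)
        masks = np.concatenate([masks, np.zeros_like(masks[:1])])
        with pytest.raises(ValueError, match="frame 2"):
            st.propagate_contour(circle(15, center=(30, 30)), masks, 0.04)


class TestLevelSelection:
    def test_nine_slices_select_quartiles(self):
        assert st.select_sax_levels(9) == {"basal": 2, "mid": 4, "apical": 6}

    def test_three_slices_forced(self):
        assert st.select_sax_levels(3) == {"basal": 0, "mid": 1, "apical": 2}

    def test_fractions_within_one_slice_of_quartiles(self):
        for n in range(3, 15):
            sel = st.select_sax_levels(n)
            for name, frac in (("basal", 0.25), ("mid", 0.5), ("apical", 0.75)):
                assert abs(sel[name] / (n - 1) - frac) <= 1.0 / (n - 1) + 1e-9

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            st.select_sax_levels(2)


class TestStrain:
    def test_lagrangian_definition(self):
        # one segment shrinking from 100 to 85 mm -> -15%
        base = np.column_stack([np.linspace(0, 100, 51), np.zeros(51)])
        seq = ContourSequence(points=np.stack([base, base * 0.85]),
                              frame_interval_s=0.05, level="4ch")
        res = st.compute_strain(seq, n_segments=2)
        assert np.allclose(res.segment_strain_pct[:, 1], -15.0)

    def test_global_is_mean_of_segments(self):
        rng = np.random.default_rng(1)
        pts = np.stack([circle(20), circle(20) * rng.uniform(0.8, 1.0)])
        seq = ContourSequence(points=pts, frame_interval_s=0.05, level="basal")
        res = st.compute_strain(seq, n_segments=6)
        assert np.array_equal(res.global_strain_pct,
                              res.segment_strain_pct.mean(axis=0))

    def test_thickness_based_radial_strain(self):
        endo = np.stack([circle(20.0), circle(20.0)])
        epi = np.stack([circle(25.0), circle(27.0)])  # wall 5 -> 7 mm
        res = st.compute_strain(
            ContourSequence(points=endo, frame_interval_s=0.05, level="mid"),
            n_segments=4,
            epi_seq=ContourSequence(points=epi, frame_interval_s=0.05,
                                    level="mid", surface="epi"),
            direction="radial")
        assert res.radial_method == "thickness"
        assert np.allclose(res.segment_strain_pct[:, 1], 40.0)

    def test_centroid_radial_strain_positive_for_inward_motion(self):
        pts = np.stack([circle(20.0), circle(17.0)])
        res = st.compute_strain(
            ContourSequence(points=pts, frame_interval_s=0.05, level="mid"),
            n_segments=4, direction="radial")
        assert res.radial_method == "centroid"
        assert np.allclose(res.segment_strain_pct[:, 1], 15.0)

    def test_rigid_per_frame_transform_invariance(self):
        rng = np.random.default_rng(3)
        base = circle(20.0)
        frames, moved = [base], [base]
        for t in range(1, 5):
            scaled = base * (1 - 0.03 * t)
            frames.append(scaled)
            ang = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            moved.append(scaled @ R.T + rng.uniform(-5, 5, 2))
        a = st.compute_strain(ContourSequence(points=np.stack(frames),
                                              frame_interval_s=0.04, level="mid"), 6)
        b = st.compute_strain(ContourSequence(points=np.stack(moved),
                                              frame_interval_s=0.04, level="mid"), 6)
        assert np.allclose(a.segment_strain_pct, b.segment_strain_pct, atol=1e-9)

    def test_too_few_segments_rejected(self):
        seq = ContourSequence(points=np.stack([circle(20)] * 2),
                              frame_interval_s=0.05, level="mid")
        with pytest.raises(ValueError):
            st.compute_strain(seq, n_segments=1)


class TestRateAndPeaks:
    def _linear_result(self, peak=-15.0, t_end=0.3, n=61):
        times = np.linspace(0.0, t_end, n)
        curve = peak * times / t_end
        seg = np.tile(curve, (4, 1))
        return st.StrainResult(level="mid", direction="circumferential",
                               times_s=times, segment_strain_pct=seg,
                               global_strain_pct=curve)

    def test_linear_strain_slope(self):
        res = st.strain_rate_and_peaks(self._linear_result(), es_frame=60)
        assert res.peaks["systolic_rate_per_s"] == pytest.approx(-0.5, rel=1e-6)
        assert res.peaks["systolic_strain_pct"] == pytest.approx(-15.0)

    def test_sinusoidal_peak_rate_matches_analytic_derivative(self):
        times = np.linspace(0.0, 0.3, 301)
        curve = -15.0 * np.sin(np.pi * times / 0.3)
        res = st.StrainResult(level="mid", direction="circumferential",
                              times_s=times, segment_strain_pct=curve[None, :],
                              global_strain_pct=curve)
        res = st.strain_rate_and_peaks(res, es_frame=300)
        assert res.peaks["systolic_rate_per_s"] == pytest.approx(
            -0.15 * np.pi / 0.3, rel=0.05)

    def test_constant_strain_has_zero_rates(self):
        times = np.linspace(0, 0.4, 11)
        seg = np.full((3, 11), -5.0)
        seg[:, 0] = -5.0
        res = st.StrainResult(level="mid", direction="circumferential",
                              times_s=times, segment_strain_pct=seg,
                              global_strain_pct=seg.mean(axis=0))
        res = st.strain_rate_and_peaks(res, es_frame=5)
        assert np.allclose(res.global_rate_per_s, 0.0)
        assert res.peaks["systolic_rate_per_s"] == 0.0

    def test_time_reversal_negates_rates(self):
        rng = np.random.default_rng(0)
        curve = np.cumsum(rng.normal(0, 1, 20))
        times = np.arange(20) * 0.04
        fwd = st.StrainResult(level="mid", direction="circumferential",
                              times_s=times, segment_strain_pct=curve[None, :],
                              global_strain_pct=curve)
        rev = st.StrainResult(level="mid", direction="circumferential",
                              times_s=times, segment_strain_pct=curve[None, ::-1],
                              global_strain_pct=curve[::-1])
        st.strain_rate_and_peaks(fwd, es_frame=10)
        st.strain_rate_and_peaks(rev, es_frame=10)
        assert np.allclose(fwd.global_rate_per_s, -rev.global_rate_per_s[::-1])

    def test_too_few_frames_rejected(self):
        res = self._linear_result(n=2)
        with pytest.raises(ValueError):
            st.strain_rate_and_peaks(res, es_frame=1)


class TestRecovery:
    @pytest.mark.parametrize("peak", [-0.05, -0.15, -0.25])
    def test_prescribed_circumferential_peak_recovered(self, template, peak):
        mesh = syn.deform_shape(template, syn.ShapeParams())
        motion = syn.MotionParams(peak_circ_strain=peak)
        contours, truth = syn.generate_cine(mesh, motion)
        results = st.analyze_cine(contours, es_frame=truth.es_frame)
        circ_mid = next(r for r in results
                        if r.level == "mid" and r.direction == "circumferential")
        assert circ_mid.peaks["systolic_strain_pct"] == pytest.approx(
            100 * peak, abs=1.0)

    def test_strain_rate_peak_recovered_within_5pct(self, template):
        mesh = syn.deform_shape(template, syn.ShapeParams())
        motion = syn.MotionParams(n_frames=40)
        contours, truth = syn.generate_cine(mesh, motion)
        results = st.analyze_cine(contours, es_frame=truth.es_frame)
        circ_mid = next(r for r in results
                        if r.level == "mid" and r.direction == "circumferential")
        # oracle: finite difference of the analytic strain curve itself
        analytic = truth.strain_pct[("circumferential", "mid")] / 100.0
        dt = truth.times_s[1] - truth.times_s[0]
        oracle = np.gradient(analytic, dt)[: truth.es_frame + 1]
        peak_oracle = oracle[np.abs(oracle).argmax()]
        assert circ_mid.peaks["systolic_rate_per_s"] == pytest.approx(
            peak_oracle, rel=0.05)
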