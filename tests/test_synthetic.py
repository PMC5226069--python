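"""Generator contracts: template, deformation, rasterization, cine, cohort."""

import numpy as np
import pytest

import rvatlas.synthetic as syn
from rvatlas.geometry import geometric_indices
from rvatlas.mesh import SHAPE_VECTOR_LEN

from conftest import ring_sphere


class TestTemplate:
    def test_shape_vector_has_3456_entries(self, template):
        assert template.shape_vector().size == SHAPE_VECTOR_LEN == 3456

    def test_deterministic(self, template):
        again = syn.generate_template()
        assert np.array_equal(template.endo, again.endo)
        assert np.array_equal(template.epi, again.epi)

    def test_endo_strictly_inside_epi(self, template):
        assert template.wall_thickness().min() > 0
        # endo cavity fully contained: every endo vertex closer to axis than epi
        assert (np.linalg.norm(template.endo[:, :2], axis=1)
                <= np.linalg.norm(template.epi[:, :2], axis=1) + 1e-9).all()

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            syn.generate_template(n_rings=10, n_circ=10)


class TestDeform:
    def test_identity_params_leave_template_unchanged(self, template):
        out = syn.deform_shape(template, syn.ShapeParams(), seed=0)
        assert np.allclose(out.shape_vector(), template.shape_vector())

    @pytest.mark.parametrize("s", [0.8, 1.25])
    def test_dilation_scales_cavity_volume_cubically(self, template, s):
        out = syn.deform_shape(template, syn.ShapeParams(dilation_scale=s))
        assert np.isclose(out.cavity_volume_ml(),
                          template.cavity_volume_ml() * s**3, rtol=1e-9)

    def test_sphericity_sweep_monotone_in_length_diameter_ratio(self, template):
        ratios = []
        for f in (0.7, 0.9, 1.1, 1.3):
            m = syn.deform_shape(template, syn.ShapeParams(sphericity_factor=f))
            ratios.append(geometric_indices(m)["sphericity_ratio"])
        assert np.all(np.diff(ratios) > 0)

    def test_deterministic_noise(self, template):
        p = syn.ShapeParams(noise_sd_mm=0.5)
        a = syn.deform_shape(template, p, seed=42)
        b = syn.deform_shape(template, p, seed=42)
        assert np.array_equal(a.endo, b.endo)

    def test_intersecting_surfaces_rejected(self, template):
        with pytest.raises(ValueError, match="intersection"):
            syn.deform_shape(template, syn.ShapeParams(wall_thickness_mm=0.01))


class TestRasterize:
    def test_sphere_volume_within_2pct(self):
        R = 20.0
        stack = syn.rasterize_segmentation(ring_sphere(R), voxel_mm=1.0,
                                           slice_thickness_mm=1.0)
        vol = stack.label_volume_ml("rv_cavity")
        assert vol == pytest.approx(4 / 3 * np.pi * R**3 / 1000.0, rel=0.02)

    def test_landmark_single_component_on_base_slice(self, template):
        stack = syn.rasterize_segmentation(template, voxel_mm=1.5,
                                           slice_thickness_mm=5.0)
        lm = stack.mask("lv_landmark")
        assert set(np.argwhere(lm)[:, 2]) == {0}
        from skimage import measure
        assert measure.label(lm[:, :, 0]).max() == 1

    def test_no_empty_trailing_slices(self, template):
        stack = syn.rasterize_segmentation(template, voxel_mm=1.5,
                                           slice_thickness_mm=5.0)
        assert (stack.data[:, :, -1] > 0).any()

    def test_excessive_slice_thickness_rejected(self, template):
        with pytest.raises(ValueError, match="thickness"):
            syn.rasterize_segmentation(template, voxel_mm=1.5,
                                       slice_thickness_mm=500.0)


@pytest.fixture(scope="module")
def cine(template):
    mesh = syn.deform_shape(template, syn.ShapeParams(dilation_scale=1.1))
    return syn.generate_cine(mesh, syn.MotionParams())


class TestCine:

    def test_frame0_strains_are_zero(self, cine):
        _, truth = cine
        for curve in truth.strain_pct.values():
            assert curve[0] == 0.0

    def test_incompressible_wall_volume_conserved(self, cine):
        _, truth = cine
        dev = np.abs(truth.wall_volume_ml / truth.wall_volume_ml[0] - 1.0)
        assert dev.max() < 0.01

    def test_ef_matches_volume_curve_formula(self, cine):
        _, truth = cine
        ef = (truth.edv_ml - truth.esv_ml) / truth.edv_ml * 100.0
        assert truth.ef_pct == pytest.approx(ef, abs=1e-12)
        assert truth.edv_ml == pytest.approx(truth.volume_ml.max())
        assert truth.esv_ml == pytest.approx(truth.volume_ml.min())

    def test_strain_truth_self_consistent_with_contours(self, cine):
        contours, truth = cine
        for lv in ("basal", "mid", "apical"):
            per = contours[(lv, "endo")].arc_lengths()
            lagrangian = 100.0 * (per / per[0] - 1.0)
            assert np.allclose(truth.strain_pct[("circumferential", lv)],
                               lagrangian, atol=1e-6)
        la = contours[("4ch", "endo")].arc_lengths()
        assert np.allclose(truth.strain_pct[("longitudinal", "4ch")],
                           100.0 * (la / la[0] - 1.0), atol=1e-6)

    def test_prescribed_peaks_reached(self, template):
        motion = syn.MotionParams(peak_circ_strain=-0.2, peak_long_strain=-0.1)
        _, truth = syn.generate_cine(template, motion)
        assert truth.strain_pct[("circumferential", "mid")].min() == pytest.approx(-20.0, abs=1e-6)
        assert truth.strain_pct[("longitudinal", "4ch")].min() == pytest.approx(-10.0, abs=1e-3)

    def test_invalid_motion_rejected(self, template):
        with pytest.raises(ValueError):
            syn.generate_cine(template, syn.MotionParams(peak_circ_strain=0.2))
        with pytest.raises(ValueError):
            syn.generate_cine(template, syn.MotionParams(n_frames=5))


class TestCohort:
    def test_paper_sized_config_yields_93_rows(self):
        table = syn.cohort_table(syn.sample_cohort(syn.default_cohort_config(seed=0)))
        assert len(table) == 93
        counts = table.groupby(["group", "stage"]).size()
        assert counts[("MBT", "I")] == 30 and counts[("RVPA", "I")] == 20
        assert counts[("MBT", "II")] == 29 and counts[("RVPA", "II")] == 14

    def test_fixed_seed_reproduces_identical_tables(self):
        t1 = syn.cohort_table(syn.sample_cohort(syn.default_cohort_config(seed=5)))
        t2 = syn.cohort_table(syn.sample_cohort(syn.default_cohort_config(seed=5)))
        assert t1.equals(t2)

    def test_subject_streams_stable_under_arm_resizing(self):
        cfg_small = syn.two_group_config(n_per_arm=5, seed=9)
        cfg_big = syn.two_group_config(n_per_arm=8, seed=9)
        small = syn.sample_cohort(cfg_small)
        big = syn.sample_cohort(cfg_big)
        by_id = {s.subject_id: s for s in big}
        for s in small:
            assert by_id[s.subject_id].shape_params == s.shape_params

    def test_too_small_arm_rejected(self):
        cfg = syn.two_group_config(n_per_arm=1)
        with pytest.raises(ValueError, match="n >= 2"):
            syn.sample_cohort(cfg)

    def test_null_effect_sizes_give_calibrated_comparisons(self):
        from rvatlas.experiments import null_shape_param_pvalues
        p = null_shape_param_pvalues(n_replicates=100, n_per_arm=15, seed=21)
        assert (p > 0.05).mean() >= 0.90

    def test_cohort_directory_layout(self, tmp_path):
        cfg = syn.two_group_config(n_per_arm=2, seed=1)
        table, records = syn.generate_cohort(cfg, out_dir=tmp_path, voxel_mm=2.5,
                                             slice_thickness_mm=6.0)
        assert (tmp_path / "cohort.csv").exists()
        sdir = tmp_path / table["subject_id"].iloc[0]
        assert (sdir / "seg.nii.gz").exists()
        assert (sdir / "truth.json").exists()
        assert (sdir / "contours_mid_endo.json").exists()
        assert (sdir / "contours_4ch_endo.json").exists()

    def test_volume_truth_matches_mesh_integration(self, template):
        spec = syn.sample_cohort(syn.two_group_config(n_per_arm=2, seed=3))[0]
        mesh, _, truth = syn.build_subject(spec, template)
        assert truth.edv_ml == pytest.approx(mesh.cavity_volume_ml(), rel=0.005)
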