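"""PCA atlas construction, projection/reconstruction and mode comparison."""

import numpy as np
import pytest

import rvatlas.atlas as at
import rvatlas.synthetic as syn
from rvatlas.experiments import cohort_shape_vectors


@pytest.fixture(scope="module")
def cohort_vectors(template):
    cfg = syn.two_group_config(n_per_arm=12, dilation_d=1.0, seed=3)
    return cohort_shape_vectors(cfg, template)


class TestBuild:
    def test_identical_shapes_have_zero_eigenvalues(self, template):
        X = np.tile(template.shape_vector(), (5, 1))
        a = at.build_atlas(X, k=3)
        assert np.allclose(a.eigenvalues_all, 0.0)
        assert np.allclose(a.mean, template.shape_vector())

    def test_two_distinct_shapes_are_rank_one(self, template):
        v1 = template.shape_vector()
        v2 = v1 * 1.1
        with pytest.warns(UserWarning, match="rank"):
            a = at.build_atlas(np.stack([v1, v2, v1, v2]), k=5)
        assert (a.eigenvalues_all > 1e-8 * a.eigenvalues_all[0]).sum() == 1
        assert at.explained_variance(a, 1) == pytest.approx(1.0)

    def test_eigenvalues_match_bruteforce_covariance_eigensolve(self, cohort_vectors):
        X, _, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1][:10]
        assert np.allclose(a.eigenvalues, eig, rtol=1e-6, atol=1e-9 * eig[0])

    def test_orthonormal_centred_and_sorted(self, cohort_vectors):
        X, _, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        a.validate()  # orthonormality, ordering, centred scores

    def test_too_few_subjects_rejected(self, template):
        with pytest.raises(ValueError, match="at least 3"):
            at.build_atlas(np.tile(template.shape_vector(), (2, 1)))


class TestExplainedVariance:
    def test_full_rank_captures_everything(self, cohort_vectors):
        X, _, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        assert at.explained_variance(a, a.eigenvalues_all.size) == pytest.approx(1.0)

    def test_monotone_in_k(self, cohort_vectors):
        X, _, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        fracs = [at.explained_variance(a, k) for k in range(1, 11)]
        assert np.all(np.diff(fracs) >= 0)

    def test_matches_oracle_eigenvalue_ratio(self, cohort_vectors):
        X, _, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0, None)
        assert at.explained_variance(a, 10) == pytest.approx(
            eig[:10].sum() / eig.sum(), abs=1e-9)

    def test_out_of_range_rejected(self, cohort_vectors):
        X, _, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        with pytest.raises(ValueError):
            at.explained_variance(a, 0)


class TestProjectReconstruct:
    def test_mean_projects_to_zero(self, cohort_vectors):
        a = at.build_atlas(cohort_vectors[0], k=10)
        assert np.allclose(at.project_shape(a, a.mean), 0.0, atol=1e-8)

    def test_single_mode_displacement_recovers_score(self, cohort_vectors):
        a = at.build_atlas(cohort_vectors[0], k=10)
        lam = a.eigenvalues[0]
        shape = a.mean + 2 * np.sqrt(lam) * a.modes[:, 0]
        scores = at.project_shape(a, shape)
        assert scores[0] == pytest.approx(2 * np.sqrt(lam))
        assert np.allclose(scores[1:], 0.0, atol=1e-8)

    def test_training_scores_reproduced(self, cohort_vectors):
        X, _, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        for i in (0, 5, 17):
            assert np.allclose(at.project_shape(a, X[i]), a.scores[i], atol=1e-8)

    def test_plus_three_sd_roundtrip(self, cohort_vectors):
        a = at.build_atlas(cohort_vectors[0], k=10)
        shape = at.reconstruct_shape(a, mode=2, k_sd=3.0)
        scores = at.project_shape(a, shape)
        assert scores[2] == pytest.approx(3.0 * np.sqrt(a.eigenvalues[2]))

    def test_full_rank_reconstruction_is_lossless(self, cohort_vectors):
        X, _, _ = cohort_vectors
        k = min(X.shape[0] - 1, X.shape[1])
        a = at.build_atlas(X, k=k)
        rec = at.reconstruct_shape(a, scores=a.scores[3])
        assert np.allclose(rec, X[3], atol=1e-7)

    def test_reconstruction_error_monotone_in_k(self, cohort_vectors):
        X, _, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        errs = []
        for k in range(1, 11):
            rec = a.mean + a.modes[:, :k] @ a.scores[7, :k]
            errs.append(np.linalg.norm(rec - X[7]))
        assert all(b <= a_ + 1e-9 for a_, b in zip(errs, errs[1:]))

    def test_extrapolation_warning(self, cohort_vectors):
        a = at.build_atlas(cohort_vectors[0], k=10)
        with pytest.warns(UserWarning, match="extrapolates"):
            at.reconstruct_shape(a, mode=0, k_sd=6.0)

    def test_length_mismatch_rejected(self, cohort_vectors):
        a = at.build_atlas(cohort_vectors[0], k=10)
        with pytest.raises(ValueError, match="length"):
            at.project_shape(a, np.zeros(100))


class TestCompareModes:
    def test_two_group_f_equals_squared_t(self, cohort_vectors):
        from scipy import stats as sps
        X, labels, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        cmp = at.compare_modes(a.scores, labels)
        for j in range(10):
            t = sps.ttest_ind(a.scores[labels == "A", j],
                              a.scores[labels == "B", j], equal_var=True)
            assert cmp["F"].iloc[j] == pytest.approx(t.statistic**2, rel=1e-9)
            assert cmp["p"].iloc[j] == pytest.approx(t.pvalue, rel=1e-9)

    def test_bonferroni_adjustment_and_flags(self, cohort_vectors):
        X, labels, _ = cohort_vectors
        a = at.build_atlas(X, k=10)
        cmp = at.compare_modes(a.scores, labels, alpha=0.05)
        assert np.allclose(cmp["p_bonferroni"], np.minimum(1.0, cmp["p"] * 10))
        assert (cmp["significant"] == (cmp["p_bonferroni"] < 0.05)).all()

    def test_zero_variance_group_uses_permutation_fallback(self):
        scores = np.array([[1.0], [1.0], [1.0], [2.0], [3.0], [2.5]])
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        cmp = at.compare_modes(scores, labels, seed=5)
        assert 0.0 < cmp["p"].iloc[0] <= 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            at.compare_modes(np.zeros((4, 2)), ["A"] * 4)


def test_injected_dilation_recovered_as_single_mode(template):
    from rvatlas.experiments import mode_recovery_replicates
    df = mode_recovery_replicates(n_per_arm=40, dilation_d=1.2,
                                  n_replicates=10, seed=77)
    assert df["recovered"].mean() >= 0.8


def test_atlas_eigenvalues_insensitive_to_subject_pose(template):
    """Rigid pose differences are removed upstream, not absorbed by PCA."""
    import rvatlas.personalize as per
    from scipy.spatial.transform import Rotation

    cfg = syn.two_group_config(n_per_arm=2, dilation_d=0.8, seed=13)
    subs = syn.sample_cohort(cfg, template)
    rng = np.random.default_rng(4)
    vecs_plain, vecs_posed = [], []
    for s in subs:
        mesh = syn.deform_shape(template, s.shape_params, seed=s.seed)
        Rz = Rotation.from_euler("z", rng.uniform(-45, 45), degrees=True).as_matrix()
        shift = np.array([*rng.uniform(-8, 8, 2), 0.0])
        for out, m in ((vecs_plain, mesh), (vecs_posed, mesh.transformed(Rz, shift))):
            stack = syn.rasterize_segmentation(m, voxel_mm=1.5, slice_thickness_mm=5.0)
            out.append(per.fit_template(per.standardize_pose(stack),
                                        template).shape_vector())
    a1 = at.build_atlas(np.stack(vecs_plain), k=2)
    a2 = at.build_atlas(np.stack(vecs_posed), k=2)
    assert a2.eigenvalues[0] == pytest.approx(a1.eigenvalues[0], rel=0.05)
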