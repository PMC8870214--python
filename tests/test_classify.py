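"""Feature assembly, standardised PCA, concentration ellipses and
Mahalanobis reclassification."""

import numpy as np
import pytest
from scipy import stats

from hairyscore.classify import (
    assemble_features,
    concentration_ellipse,
    fit_pca,
    flag_gray_zone,
    reclassify,
)
from hairyscore.markers import CHCL, VHCL_SDRPL


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    return rng.normal(size=(6, 4)) @ np.diag([3.0, 1.0, 0.5, 0.2])


class TestAssembleFeatures:
    def test_markers13_shape(self, fixture_cohort, fixture_profiles):
        patients, samples, _ = fixture_cohort
        X = assemble_features(patients, samples, fixture_profiles, "markers13")
        assert X.values.shape == (82, 28)
        assert X.feature_names[-2:] == [
            "abnormal_pct_of_sample", "abnormal_pct_of_lymphocytes"
        ]

    def test_markers4_geno_names(self, fixture_cohort, fixture_profiles):
        patients, samples, _ = fixture_cohort
        X = assemble_features(patients, samples, fixture_profiles, "markers4_geno")
        assert len(X.feature_names) == 12
        assert X.feature_names[-3:] == ["BRAF_V600E", "MAP2K1", "KLF2"]
        assert set(np.unique(X.values[:, -3:])) <= {0.0, 1.0}

    def test_blood_variant_adds_counts_ratio_and_cd26(
        self, fixture_cohort, fixture_profiles
    ):
        patients, samples, _ = fixture_cohort
        X = assemble_features(
            patients, samples, fixture_profiles, "markers4_geno_blood"
        )
        assert X.values.shape == (82, 20)
        for name in ("ALC", "Hb", "cd4_cd8_ratio", "CD26_pct", "CD26_mfi"):
            assert name in X.feature_names

    def test_missing_values_mean_imputed_with_mask(
        self, fixture_cohort, fixture_profiles
    ):
        # several fixture cHCL samples lack CD123 in their panel
        patients, samples, _ = fixture_cohort
        X = assemble_features(patients, samples, fixture_profiles, "markers13")
        j = X.feature_names.index("CD123_mfi")
        assert X.missing_mask[:, j].sum() == 6
        observed = X.values[~X.missing_mask[:, j], j]
        imputed = X.values[X.missing_mask[:, j], j]
        assert np.allclose(imputed, observed.mean())

    def test_device_filter(self, fixture_cohort, fixture_profiles):
        patients, samples, _ = fixture_cohort
        X = assemble_features(
            patients, samples, fixture_profiles, "markers13",
            device_filter="FACSCANTO-II",
        )
        assert X.values.shape[0] == 76

    def test_unknown_variant_errors(self, fixture_cohort, fixture_profiles):
        patients, samples, _ = fixture_cohort
        with pytest.raises(ValueError):
            assemble_features(patients, samples, fixture_profiles, "markers99")


class TestFitPca:
    def test_matches_correlation_eigendecomposition(self, toy):
        """Loadings and explained variance agree with a brute-force
        eigendecomposition of the correlation matrix."""
        model = fit_pca(toy)
        Z = (toy - toy.mean(0)) / toy.std(0)
        corr = (Z.T @ Z) / len(Z)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        np.testing.assert_allclose(
            model.explained_pct, 100 * eigval / eigval.sum(), atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(model.loadings), np.abs(eigvec), atol=1e-8
        )

    def test_reconstruction(self, toy):
        model = fit_pca(toy)
        Z = (toy - model.center) / model.scale
        np.testing.assert_allclose(
            model.scores @ model.loadings.T, Z, atol=1e-8
        )

    def test_loadings_orthonormal_and_explained_sums_to_100(self, toy):
        model = fit_pca(toy)
        k = model.loadings.shape[1]
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(k), atol=1e-8
        )
        assert model.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_sign_convention(self, toy):
        model = fit_pca(toy)
        for k in range(model.loadings.shape[1]):
            j = np.argmax(np.abs(model.loadings[:, k]))
            assert model.loadings[j, k] > 0

    def test_feature_permutation_equivariance(self, toy):
        model = fit_pca(toy)
        perm = [2, 0, 3, 1]
        permuted = fit_pca(toy[:, perm])
        np.testing.assert_allclose(permuted.scores, model.scores, atol=1e-8)
        np.testing.assert_allclose(
            permuted.explained_pct, model.explained_pct, atol=1e-8
        )
        np.testing.assert_allclose(
            permuted.loadings, model.loadings[perm, :], atol=1e-8
        )

    def test_collinear_features_put_all_variance_on_pc1(self):
        x = np.linspace(0, 1, 8)
        model = fit_pca(np.column_stack([x, 2 * x]))
        assert model.explained_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_zero_variance_feature_dropped_with_warning(self, toy):
        X = np.column_stack([toy, np.full(len(toy), 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_pca(X)
        assert model.loadings.shape[0] == toy.shape[1]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((2, 4)))


class TestConcentrationEllipse:
    def test_boundary_radius_is_chi2_quantile(self):
        rng = np.random.default_rng(0)
        e = concentration_ellipse(rng.normal(size=(500, 2)), "g")
        assert e.radius_sq == pytest.approx(stats.chi2.ppf(0.90, 2))
        assert e.radius_sq == pytest.approx(4.60517, abs=1e-4)

    def test_monte_carlo_coverage(self):
        """Points simulated from the fitted Gaussian fall inside the 90%
        ellipse at the nominal rate (+-1% at n=1e4)."""
        rng = np.random.default_rng(3)
        pts = rng.multivariate_normal([1, -2], [[2.0, 0.7], [0.7, 1.0]], 2000)
        e = concentration_ellipse(pts, "g")
        sim = rng.multivariate_normal(e.center, e.covariance, 10_000)
        inside = e.contains(sim).mean()
        assert abs(inside - 0.90) <= 0.01

    def test_two_samples_error(self):
        with pytest.raises(ValueError):
            concentration_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]), "g")


class TestGrayZone:
    @staticmethod
    def _two_ellipses():
        eye = np.eye(2)
        return {
            "A": concentration_ellipse(
                np.random.default_rng(0).normal([0, 0], 1, (50, 2)), "A"
            ),
            "B": concentration_ellipse(
                np.random.default_rng(1).normal([10, 0], 1, (50, 2)), "B"
            ),
        }

    def test_sample_at_own_center_not_gray(self):
        ell = self._two_ellipses()
        flags = flag_gray_zone(ell["A"].center[None, :], ["A"], ell)
        assert not flags[0]

    def test_sample_inside_other_ellipse_is_gray(self):
        ell = self._two_ellipses()
        flags = flag_gray_zone(ell["B"].center[None, :], ["A"], ell)
        assert flags[0]

    def test_sample_outside_all_ellipses_is_gray(self):
        ell = self._two_ellipses()
        flags = flag_gray_zone(np.array([[100.0, 100.0]]), ["A"], ell)
        assert flags[0]


class TestReclassify:
    @staticmethod
    def _symmetric_scores():
        rng = np.random.default_rng(5)
        a = rng.normal([-4, 0], 1, (30, 2))
        b = rng.normal([4, 0], 1, (30, 2))
        scores = np.vstack([a, b])
        labels = [CHCL] * 30 + [VHCL_SDRPL] * 30
        ids = [f"s{i}" for i in range(60)]
        return scores, ids, labels

    def test_sample_at_reference_centroid(self):
        scores, ids, labels = self._symmetric_scores()
        centroid = scores[:30].mean(0)
        scores2 = np.vstack([scores, centroid])
        res = reclassify(scores2, ids + ["probe"], labels + ["?"])
        assert res[-1].new_label == "HCL"

    def test_equidistant_sample_is_ambiguous(self):
        rng = np.random.default_rng(7)
        jitter = rng.normal(0, 1, (30, 2))
        jitter -= jitter.mean(axis=0)  # exact mirror symmetry about 0
        a = jitter + [-4, 0]
        b = jitter + [4, 0]  # identical covariances by construction
        scores = np.vstack([a, b, [[0.0, 0.0]]])
        labels = [CHCL] * 30 + [VHCL_SDRPL] * 30 + ["?"]
        ids = [f"s{i}" for i in range(61)]
        res = reclassify(scores, ids, labels)
        assert res[-1].new_label == "ambiguous"

    def test_small_reference_group_errors(self):
        scores = np.zeros((4, 2))
        with pytest.raises(ValueError):
            reclassify(scores, list("abcd"), [CHCL, CHCL, CHCL, VHCL_SDRPL])

    def test_fixture_upn_v18_analog_reclassified_as_hcl(
        self, fixture_cohort, fixture_profiles
    ):
        """The NOS patient with a cHCL-like marker/genotype profile lands
        in the HCL group despite its HCL-like label."""
        patients, samples, _ = fixture_cohort
        X = assemble_features(patients, samples, fixture_profiles, "markers4_geno")
        model = fit_pca(X)
        group_of = {p.patient_id: p.group for p in patients}
        sid2pid = {s.sample_id: s.patient_id for s in samples}
        labels = [group_of[sid2pid[sid]] for sid in X.sample_ids]
        res = reclassify(model.scores, X.sample_ids, labels)
        v18 = next(r for r in res if r.sample_id == "S-NOS-002")
        assert v18.new_label == "HCL"
        # and every cHCL sample stays in the HCL group
        for r in res:
            if r.original_group == CHCL:
                assert r.new_label == "HCL"
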