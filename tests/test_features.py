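"""PCA diagnostics and the nine plasticity features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastphen.features import (
    FEATURE_NAMES,
    N_SCREEN_TESTS,
    compute_features,
    cos2_by_protein,
    feature_table,
    run_pca,
    screen_features,
)
from plastphen.preprocess import ExpressionMatrix
from plastphen.synthetic import PROTEINS


def matrix_from_values(values: np.ndarray) -> ExpressionMatrix:
    idx = [f"p{i}" for i in range(len(values))]
    vals = pd.DataFrame(values, columns=list(PROTEINS), index=idx)
    meta = pd.DataFrame(
        {"condition": "A", "age_wks": 5.0, "region": "C", "animal_id": "a"}, index=idx
    )
    return ExpressionMatrix(values=vals, metadata=meta)


class TestPCA:
    def test_variance_fractions_sum_to_one_and_nonincreasing(self, default_pca):
        vf = default_pca.variance_fraction
        assert vf.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(vf) <= 1e-12)

    def test_basis_orthonormal(self, default_pca):
        v = default_pca.loadings.to_numpy()
        np.testing.assert_allclose(v.T @ v, np.eye(7), atol=1e-8)

    def test_reconstruction(self, default_matrix, default_pca):
        rec = default_pca.reconstruct().to_numpy()
        x = default_matrix.values.to_numpy()
        rel = np.linalg.norm(rec - x) / np.linalg.norm(x)
        assert rel < 1e-8

    def test_variance_fractions_match_covariance_eigenvalue_oracle(self, default_matrix, default_pca):
        cov = np.cov(default_matrix.values.to_numpy(), rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            default_pca.variance_fraction, eig / eig.sum(), atol=1e-8
        )

    def test_rank_one_matrix(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=7)
        coef = rng.normal(size=20)
        x = 5.0 + np.outer(coef, direction)
        pca = run_pca(matrix_from_values(np.abs(x)))
        assert pca.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention_deterministic(self, default_matrix):
        p1 = run_pca(default_matrix)
        p2 = run_pca(default_matrix)
        pd.testing.assert_frame_equal(p1.loadings, p2.loadings)
        for dim in p1.dims:
            col = p1.loadings[dim]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match=">= 8"):
            run_pca(matrix_from_values(np.ones((5, 7)) + np.eye(5, 7)))


class TestCos2:
    def test_rows_sum_to_one(self, default_pca, default_matrix):
        c2 = cos2_by_protein(default_pca, default_matrix)
        np.testing.assert_allclose(c2.sum(axis=1).to_numpy(), 1.0, atol=1e-8)

    def test_rank_one_all_quality_on_dim1(self):
        rng = np.random.default_rng(1)
        direction = np.abs(rng.normal(size=7)) + 0.5
        coef = rng.normal(size=15)
        x = np.abs(5.0 + np.outer(coef, direction))
        m = matrix_from_values(x)
        c2 = cos2_by_protein(run_pca(m), m)
        np.testing.assert_allclose(c2["Dim1"].to_numpy(), 1.0, atol=1e-10)
        assert (c2.drop(columns="Dim1").to_numpy() < 1e-10).all()

    def test_equals_squared_pearson_oracle(self, default_pca, default_matrix):
        from scipy.stats import pearsonr

        c2 = cos2_by_protein(default_pca, default_matrix)
        for protein in ("GluA2", "GABAAa1"):
            for dim in ("Dim1", "Dim2"):
                r = pearsonr(
                    default_matrix.values[protein], default_pca.scores[dim]
                ).statistic
                assert c2.loc[protein, dim] == pytest.approx(r**2, abs=1e-8)

    def test_constant_protein_reported_missing(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1, 0.2, (12, 7))
        x[:, 6] = 1.0
        m = matrix_from_values(np.abs(x))
        c2 = cos2_by_protein(run_pca(m), m)
        assert c2.loc["Synapsin"].isna().all()


class TestComputeFeatures:
    def test_all_ones_symmetry(self):
        f = compute_features({p: 1.0 for p in PROTEINS})
        assert f["all_protein_sum"] == pytest.approx(1.0)
        assert f["glutr_sum"] == pytest.approx(1.0)
        assert f["gabar_sum"] == pytest.approx(1.0)
        for name in FEATURE_NAMES[3:]:
            assert f[name] == pytest.approx(0.0)

    def test_glun2b_glun2a_orientation(self):
        """The 2B:2A band computes (2A - 2B)/(2A + 2B): 2A-positive."""
        od = {p: 1.0 for p in PROTEINS}
        od.update(GluN2A=0.35, GluN2B=0.65)
        assert compute_features(od)["glun2b_glun2a"] == pytest.approx(-0.30)

    def test_swap_antisymmetry(self):
        od = {p: 1.0 for p in PROTEINS}
        od.update(GluN2A=0.35, GluN2B=0.65)
        swapped = dict(od, GluN2A=0.65, GluN2B=0.35)
        assert compute_features(od)["glun2b_glun2a"] == pytest.approx(
            -compute_features(swapped)["glun2b_glun2a"]
        )

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance_of_indices_and_scaling_of_sums(self, c):
        rng = np.random.default_rng(3)
        base = {p: float(v) for p, v in zip(PROTEINS, rng.uniform(0.2, 2.0, 7))}
        scaled = {p: v * c for p, v in base.items()}
        f0, f1 = compute_features(base), compute_features(scaled)
        for name in FEATURE_NAMES[3:]:
            assert f1[name] == pytest.approx(f0[name], rel=1e-9)
        for name in FEATURE_NAMES[:3]:
            assert f1[name] == pytest.approx(f0[name] * c, rel=1e-9)

    def test_indices_bounded(self, default_features):
        idx = default_features[list(FEATURE_NAMES[3:])].to_numpy()
        assert np.nanmax(np.abs(idx)) <= 1.0
        assert (default_features[list(FEATURE_NAMES[:3])].to_numpy() >= 0).all()

    def test_zero_denominator_is_missing(self):
        od = {p: 1.0 for p in PROTEINS}
        od.update(GluN2A=0.0, GluN2B=0.0)
        assert np.isnan(compute_features(od)["glun2b_glun2a"])

    def test_requires_all_proteins(self):
        with pytest.raises(ValueError, match="missing proteins"):
            compute_features({"GluA2": 1.0})


class TestScreening:
    def test_bonferroni_count(self, default_screening):
        assert N_SCREEN_TESTS == 9 * 3
        assert default_screening.alpha_adjusted == pytest.approx(0.05 / 27)

    def test_copy_of_dim1_is_retained(self, default_matrix, default_pca, default_features):
        feats = default_features.copy()
        feats["all_protein_sum"] = default_pca.scores["Dim1"]
        scr = screen_features(feats, default_pca)
        assert "all_protein_sum" in scr.retained
        assert scr.correlations.loc["all_protein_sum", "Dim1"] == pytest.approx(1.0)

    def test_pure_noise_feature_rarely_retained(self, default_pca, default_features):
        """Type-I calibration: an independent-noise feature survives the
        Bonferroni screen at no more than the nominal rate."""
        rng = np.random.default_rng(42)
        n_reps, hits = 200, 0
        for _ in range(n_reps):
            feats = default_features.copy()
            feats["ei_index"] = rng.normal(size=len(feats))
            scr = screen_features(feats, default_pca)
            hits += "ei_index" in scr.retained
        # 3 tests at alpha/27 each -> per-feature familywise rate <= 0.05/9
        nominal = 3 * 0.05 / 27
        mc_se = np.sqrt(nominal * (1 - nominal) / n_reps)
        assert hits / n_reps <= nominal + 2 * mc_se

    def test_ei_index_always_in_phenotype(self, default_pca, default_features):
        rng = np.random.default_rng(7)
        feats = default_features.copy()
        feats["ei_index"] = rng.normal(size=len(feats))  # decorrelate from dims
        scr = screen_features(feats, default_pca)
        assert "ei_index" in scr.phenotype_features

    def test_protein_sum_tracks_dim1_on_default_data(self, default_screening):
        """All proteins load positively on Dim1 in these data, so the overall
        protein sum correlates positively with it."""
        assert default_screening.correlations.loc["all_protein_sum", "Dim1"] > 0
        assert "all_protein_sum" in default_screening.retained

    def test_misaligned_rows_raise(self, default_pca, default_features):
        with pytest.raises(ValueError, match="row-aligned"):
            screen_features(default_features.iloc[:-1], default_pca)
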