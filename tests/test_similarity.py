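"""Matrix-similarity tests: vectorization round trips, Spearman against a
rank-then-Pearson oracle, Williams' test against an independent formula
evaluation and a Monte-Carlo calibration, and the PCA contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connocorr.connmat import ConnMatrix
from connocorr.similarity import (TriVector, matrix_from_upper,
                                  similarity_report, spearman_similarity,
                                  stack_and_pca, vectorize_upper,
                                  williams_permutation, williams_test)
from connocorr.synthetic import (CovSpec, make_atlas,
                                 make_network_covariance,
                                 random_factor_correlation)


def oracle_spearman(x, y):
    """Rank with a naive average-rank procedure, then Pearson."""
    def naive_rank(v):
        v = np.asarray(v, float)
        r = np.empty(v.size)
        for i, val in enumerate(v):
            less = np.sum(v < val)
            equal = np.sum(v == val)
            r[i] = less + (equal + 1) / 2.0
        return r
    rx, ry = naive_rank(x), naive_rank(y)
    return np.corrcoef(rx, ry)[0, 1]


def oracle_williams_t(r_jk, r_jh, r_kh, n):
    """Independent evaluation of the dependent-correlation t statistic."""
    det = 1 - r_jk ** 2 - r_jh ** 2 - r_kh ** 2 + 2 * r_jk * r_jh * r_kh
    rbar = (r_jk + r_jh) / 2
    num = (n - 1) * (1 + r_kh)
    den = 2 * ((n - 1) / (n - 3)) * det + rbar ** 2 * (1 - r_kh) ** 3
    return (r_jk - r_jh) * np.sqrt(num / den)


def corr_from(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"R{i + 1}" for i in range(values.shape[0])]
    return ConnMatrix(values, names)


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------

class TestVectorizeUpper:
    def test_114_roi_length(self):
        C = make_network_covariance(make_atlas(), CovSpec(0.5, 0.6, 0.05))
        assert len(vectorize_upper(C)) == 6441

    def test_two_roi_single_value(self):
        tri = vectorize_upper(np.array([[1.0, 0.37], [0.37, 1.0]]))
        assert tri.values.tolist() == [0.37]

    def test_round_trip(self, rng):
        C = random_factor_correlation(9, 3, seed=1)
        back = matrix_from_upper(vectorize_upper(C))
        np.testing.assert_allclose(back, C, atol=1e-15)

    def test_row_major_ordering(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.1
        m[0, 2] = m[2, 0] = 0.2
        m[1, 2] = m[2, 1] = 0.3
        assert vectorize_upper(m).values.tolist() == [0.1, 0.2, 0.3]

    def test_asymmetric_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_upper(m)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(n=st.integers(2, 20), seed=st.integers(0, 2 ** 16))
    def test_round_trip_property(self, n, seed):
        """vectorize -> reconstruct is the identity for any symmetric
        unit-diagonal matrix, at any size."""
        rng = np.random.default_rng(seed)
        u = np.triu(rng.uniform(-1, 1, (n, n)), 1)
        m = u + u.T + np.eye(n)
        tri = vectorize_upper(m)
        assert len(tri) == n * (n - 1) // 2
        np.testing.assert_array_equal(matrix_from_upper(tri), m)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_identity_and_antitone(self, rng):
        v = rng.standard_normal(20)
        assert spearman_similarity(v, v)[0] == pytest.approx(1.0)
        order = np.argsort(v)
        rev = np.empty_like(v)
        rev[order] = v[order][::-1]
        assert spearman_similarity(v, rev)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(10):
            x = np.round(rng.standard_normal(10), 0)   # heavy ties
            y = np.round(rng.standard_normal(10), 0)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = spearman_similarity(x, y)
            assert rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.standard_normal((2, 50))
        rho, _ = spearman_similarity(x, y)
        rho_t, _ = spearman_similarity(np.exp(3 * x) - 5, y)
        assert rho_t == pytest.approx(rho, abs=1e-12)

    def test_constant_input_fails(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_similarity(np.ones(10), np.arange(10.0))

    def test_nan_pairs_dropped(self, rng):
        x, y = rng.standard_normal((2, 30))
        x_nan = x.copy()
        x_nan[:5] = np.nan
        rho, _ = spearman_similarity(x_nan, y)
        assert rho == pytest.approx(spearman_similarity(x[5:], y[5:])[0])


# ---------------------------------------------------------------------------
# Williams' test
# ---------------------------------------------------------------------------

class TestWilliams:
    def test_equal_correlations_give_t_zero(self):
        res = williams_test(0.5, 0.5, 0.3, 100)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.df == 97

    def test_antisymmetry(self):
        a = williams_test(0.7, 0.4, 0.5, 200)
        b = williams_test(0.4, 0.7, 0.5, 200)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_matches_independent_formula_over_grid(self):
        grid = [(rjk, rjh, rkh, n)
                for rjk in (-0.3, 0.1, 0.5, 0.8)
                for rjh in (-0.2, 0.3, 0.6)
                for rkh in (0.0, 0.4, 0.7)
                for n in (10, 200, 6441)]
        for rjk, rjh, rkh, n in grid:
            det = 1 - rjk**2 - rjh**2 - rkh**2 + 2 * rjk * rjh * rkh
            if det <= 0:
                continue
            res = williams_test(rjk, rjh, rkh, n)
            assert res.t == pytest.approx(
                oracle_williams_t(rjk, rjh, rkh, n), abs=1e-10)
            assert res.p == pytest.approx(
                2 * stats.t.sf(abs(res.t), n - 3), abs=1e-12)

    def test_large_n_matrix_scale_contrast_significant(self):
        """At the matrix-comparison scale (6,441 ROI pairs), a 0.71 vs 0.64
        contrast with r_kh = 0.8 is decisively significant."""
        res = williams_test(0.71, 0.64, 0.8, 6441)
        assert res.p < 0.001
        assert res.t > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="n > 3"):
            williams_test(0.5, 0.3, 0.2, 3)
        with pytest.raises(ValueError, match=r"\|R\|"):
            williams_test(0.9, -0.9, 0.9, 100)
        with pytest.raises(ValueError, match="r_jk"):
            williams_test(1.0, 0.3, 0.2, 100)

    def test_type_i_error_calibration(self):
        """Trivariate normals with equal dependent correlations: empirical
        two-tailed rejection at alpha = .05 stays near nominal."""
        r, rkh, n, reps = 0.5, 0.4, 200, 1000
        Sigma = np.array([[1, r, r], [r, 1, rkh], [r, rkh, 1]])
        L = np.linalg.cholesky(Sigma)
        rng = np.random.default_rng(2025)
        rejections = 0
        for _ in range(reps):
            X = rng.standard_normal((n, 3)) @ L.T
            C = np.corrcoef(X, rowvar=False)
            res = williams_test(C[0, 1], C[0, 2], C[1, 2], n)
            rejections += res.p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_permutation_contrast_direction(self, rng):
        """The permutation alternative agrees in direction with the
        parametric contrast when one matrix clearly tracks the reference."""
        ref = random_factor_correlation(12, 4, seed=3)
        noise = 0.05 * np.triu(rng.standard_normal((12, 12)), 1)
        near = np.clip(ref + noise + noise.T, -0.99, 0.99)
        np.fill_diagonal(near, 1.0)
        far = random_factor_correlation(12, 4, seed=4)
        res = williams_permutation(corr_from(near), corr_from(far),
                                   corr_from(ref), n_perm=200, seed=8)
        assert res["delta_rho"] > 0
        assert res["p_perm"] < 0.05


# ---------------------------------------------------------------------------
# PCA over stacked matrices
# ---------------------------------------------------------------------------

class TestStackAndPca:
    def test_identical_matrices_rank_one(self):
        C = random_factor_correlation(8, 3, seed=6)
        rep = stack_and_pca([corr_from(C)] * 4, list("abcd"))
        assert rep.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.allclose(rep.loadings[:, 0], rep.loadings[0, 0])
        assert rep.loadings[0, 0] > 0

    def test_orthogonal_pair_splits_variance(self):
        """Two matrices whose upper triangles are constructed orthogonal
        after standardization load two equal components."""
        n = 5
        m = n * (n - 1) // 2
        v1 = np.linspace(-0.8, 0.8, m)
        # permute to make rank-orthogonality explicit by construction
        v2 = np.array([0.8, -0.8, 0.4, -0.4, 0.0, 0.0, -0.4, 0.4, -0.8, 0.8])
        z1 = (v1 - v1.mean()) / v1.std(ddof=1)
        z2 = (v2 - v2.mean()) / v2.std(ddof=1)
        assert abs(np.dot(z1, z2)) < 1e-10
        m1 = matrix_from_upper(TriVector(v1, n))
        m2 = matrix_from_upper(TriVector(v2, n))
        rep = stack_and_pca([corr_from(m1), corr_from(m2)])
        np.testing.assert_allclose(rep.explained_variance_ratio, [0.5, 0.5],
                                   atol=1e-10)

    def test_score_matrix_symmetric_round_trip(self):
        """Reshaped score matrices are symmetric and vectorize back to the
        component scores in the fixed upper-triangle ordering."""
        mats = [corr_from(random_factor_correlation(7, 3, seed=s))
                for s in range(3)]
        rep = stack_and_pca(mats)
        X = np.column_stack([
            (vectorize_upper(m).values - vectorize_upper(m).values.mean())
            / vectorize_upper(m).values.std(ddof=1) for m in mats])
        for c, S in enumerate(rep.score_matrices):
            np.testing.assert_array_equal(S, S.T)
            # project the standardized stack onto the component's loading
            np.testing.assert_allclose(vectorize_upper(S).values,
                                       X @ rep.loadings[:, c], atol=1e-8)

    def test_variance_fractions_sum_to_one_and_reconstruct(self):
        mats = [corr_from(random_factor_correlation(10, 4, seed=s))
                for s in range(5)]
        rep = stack_and_pca(mats)
        assert rep.explained_variance_ratio.sum() == pytest.approx(1.0,
                                                                   abs=1e-10)
        X = np.column_stack([
            (vectorize_upper(m).values - vectorize_upper(m).values.mean())
            / vectorize_upper(m).values.std(ddof=1) for m in mats])
        scores = np.column_stack([vectorize_upper(S).values
                                  for S in rep.score_matrices])
        np.testing.assert_allclose(scores @ rep.loadings.T, X, atol=1e-8)

    def test_constant_matrix_rejected(self):
        flat = np.full((4, 4), 0.5)
        np.fill_diagonal(flat, 1.0)
        with pytest.raises(ValueError, match="constant"):
            stack_and_pca([corr_from(flat), corr_from(np.eye(4))])


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

class TestSimilarityReport:
    def test_duplicate_matrices_all_ones(self):
        C = random_factor_correlation(6, 2, seed=9)
        rep = similarity_report({"a": corr_from(C), "b": corr_from(C)},
                                do_pca=False)
        np.testing.assert_allclose(rep.rho.to_numpy(), 1.0, atol=1e-12)

    def test_two_latent_groups_cluster_in_loadings(self):
        """Eight matrices from two latent structures: the rho matrix is
        block-structured and PC loadings separate the groups."""
        rng = np.random.default_rng(10)
        A = random_factor_correlation(12, 4, seed=11)
        B = random_factor_correlation(12, 4, seed=12)
        mats = {}
        for g, base in (("a", A), ("b", B)):
            for k in range(4):
                noise = 0.1 * np.triu(rng.standard_normal((12, 12)), 1)
                m = np.clip(base + noise + noise.T, -0.99, 0.99)
                np.fill_diagonal(m, 1.0)
                mats[f"{g}{k}"] = corr_from(m)
        rep = similarity_report(mats)
        rho = rep.rho.to_numpy()
        within = np.concatenate([rho[:4, :4][np.triu_indices(4, 1)],
                                 rho[4:, 4:][np.triu_indices(4, 1)]])
        between = rho[:4, 4:].ravel()
        assert within.min() > between.max()
        # groups separate in the (PC1, PC2) loading plane
        L = rep.pca.loadings[:, :2]
        centroid_a, centroid_b = L[:4].mean(axis=0), L[4:].mean(axis=0)
        for i in range(8):
            own = centroid_a if i < 4 else centroid_b
            other = centroid_b if i < 4 else centroid_a
            assert (np.linalg.norm(L[i] - own)
                    < np.linalg.norm(L[i] - other))

    def test_williams_contrast_wiring(self):
        rng = np.random.default_rng(13)
        ref = random_factor_correlation(10, 3, seed=14)
        noise = 0.05 * np.triu(rng.standard_normal((10, 10)), 1)
        near = np.clip(ref + noise + noise.T, -0.99, 0.99)
        np.fill_diagonal(near, 1.0)
        far = random_factor_correlation(10, 3, seed=15)
        rep = similarity_report(
            {"near": corr_from(near), "far": corr_from(far),
             "ref": corr_from(ref)},
            williams_contrasts=[("near", "far", "ref")], do_pca=False)
        w = rep.williams[0]
        assert w["direction"] == "near"
        assert w["n_pairs"] == 45
        assert w["rho_a_ref"] > w["rho_b_ref"]

    def test_removing_a_matrix_leaves_other_pairs(self):
        mats = {k: corr_from(random_factor_correlation(8, 3, seed=s))
                for k, s in (("x", 16), ("y", 17), ("z", 18))}
        full = similarity_report(mats, do_pca=False)
        partial = similarity_report({k: mats[k] for k in ("x", "y")},
                                    do_pca=False)
        assert full.rho.loc["x", "y"] == pytest.approx(
            partial.rho.loc["x", "y"], abs=1e-15)

    def test_json_serialization(self, tmp_path):
        mats = {k: corr_from(random_factor_correlation(6, 2, seed=s))
                for k, s in (("p", 19), ("q", 20))}
        rep = similarity_report(mats)
        rep.to_json(tmp_path / "rep.json")
        import json
        data = json.loads((tmp_path / "rep.json").read_text())
        assert set(data) >= {"rho", "p", "williams", "pca"}
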