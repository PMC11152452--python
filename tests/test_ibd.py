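"""Distance matrices, Weir-Cockerham F_ST, MRM and the SNP-null procedure."""

import math

import numpy as np
import pytest

from transinv.ibd import (
    DistanceMatrixRegression,
    DistanceMatrixSet,
    abs_diff_matrix,
    great_circle_km,
    single_locus_fst,
    slope_contrast,
    snp_null_test,
)


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle_km(-8.5, 147.2, -8.5, 147.2) == 0.0

    def test_antipodal(self):
        assert great_circle_km(0, 0, 0, 180) == pytest.approx(math.pi * 6371.0088, rel=1e-6)

    def test_quarter_meridian(self):
        assert great_circle_km(0, 0, 90, 0) == pytest.approx(math.pi * 6371.0088 / 2, rel=1e-6)

    def test_out_of_range_latitude(self):
        with pytest.raises(ValueError):
            great_circle_km(95, 0, 0, 0)

    def test_symmetry(self):
        a = great_circle_km(-5.2, 145.8, -9.4, 147.2)
        b = great_circle_km(-9.4, 147.2, -5.2, 145.8)
        assert a == pytest.approx(b)


def brute_weir_cockerham(counts_a, counts_b):
    """Weir & Cockerham (1984) theta-hat components written out long-hand."""
    import numpy as np

    n1, n2 = sum(counts_a), sum(counts_b)
    p1 = (counts_a[2] + counts_a[1] / 2) / n1
    p2 = (counts_b[2] + counts_b[1] / 2) / n2
    h1, h2 = counts_a[1] / n1, counts_b[1] / n2
    r = 2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


class TestSingleLocusFst:
    def test_fixed_alternative_homokaryotypes(self):
        assert single_locus_fst((10, 0, 0), (0, 0, 10)) == pytest.approx(1.0)

    def test_identical_genotype_arrays_clip_to_zero(self):
        assert single_locus_fst((5, 3, 2), (5, 3, 2)) == 0.0
        assert single_locus_fst((5, 3, 2), (5, 3, 2), clip=False) <= 0.0

    def test_toy_counts_match_longhand_weir_cockerham(self):
        for ca, cb in [((5, 5, 0), (0, 2, 8)), ((3, 4, 3), (6, 2, 2)), ((9, 1, 0), (1, 1, 8))]:
            expected = brute_weir_cockerham(ca, cb)
            assert single_locus_fst(ca, cb, clip=False) == pytest.approx(expected, rel=1e-12)
            assert single_locus_fst(ca, cb) == pytest.approx(max(expected, 0.0), rel=1e-12)

    def test_too_small_population_is_missing(self):
        assert math.isnan(single_locus_fst((1, 0, 0), (5, 5, 0)))


def _random_matrices(rng, k, names=("geo", "precip", "temp")):
    mats = {}
    for name in names:
        v = rng.random(k) * 10
        mats[name] = abs_diff_matrix(v)
    return mats


class TestMrm:
    def test_exact_linear_combination_recovered(self):
        rng = np.random.default_rng(0)
        k = 8
        preds = _random_matrices(rng, k)
        resp = 0.3 * preds["geo"] - 1.7 * preds["precip"] + 0.05 * preds["temp"] + 2.0
        np.fill_diagonal(resp, 0)
        model = DistanceMatrixRegression(resp, preds)
        res = model.fit(n_permutations=49, seed=1)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.params["geo"] == pytest.approx(0.3, abs=1e-10)
        assert res.params["precip"] == pytest.approx(-1.7, abs=1e-10)
        assert res.params["temp"] == pytest.approx(0.05, abs=1e-10)

    def test_coefficients_equal_direct_ols(self):
        rng = np.random.default_rng(1)
        k = 6
        preds = _random_matrices(rng, k)
        resp = abs_diff_matrix(rng.random(k))
        model = DistanceMatrixRegression(resp, preds)
        res = model.fit(n_permutations=9, seed=0)
        i, j = np.tril_indices(k, k=-1)
        X = np.column_stack([np.ones(len(i))] + [preds[n][i, j] for n in preds])
        beta = np.linalg.lstsq(X, resp[i, j], rcond=None)[0]
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_lmg_shares_sum_to_r_squared(self):
        rng = np.random.default_rng(2)
        preds = _random_matrices(rng, 7)
        resp = abs_diff_matrix(rng.random(7))
        res = DistanceMatrixRegression(resp, preds).fit(n_permutations=9, seed=0)
        assert res.relative_importance.sum() == pytest.approx(res.r_squared, abs=1e-10)
        assert (res.relative_importance >= -1e-12).all()

    def test_orthogonal_predictor_share_equals_marginal_r2(self):
        # orthogonal design on lower triangles: build predictors whose
        # vectorized triangles are exactly orthogonal after centering
        k = 4
        tri = np.tril_indices(k, k=-1)

        def from_tri(v):
            m = np.zeros((k, k))
            m[tri] = v
            return m + m.T

        # 6 pairs; two centered orthogonal vectors
        p1 = from_tri(np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]))
        p2 = from_tri(np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0]) * 2)
        assert np.dot(p1[tri] - p1[tri].mean(), p2[tri] - p2[tri].mean()) == 0
        resp = from_tri(0.5 * p1[tri] + 0.25 * p2[tri])
        res = DistanceMatrixRegression(resp, {"a": p1, "b": p2}).fit(9, seed=0)
        r2_a = DistanceMatrixRegression(resp, {"a": p1}).fit(9, seed=0).r_squared
        r2_b = DistanceMatrixRegression(resp, {"b": p2}).fit(9, seed=0).r_squared
        assert res.relative_importance["a"] == pytest.approx(r2_a, abs=1e-10)
        assert res.relative_importance["b"] == pytest.approx(r2_b, abs=1e-10)

    def test_rank_deficiency_names_collinear_pair(self):
        rng = np.random.default_rng(3)
        m = abs_diff_matrix(rng.random(6))
        with pytest.raises(ValueError, match="geo.*dupe|dupe.*geo"):
            DistanceMatrixRegression(abs_diff_matrix(rng.random(6)), {"geo": m, "dupe": 2 * m})

    def test_null_permutation_p_is_calibrated(self):
        """Type-I error of the permutation test ~ alpha under independence."""
        rng = np.random.default_rng(4)
        k = 7
        rejections = 0
        n_sim = 120
        for s in range(n_sim):
            preds = _random_matrices(rng, k)
            resp = abs_diff_matrix(rng.random(k))
            res = DistanceMatrixRegression(resp, preds).fit(n_permutations=99, seed=s)
            if res.perm_pvalues["geo"] <= 0.05:
                rejections += 1
        # binomial 99.7% bounds around 0.05 for n=120
        assert rejections / n_sim < 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)

    def test_matrix_set_alignment_checked(self):
        dset = DistanceMatrixSet(labels=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            dset.add("geo", np.zeros((3, 3)))


class TestSnpNull:
    def _predictors(self, rng, k=8):
        return _random_matrices(rng, k)

    def test_zero_effect_with_symmetric_null_caps_at_one(self):
        rng = np.random.default_rng(5)
        k = 8
        preds = self._predictors(rng, k)
        inv = np.full(k, 0.5)  # |delta p| = 0 -> beta = 0
        snps = rng.random((150, k)) * 0.8 + 0.1
        out = snp_null_test(inv, snps, preds, n_chromosome_tests=4)
        assert (out["p_adjusted"] == 1.0).all()

    def test_strong_cline_detected(self):
        rng = np.random.default_rng(6)
        k = 10
        precip = np.sort(rng.random(k)) * 10
        preds = {"precip": abs_diff_matrix(precip), "geo": abs_diff_matrix(rng.random(k))}
        inv = precip / 10  # frequency tracks precipitation exactly
        snps = rng.random((200, k))
        out = snp_null_test(inv, snps, preds, n_chromosome_tests=1)
        assert out.loc["precip", "p_adjusted"] <= 0.05

    def test_empty_null_rejected(self):
        rng = np.random.default_rng(7)
        preds = self._predictors(rng, 6)
        with pytest.raises(ValueError):
            snp_null_test(np.zeros(6), np.empty((0, 6)), preds)

    def test_maf_filter_applied(self):
        rng = np.random.default_rng(8)
        preds = self._predictors(rng, 6)
        snps = np.full((50, 6), 0.001)  # all below MAF threshold
        with pytest.raises(ValueError):
            snp_null_test(np.linspace(0, 1, 6), snps, preds)


class TestSlopeContrast:
    def test_identical_matrices_zero_interaction(self):
        rng = np.random.default_rng(9)
        f = abs_diff_matrix(rng.random(6))
        d = abs_diff_matrix(rng.random(6) * 100)
        out = slope_contrast(f, f, d)
        assert out["interaction"] == pytest.approx(0.0, abs=1e-12)
        assert out["caveat_nonindependence"] is True

    def test_doubled_slope_recovered_exactly(self):
        rng = np.random.default_rng(10)
        d = abs_diff_matrix(rng.random(7) * 100)
        fc = 0.002 * d
        fi = 0.004 * d
        out = slope_contrast(fi, fc, d)
        assert out["interaction"] == pytest.approx(0.002, abs=1e-10)
        assert out["slope_collinear"] == pytest.approx(0.002, abs=1e-10)
        assert out["slope_inversion"] == pytest.approx(0.004, abs=1e-10)

    def test_mismatched_sizes_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            slope_contrast(
                abs_diff_matrix(rng.random(5)),
                abs_diff_matrix(rng.random(6)),
                abs_diff_matrix(rng.random(6)),
            )
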