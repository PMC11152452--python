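"""Windowed F_ST, span calling, PCA karyotyping and validation statistics."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_table
from transinv.scan import (
    FstWindow,
    call_inversion_span,
    heterozygosity_contrast,
    hudson_fst_components,
    hwe_deviation_fis,
    karyotype_by_pca,
    windowed_fst,
)
from transinv.simulate import default_scenario, simulate_radiation


def brute_hudson_site(alt1, n1, alt2, n2):
    """Hudson F_ST numerator/denominator for one site, from first principles.

    num = within-vs-between difference probabilities using distinct-pair
    sampling: (p1-p2)^2 - p1q1/(n1-1) - p2q2/(n2-1); den = p1q2 + p2q1.
    """
    p1, p2 = alt1 / n1, alt2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        d = np.r_[np.zeros((3, 6)), np.full((3, 6), 2)].astype(int)
        t = make_table(d, pops=["a"] * 3 + ["b"] * 3, positions=np.arange(6) * 100)
        wins = windowed_fst(t, "a", "b", window_bp=1000)
        assert wins[0].fst == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.5, size=(20, 40))
        d = np.vstack([d, d])  # population b duplicates a exactly
        t = make_table(d, pops=["a"] * 20 + ["b"] * 20, positions=np.arange(40))
        wins = windowed_fst(t, "a", "b", window_bp=100)
        assert abs(wins[0].fst) < 0.05

    @pytest.mark.parametrize("seed", range(6))
    def test_ratio_of_averages_equals_bruteforce(self, seed):
        """Windowed estimator == site-wise brute force on small random tables."""
        rng = np.random.default_rng(seed)
        n_sites = rng.integers(1, 6)
        d = rng.integers(0, 3, size=(6, n_sites))
        t = make_table(d, pops=["a"] * 3 + ["b"] * 3, positions=np.arange(n_sites))
        wins = windowed_fst(t, "a", "b", window_bp=1000)
        nums, dens = [], []
        for s in range(n_sites):
            alt1, alt2 = d[:3, s].sum(), d[3:, s].sum()
            num, den = brute_hudson_site(alt1, 6, alt2, 6)
            nums.append(num)
            dens.append(den)
        if sum(dens) > 0:
            assert wins[0].fst == pytest.approx(min(sum(nums) / sum(dens), 1.0), rel=1e-12)
        else:
            assert math.isnan(wins[0].fst)

    def test_unknown_population_rejected(self):
        t = make_table(np.zeros((2, 3), dtype=int), pops=["a", "b"])
        with pytest.raises(KeyError):
            windowed_fst(t, "a", "nope")

    def test_empty_windows_carry_nan(self):
        t = make_table([[0, 2], [2, 0]], pops=["a", "b"], positions=[0, 5000])
        wins = windowed_fst(t, "a", "b", window_bp=1000, step_bp=1000, chrom_length=6000)
        assert any(math.isnan(w.fst) for w in wins)


class TestSpanCalling:
    def windows(self, fsts, window_bp=10_000, step_bp=2_000):
        return [
            FstWindow("chr1", i * step_bp, i * step_bp + window_bp, 5, f)
            for i, f in enumerate(fsts)
        ]

    def test_direct_rule_application(self):
        wins = self.windows([0.1, 0.9, 0.95, 0.85, 0.2])
        span = call_inversion_span(wins, threshold=0.77, buffer_bp=0)
        assert (span.start, span.end) == (2_000, 16_000)

    def test_all_below_threshold_is_no_call(self):
        wins = self.windows([0.1, 0.2, 0.3])
        assert call_inversion_span(wins, 0.77, 0) is None

    def test_idempotent_on_own_output(self):
        wins = self.windows([0.1, 0.9, 0.8, 0.9, 0.1])
        s1 = call_inversion_span(wins, 0.5, 1000)
        inner = [w for w in wins if s1.start <= w.start and w.end <= s1.end]
        s2 = call_inversion_span(inner, 0.5, 1000)
        assert (s1.start, s1.end) == (s2.start, s2.end)

    def test_collinear_complement_clamped(self):
        wins = self.windows([0.1, 0.9, 0.1])
        span = call_inversion_span(wins, 0.5, buffer_bp=3_000)
        parts = span.collinear(chrom_length=30_000)
        assert parts == [(15_000, 30_000)]  # left side swallowed by the buffer


class TestKaryotyping:
    def test_recovery_on_trans_species_inversion(self, radiation):
        scenario, res = radiation
        inside = res.ingroup.restrict("chr1", *res.true_span)
        calls = karyotype_by_pca(inside)
        assert calls.diagnostic == "ok"
        truth = res.true_karyotypes.loc[calls.genotype.index]
        acc = (calls.genotype == truth).mean()
        calls.swap_polarity()  # A/D polarity is provisional before polarization
        acc_swapped = (calls.genotype == truth).mean()
        assert max(acc, acc_swapped) >= 0.99

    def test_sample_order_invariance(self, radiation):
        _, res = radiation
        inside = res.ingroup.restrict("chr1", *res.true_span)
        calls = karyotype_by_pca(inside)
        perm = list(np.random.default_rng(1).permutation(inside.sample_ids))
        calls_perm = karyotype_by_pca(inside.take_samples(perm))
        assert (calls.genotype.loc[perm] == calls_perm.genotype).all()

    def test_no_inversion_structure_is_degenerate(self):
        rng = np.random.default_rng(2)
        d = (rng.random((30, 300)) < rng.random(300) * 0.5).astype(int) + (
            rng.random((30, 300)) < rng.random(300) * 0.5
        ).astype(int)
        t = make_table(d, positions=np.arange(300))
        calls = karyotype_by_pca(t)
        assert calls.diagnostic.startswith("no-inversion")

    def test_too_few_samples_rejected(self):
        t = make_table([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            karyotype_by_pca(t)

    def test_ad_center_between_homokaryotype_centers(self, radiation):
        _, res = radiation
        inside = res.ingroup.restrict("chr1", *res.true_span)
        calls = karyotype_by_pca(inside)
        assert calls.centers[0] < calls.centers[1] < calls.centers[2]


class TestHeterozygosityContrast:
    def test_heterokaryotypes_have_excess(self, radiation):
        scenario, res = radiation
        inside = res.ingroup.restrict("chr1", *res.true_span)
        calls = karyotype_by_pca(inside)
        from transinv.scan import InversionSpan

        span = InversionSpan("chr1", *res.true_span, threshold=0.5, buffer_bp=200_000)
        out = heterozygosity_contrast(
            res.ingroup, calls, span, scenario.chrom_length, n_permutations=199, seed=1
        )
        assert out["contrast"] > 0
        assert out["p_value"] < 0.05

    def test_no_heterokaryotypes_reports_missing(self, radiation):
        scenario, res = radiation
        inside = res.ingroup.restrict("chr1", *res.true_span)
        calls = karyotype_by_pca(inside)
        calls.genotype[:] = "AA"
        from transinv.scan import InversionSpan

        span = InversionSpan("chr1", *res.true_span, threshold=0.5, buffer_bp=0)
        out = heterozygosity_contrast(res.ingroup, calls, span, scenario.chrom_length)
        assert math.isnan(out["contrast"])


class TestFis:
    def test_all_heterozygotes_strongly_negative(self):
        # n=3 diploids all het: H_exp = 0.5 * 6/5, F_IS = 1 - 1/0.6
        t = make_table([[1], [1], [1]])
        n = 6
        h_exp = 2 * 0.5 * 0.5 * n / (n - 1)
        assert hwe_deviation_fis(t) == pytest.approx(1 - 1 / h_exp)

    def test_hwe_proportions_near_zero(self):
        rng = np.random.default_rng(3)
        p = 0.4
        haps = (rng.random((400, 50)) < p).astype(int)
        d = haps[::2] + haps[1::2]
        t = make_table(d, positions=np.arange(50))
        assert abs(hwe_deviation_fis(t)) < 0.02

    def test_monomorphic_undefined(self):
        t = make_table(np.zeros((4, 6), dtype=int))
        assert math.isnan(hwe_deviation_fis(t))

    def test_heterokaryotypes_more_negative_inside_inversion(self, radiation):
        _, res = radiation
        inside = res.ingroup.restrict("chr1", *res.true_span)
        calls = karyotype_by_pca(inside)
        fis_het = hwe_deviation_fis(inside, calls.heterokaryotypes)
        fis_hom = hwe_deviation_fis(inside, calls.samples_with("AA"))
        assert fis_het < fis_hom
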