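"""Genotype filtering, kinship, mixed-model association and windowed FST."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flameback import assoc
from flameback.assoc import (centred_kinship, filter_variants,
                             genome_coverage_percent, impute_missing, lmm_wald,
                             manhattan_table, read_vcf, windowed_fst, write_vcf)

from conftest import toy_matrix


class TestVcfRoundTrip:
    def make_fixture(self):
        gt = np.array([[0, 1, 2, -1, 1],
                       [1, 0, 2, 0, -1],
                       [2, 2, 0, 1, 0]])
        dp = np.array([[10, 8, 30, 5, 12],
                       [7, 9, 25, 6, 11],
                       [14, 6, 40, 8, 9]], dtype=float)
        gq = np.array([[40, 35, 60, 20, 45],
                       [38, 42, 55, 30, 50],
                       [44, 33, 58, 41, 36]], dtype=float)
        ad_alt = np.array([[0, 4, 30, 0, 6],
                           [3, 0, 25, 0, 0],
                           [14, 6, 0, 4, 0]], dtype=float)
        return toy_matrix(gt, dp=dp, gq=gq, ad_alt=ad_alt,
                          pos=np.array([100, 200, 300, 400, 500]))

    def test_gt_dp_gq_ad_round_trip(self, tmp_path):
        m = self.make_fixture()
        path = tmp_path / "t.vcf"
        write_vcf(m, path)
        back = read_vcf(path)
        assert back.samples == m.samples
        np.testing.assert_array_equal(back.gt, m.gt)
        np.testing.assert_array_equal(back.dp, m.dp)
        np.testing.assert_array_equal(back.gq, m.gq)
        np.testing.assert_array_equal(back.ad_alt, m.ad_alt)
        np.testing.assert_array_equal(back.ad_ref, m.ad_ref)
        np.testing.assert_array_equal(back.pos, m.pos)

    def test_missing_genotype_parsed_as_missing(self, tmp_path):
        m = self.make_fixture()
        path = tmp_path / "t.vcf"
        write_vcf(m, path)
        back = read_vcf(path)
        assert np.isnan(back.dosage_matrix()[0, 3])

    def test_multiallelic_record_flagged_not_dropped(self, tmp_path):
        m = self.make_fixture()
        m.alt[2] = "G,T"
        path = tmp_path / "t.vcf"
        write_vcf(m, path)
        back = read_vcf(path)
        assert back.n_sites == 5
        assert not back.is_biallelic_snp[2]
        assert back.is_biallelic_snp[[0, 1, 3, 4]].all()


class TestFilterVariants:
    def test_multiallelic_removed_first(self):
        m = toy_matrix(np.array([[0, 1], [1, 1], [2, 1], [1, 0], [1, 2]]))
        m.alt[0] = "G,T"
        out, counts = filter_variants(m, mac_min=0, max_missing_frac=1.0)
        assert counts["non_biallelic_snp"] == 1
        assert out.n_sites == 1

    def test_low_mac_site_removed(self):
        # alt allele seen twice in total -> mac 2 < 3
        gt = np.array([[1, 1, 0, 0, 0, 0],    # mac 2
                       [1, 1, 1, 0, 0, 0]]).T  # mac 3
        out, counts = filter_variants(toy_matrix(gt))
        assert counts["mac_below_min"] == 1
        assert out.n_sites == 1

    def test_low_depth_genotype_masked_not_site_dropped(self):
        gt = np.tile([0, 1, 2, 1, 0, 1], (1, 1)).T.reshape(6, 1)
        dp = np.full((6, 1), 20.0)
        dp[0, 0] = 2  # below dp_min with high GQ
        out, counts = filter_variants(toy_matrix(gt, dp=dp))
        assert counts["genotypes_masked"] == 1
        assert out.n_sites == 1
        assert np.isnan(out.dosage_matrix()[0, 0])

    def test_excess_missing_site_dropped(self):
        gt = np.array([[-1, -1, -1, 1, 1, 0],   # 50% missing: kept
                       [-1, -1, -1, -1, 1, 1]]).T  # 67% missing: dropped
        out, counts = filter_variants(toy_matrix(gt), mac_min=0)
        assert counts["excess_missing"] == 1
        assert out.n_sites == 1

    def test_site_rule_counts_sum_to_removed(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 3, size=(12, 40))
        gt[rng.random(gt.shape) < 0.3] = -1
        m = toy_matrix(gt)
        m.alt[:5] = "G,T"
        out, counts = filter_variants(m)
        removed = (counts["non_biallelic_snp"] + counts["mac_below_min"]
                   + counts["excess_missing"])
        assert removed == counts["sites_in"] - counts["sites_out"]


class TestImputation:
    def test_global_mean_fills_with_site_mean(self):
        m = toy_matrix(np.array([[0], [2], [-1]]))
        out = impute_missing(m, method="global_mean")
        assert out.dosages[2, 0] == pytest.approx(1.0)

    def test_complete_matrix_unchanged(self):
        gt = np.array([[0, 1], [2, 1], [1, 0]])
        out = impute_missing(toy_matrix(gt), method="global_mean")
        np.testing.assert_allclose(out.dosages, gt)

    def test_all_missing_site_errors(self):
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(toy_matrix(np.array([[-1], [-1], [-1]])),
                           method="global_mean")

    def test_group_mean_uses_group_frequencies(self):
        m = toy_matrix(np.array([[2], [2], [0], [0], [-1]]))
        groups = {"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "A"}
        out = impute_missing(m, method="group_mean", groups=groups)
        assert out.dosages[4, 0] == pytest.approx(2.0)


class TestKinship:
    def test_row_sums_zero(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(20, 100)).astype(float)
        K = centred_kinship(X)
        assert np.abs(K.sum(axis=1)).max() < 1e-9

    def test_duplicate_individuals_identical_rows(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(5, 50)).astype(float)
        X = np.vstack([X, X[0]])
        K = centred_kinship(X)
        np.testing.assert_allclose(K[0], K[-1], atol=1e-12)

    def test_positive_semi_definite(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(15, 60)).astype(float)
        K = centred_kinship(X)
        assert np.linalg.eigvalsh(K).min() >= -1e-8 * np.trace(K)

    def test_missing_values_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="missing"):
            centred_kinship(X)


def ols_wald_p(y, x):
    """Closed-form OLS Wald oracle: chi-square(1) on (beta/se)^2 with
    sigma^2 = RSS / (n - 2)."""
    n = y.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    wald = beta[1] ** 2 / cov[1, 1]
    return beta[1], float(sps.chi2.sf(wald, df=1))


class TestLmmWald:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(4)
        n, p = 60, 25
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        y = 0.3 * X[:, 0] + rng.normal(size=n)
        out = lmm_wald(y, X, np.eye(n))
        for j in range(p):
            beta, pval = ols_wald_p(y, X[:, j])
            assert out["beta"][j] == pytest.approx(beta, abs=1e-6)
            assert out["wald_p"][j] == pytest.approx(pval, abs=1e-6)

    def test_constant_phenotype_null_results(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(30, 10)).astype(float)
        out = lmm_wald(np.ones(30), X, np.eye(30))
        assert np.allclose(out["beta"], 0.0, atol=1e-10)
        assert (out["wald_p"] > 0.99).all()

    def test_fdr_column_reproduces_bh(self):
        from flameback.stats import bh_fdr
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(40, 30)).astype(float)
        y = rng.normal(size=40)
        out = lmm_wald(y, X, centred_kinship(X))
        np.testing.assert_allclose(out["fdr_adjusted_p"],
                                   bh_fdr(out["wald_p"].to_numpy()))

    def test_asymmetric_kinship_rejected(self):
        K = np.eye(4)
        K[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            lmm_wald(np.zeros(4), np.zeros((4, 2)), K)


def hudson_site(p1, n1, p2, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


class TestWindowedFst:
    def pops(self, n_each=4):
        return {f"s{i}": ("p1" if i < n_each else "p2") for i in range(2 * n_each)}

    def test_fixed_differences_give_one(self):
        gt = np.vstack([np.zeros((4, 5)), np.full((4, 5), 2)]).astype(int)
        out = windowed_fst(toy_matrix(gt), self.pops())
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_identical_genotype_columns_give_estimator_floor(self):
        # with the sample-size-corrected Hudson terms, identical columns give
        # exactly -1/(n_alleles - 1), which vanishes as samples grow
        block = np.array([[0, 1], [1, 2], [2, 0], [1, 1]])
        gt = np.vstack([block, block])
        out = windowed_fst(toy_matrix(gt), self.pops())
        assert out["fst"].iloc[0] == pytest.approx(-1 / 7, abs=1e-12)
        big = np.vstack([block] * 20)
        gt_big = np.vstack([big, big])
        pops = {f"s{i}": ("p1" if i < 80 else "p2") for i in range(160)}
        out_big = windowed_fst(toy_matrix(gt_big), pops)
        assert abs(out_big["fst"].iloc[0]) < 0.01

    def test_five_site_window_matches_per_site_oracle(self):
        rng = np.random.default_rng(7)
        gt = rng.integers(0, 3, size=(8, 5))
        out = windowed_fst(toy_matrix(gt), self.pops())
        nums, dens = [], []
        for j in range(5):
            p1 = gt[:4, j].sum() / 8
            p2 = gt[4:, j].sum() / 8
            n, d = hudson_site(p1, 8, p2, 8)
            nums.append(n)
            dens.append(d)
        expected = sum(nums) / sum(dens)
        assert out["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_sample_order_and_allele_flip(self):
        rng = np.random.default_rng(8)
        gt = rng.integers(0, 3, size=(8, 12))
        m = toy_matrix(gt)
        pops = self.pops()
        base = windowed_fst(m, pops)["fst"].iloc[0]
        # sample order
        perm = rng.permutation(8)
        m2 = toy_matrix(gt[perm])
        pops2 = {f"s{i}": pops[f"s{j}"] for i, j in enumerate(perm)}
        assert windowed_fst(m2, pops2)["fst"].iloc[0] == pytest.approx(base, abs=1e-12)
        # ref/alt flip at every site
        m3 = toy_matrix(2 - gt)
        assert windowed_fst(m3, pops)["fst"].iloc[0] == pytest.approx(base, abs=1e-12)

    def test_window_mode_sequenced_counts_covered_sites(self):
        rng = np.random.default_rng(9)
        gt = rng.integers(0, 3, size=(8, 10))
        out = windowed_fst(toy_matrix(gt), self.pops(), window_sequenced_bp=4)
        assert out["n_sites"].tolist() == [4, 4, 2]

    def test_weir_cockerham_estimator_agrees_on_fixed_differences(self):
        gt = np.vstack([np.zeros((4, 5)), np.full((4, 5), 2)]).astype(int)
        out = windowed_fst(toy_matrix(gt), self.pops(), estimator="weir_cockerham")
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_three_populations_rejected(self):
        pops = {f"s{i}": f"p{i % 3}" for i in range(6)}
        with pytest.raises(ValueError, match="two populations"):
            windowed_fst(toy_matrix(np.zeros((6, 3), dtype=int)), pops)


class TestManhattanAndCoverage:
    def test_boundary_site_flagged(self):
        df = pd.DataFrame({"chrom": ["c"] * 2, "pos": [1, 2],
                           "wald_p": [0.01, 0.9],
                           "fdr_adjusted_p": [0.05, 1.0]})
        out = manhattan_table(df)
        assert bool(out["significant"][0])
        assert not bool(out["significant"][1])

    def test_all_null_gives_empty_significant_list(self):
        df = pd.DataFrame({"chrom": ["c"] * 3, "pos": [1, 2, 3],
                           "wald_p": [1.0] * 3, "fdr_adjusted_p": [1.0] * 3})
        assert not manhattan_table(df)["significant"].any()

    def test_reduced_representation_coverage_fraction(self):
        assert genome_coverage_percent(44_246_048, 1.19e9) == pytest.approx(3.7, abs=0.05)
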