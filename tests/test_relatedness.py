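"""GRM construction, weighting schemes, PCA, covariate similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wgpred import (
    KinshipMatrix,
    SNPWeightVector,
    apply_scheme_nzw,
    apply_scheme_w1,
    apply_scheme_w2,
    combine_similarity,
    compute_grm,
    covariate_similarity,
    genotype_pca,
    grm_for_scheme,
)
from wgpred.simulate import SimConfig, simulate_genotypes

from conftest import make_genotypes


def brute_force_grm(dosages, weights=None):
    """Independent double-loop oracle for the weighted GRM."""
    n, m = dosages.shape
    w = np.ones(m) if weights is None else np.asarray(weights, float)
    p = dosages.mean(axis=0) / 2.0
    a = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for i in range(m):
                denom = 2 * p[i] * (1 - p[i])
                acc += (
                    w[i]
                    * (dosages[j, i] - 2 * p[i])
                    * (dosages[k, i] - 2 * p[i])
                    / denom
                )
            a[j, k] = acc / w.sum()
    return a


class TestComputeGRM:
    def test_identical_genotypes_identical_entries(self):
        d = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0.0]])
        k = compute_grm(make_genotypes(d))
        assert k.values[0, 1] == pytest.approx(k.values[0, 0])
        assert k.values[0, 1] == pytest.approx(k.values[1, 1])

    def test_two_subject_worked_example(self):
        # dosages A=(0,2), B=(2,0), p=(0.5,0.5):
        # A_AB = [(0-1)(2-1)/(2*0.5*0.5) + (2-1)(0-1)/(2*0.5*0.5)] / 2
        #      = (-2 - 2) / 2 = -2, and A_AA = (+2 + 2)/2 = +2
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        k = compute_grm(make_genotypes(d))
        assert k.values[0, 1] == pytest.approx(-2.0, abs=1e-12)
        assert k.values[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_mean_diagonal_near_one_under_hwe(self):
        g = simulate_genotypes(SimConfig(n_subjects=500, n_snps=5000, seed=6))
        k = compute_grm(g)
        assert np.diag(k.values).mean() == pytest.approx(1.0, abs=0.02)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (12, 25)).astype(float)
        g = make_genotypes(d)
        w = rng.uniform(0.1, 2.0, 25)
        k1 = compute_grm(g, SNPWeightVector(g.snp_ids, w, "W1"))
        k2 = compute_grm(g, SNPWeightVector(g.snp_ids, 37.5 * w, "W1"))
        np.testing.assert_allclose(k1.values, k2.values, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(3):
            n, m = rng.integers(3, 11), rng.integers(5, 21)
            d = rng.integers(0, 3, (n, m)).astype(float)
            d[:, d.sum(axis=0) == 0] = 1.0  # avoid monomorphic
            g = make_genotypes(d)
            w = rng.uniform(0.0, 1.0, m)
            w[0] = 1.0
            k = compute_grm(g, SNPWeightVector(g.snp_ids, w, "W1"))
            np.testing.assert_allclose(
                k.values, brute_force_grm(d, w), atol=1e-10
            )

    def test_standard_grm_is_zzT_over_m(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (10, 20)).astype(float)
        assert np.all(d.std(axis=0) > 0)  # seed chosen to avoid monomorphs
        g = make_genotypes(d)
        p = g.allele_freqs()
        z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
        np.testing.assert_allclose(
            compute_grm(g).values, z @ z.T / d.shape[1], atol=1e-10
        )

    def test_monomorphic_with_weight_rejected(self):
        d = np.array([[0.0, 1], [0, 2], [0, 1]])
        g = make_genotypes(d)
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(g)

    def test_missing_genotypes_rejected(self):
        g = make_genotypes(np.array([[0.0, np.nan], [1, 2], [2, 1]]))
        with pytest.raises(ValueError, match="impute"):
            compute_grm(g)

    def test_numerical_psd(self, small_grm):
        vals = np.linalg.eigvalsh(small_grm.values)
        assert vals.min() >= -1e-8 * vals.max()


def _score_table(snp_ids, total, reg):
    total = np.asarray(total, float)
    reg = np.asarray(reg, float)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "total_score": total,
            "regulatory_component": reg,
            "maf_component": total - reg,
        }
    )


class TestWeightingSchemes:
    def setup_method(self):
        rng = np.random.default_rng(4)
        self.d = rng.integers(0, 3, (20, 10)).astype(float)
        self.d[0, self.d.sum(axis=0) == 0] = 1.0
        self.g = make_genotypes(self.d)

    def test_w1_uses_total_score_zeros_drop_out(self):
        total = np.array([0.5, 0, 1, 1, 1, 1, 1, 1, 1, 1.0])
        scores = _score_table(self.g.snp_ids, total, total / 2)
        k = compute_grm(self.g, apply_scheme_w1(scores, self.g.snp_ids))
        # SNP rs1 contributes nothing: equals GRM on the manual subset
        keep = total > 0
        sub = self.g.subset_snps(keep)
        k2 = compute_grm(
            sub, SNPWeightVector(sub.snp_ids, total[keep], "W1"),
            allele_freqs=self.g.allele_freqs()[keep],
        )
        np.testing.assert_allclose(k.values, k2.values, atol=1e-12)

    def test_w2_regulatory_component_only(self):
        total = np.ones(10)
        reg = np.zeros(10)
        reg[:5] = 1.0  # SNPs 5..9 are purely MAF-driven
        scores = _score_table(self.g.snp_ids, total, reg)
        w1 = apply_scheme_w1(scores, self.g.snp_ids)
        w2 = apply_scheme_w2(scores, self.g.snp_ids)
        assert np.all(w1.weights > 0)
        np.testing.assert_array_equal(w2.weights[5:], 0.0)
        # W2 == W1 when MAF components vanish
        scores_nomaf = _score_table(self.g.snp_ids, reg, reg)
        w1b = apply_scheme_w1(scores_nomaf, self.g.snp_ids)
        np.testing.assert_array_equal(
            apply_scheme_w2(scores_nomaf, self.g.snp_ids).weights, w1b.weights
        )

    def test_w1_w2_rank_correlation_on_fixture(self):
        rng = np.random.default_rng(5)
        reg = rng.uniform(0, 0.1, 10)
        total = reg + rng.uniform(0, 0.02, 10)
        scores = _score_table(self.g.snp_ids, total, reg)
        w1 = apply_scheme_w1(scores, self.g.snp_ids).weights
        w2 = apply_scheme_w2(scores, self.g.snp_ids).weights
        rho = stats.spearmanr(w1, w2).statistic
        assert rho > 0.8

    def test_nzw_subset_and_standard_weights(self):
        total = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1.0])
        scores = _score_table(self.g.snp_ids, total, total)
        sub, w = apply_scheme_nzw(scores, self.g)
        assert sub.n_snps == 6
        np.testing.assert_array_equal(w.weights, 1.0)
        # NZW GRM equals the standard GRM of the manually subset matrix
        k = grm_for_scheme(self.g, "NZW", scores)
        k2 = compute_grm(self.g.subset_snps(total > 0))
        np.testing.assert_allclose(k.values, k2.values, atol=1e-12)

    def test_nzw_all_positive_is_identity_subset(self):
        scores = _score_table(self.g.snp_ids, np.ones(10), np.ones(10))
        sub, _ = apply_scheme_nzw(scores, self.g)
        assert sub.n_snps == self.g.n_snps

    def test_all_zero_scores_rejected(self):
        scores = _score_table(self.g.snp_ids, np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            apply_scheme_w1(scores, self.g.snp_ids)
        with pytest.raises(ValueError):
            apply_scheme_nzw(scores, self.g)


class TestPCA:
    def _two_pop_grm(self, n_per=60, m=400, seed=7):
        rng = np.random.default_rng(seed)
        p1 = rng.uniform(0.1, 0.5, m)
        shift = rng.uniform(-0.2, 0.2, m)
        p2 = np.clip(p1 + shift, 0.05, 0.5)
        d = np.vstack(
            [rng.binomial(2, p1, (n_per, m)), rng.binomial(2, p2, (n_per, m))]
        ).astype(float)
        poly = d.std(axis=0) > 0
        return compute_grm(make_genotypes(d[:, poly])), np.repeat([0, 1], n_per)

    def test_pc1_separates_populations(self):
        k, pop = self._two_pop_grm()
        pcs = genotype_pca(k, 2)
        r = stats.pointbiserialr(pop, pcs["PC1"].to_numpy()).statistic
        assert abs(r) > 0.9

    def test_components_orthogonal(self, small_grm):
        pcs = genotype_pca(small_grm, 6).to_numpy()
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_too_many_components_rejected(self, small_grm):
        with pytest.raises(ValueError, match="n_components"):
            genotype_pca(small_grm, small_grm.n_subjects)

    def test_asymmetric_matrix_rejected(self):
        vals = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            KinshipMatrix(["a", "b"], vals, 1)


class TestCovariateSimilarity:
    def test_binary_covariate_block_structure(self):
        cov = pd.DataFrame({"x": [1.0, 1, 1, 0, 0, 0]},
                           index=[f"s{i}" for i in range(6)])
        k = covariate_similarity(cov)
        assert k.values[0, 1] > k.values[0, 3]

    def test_identical_rows_maximal(self):
        rng = np.random.default_rng(8)
        cov = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"s{i}" for i in range(5)])
        cov.iloc[1] = cov.iloc[0]
        k = covariate_similarity(cov)
        assert k.values[0, 1] == pytest.approx(k.values[0, 0])
        assert k.values[0, 1] >= k.values[0, 2:].max()

    def test_hand_computed_three_subject_example(self):
        # covariates: a=(1,2,3), b=(0,0,3); standardized (ddof=0):
        # za=(-1.2247, 0, 1.2247)/..., computed below independently
        cov = pd.DataFrame(
            {"a": [1.0, 2, 3], "b": [0.0, 0, 3]}, index=["s0", "s1", "s2"]
        )
        x = cov.to_numpy()
        z = (x - x.mean(0)) / x.std(0)
        expected = z @ z.T / 2
        k = covariate_similarity(cov)
        np.testing.assert_allclose(k.values, expected, atol=1e-12)

    def test_categoricals_one_hot_encoded(self):
        cov = pd.DataFrame(
            {"race": ["w", "w", "b", "h"], "age": [8.0, 9, 10, 11]},
            index=[f"s{i}" for i in range(4)],
        )
        k = covariate_similarity(cov)
        assert k.n_snps_used == 4  # 3 race levels + age

    def test_zero_variance_column_dropped_with_warning(self):
        cov = pd.DataFrame(
            {"const": [1.0, 1, 1], "x": [0.0, 1, 2]}, index=["a", "b", "c"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            k = covariate_similarity(cov)
        assert k.n_snps_used == 1

    def test_missing_covariates_rejected(self):
        cov = pd.DataFrame({"x": [1.0, np.nan, 2]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="impute"):
            covariate_similarity(cov)


class TestCombineSimilarity:
    def test_degenerate_mixings(self, small_grm):
        other = KinshipMatrix(
            small_grm.subject_ids, np.eye(small_grm.n_subjects), 1, "covariate"
        )
        k = combine_similarity([small_grm, other], (1.0, 0.0))
        np.testing.assert_array_equal(k.values, small_grm.values)
        k2 = combine_similarity([small_grm, small_grm], (0.5, 0.5))
        np.testing.assert_allclose(k2.values, small_grm.values, atol=1e-14)

    def test_invalid_mixing_rejected(self, small_grm):
        with pytest.raises(ValueError, match="sum to 1"):
            combine_similarity([small_grm, small_grm], (0.5, 0.4))
        with pytest.raises(ValueError, match="non-negative"):
            combine_similarity([small_grm, small_grm], (1.5, -0.5))

    def test_id_mismatch_rejected(self, small_grm):
        other = KinshipMatrix(
            [f"x{i}" for i in range(small_grm.n_subjects)],
            np.eye(small_grm.n_subjects), 1,
        )
        with pytest.raises(ValueError, match="ids"):
            combine_similarity([small_grm, other], (0.5, 0.5))
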