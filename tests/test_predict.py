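"""G-BLUP / kriging prediction and the baseline predictors."""

import numpy as np
import pytest
from scipy import stats

from wgpred import (
    KinshipMatrix,
    LassoLogisticWGP,
    LinearSVMWGP,
    NaiveBayesWGP,
    auc,
    compute_grm,
    gblup_predict,
    kriging_simple_predict,
    loo_predict,
    predict_with_covariates,
)

from conftest import make_genotypes


@pytest.fixture(scope="module")
def kinship_and_trait(small_cohort, small_grm):
    y = small_cohort.phenotypes["trait"].to_numpy()
    labels = small_cohort.phenotypes["label"].to_numpy()
    ids = small_grm.subject_ids
    return small_grm, y, labels, ids


class TestGBLUP:
    def test_infinite_shrinkage_returns_training_mean(self, kinship_and_trait):
        k, y, _, ids = kinship_and_trait
        out = gblup_predict(k, y[:150], ids[:150], ids[150:], ridge=1e9)
        np.testing.assert_allclose(out.scores, y[:150].mean(), atol=1e-5)

    def test_identity_kinship_returns_training_mean(self):
        n = 30
        k = KinshipMatrix([f"s{i}" for i in range(n)], np.eye(n), 10)
        y = np.random.default_rng(0).normal(size=20)
        out = gblup_predict(k, y, [f"s{i}" for i in range(20)],
                            [f"s{i}" for i in range(20, 30)], ridge=1.0)
        np.testing.assert_allclose(out.scores, y.mean(), atol=1e-12)

    def test_mixed_model_equations_oracle(self):
        """n=20 toy: scores equal a direct MME solve to 1e-8."""
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (20, 400)).astype(float)
        d = d[:, d.std(axis=0) > 0]
        g = make_genotypes(d)
        k = compute_grm(g)
        y = rng.normal(size=14)
        ids = g.subject_ids
        lam = 0.7
        ours = gblup_predict(k, y, ids[:14], ids[14:], ridge=lam).scores

        ktt = k.values[:14, :14]
        kxt = k.values[14:, :14]
        kinv = np.linalg.inv(ktt)
        x = np.ones((14, 1))
        lhs = np.block(
            [[x.T @ x, x.T], [x, np.eye(14) + lam * kinv]]
        )
        rhs = np.concatenate([x.T @ y, y])
        sol = np.linalg.solve(lhs, rhs)
        beta, u = sol[0], sol[1:]
        mme = beta + kxt @ kinv @ u
        np.testing.assert_allclose(ours, mme, atol=1e-8)

    def test_equivariance_shift_scale(self, kinship_and_trait):
        k, y, _, ids = kinship_and_trait
        base = gblup_predict(k, y[:150], ids[:150], ids[150:], ridge=1.0).scores
        shift = gblup_predict(k, y[:150] + 5.0, ids[:150], ids[150:], ridge=1.0).scores
        scale = gblup_predict(k, 2.0 * y[:150], ids[:150], ids[150:], ridge=1.0).scores
        np.testing.assert_allclose(shift, base + 5.0, atol=1e-10)
        np.testing.assert_allclose(scale, 2.0 * base, atol=1e-10)

    def test_overlapping_sets_rejected(self, kinship_and_trait):
        k, y, _, ids = kinship_and_trait
        with pytest.raises(ValueError, match="overlap"):
            gblup_predict(k, y[:10], ids[:10], ids[5:15], ridge=1.0)


class TestKrigingSimple:
    def test_identical_subject_k1_returns_its_label(self):
        d = np.array([[0, 1, 2, 0], [2, 1, 0, 2], [0, 1, 2, 0.0]])
        k = compute_grm(make_genotypes(d))  # subject 2 == subject 0
        out = kriging_simple_predict(k, np.array([1.0, 0.0]), ["S0", "S1"],
                                     ["S2"], k_neighbors=1)
        assert out.scores[0] == pytest.approx(1.0)

    def test_uniform_kinship_returns_mean(self):
        n = 5
        k = KinshipMatrix([f"s{i}" for i in range(n)], np.full((n, n), 0.3), 10)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        out = kriging_simple_predict(k, y, [f"s{i}" for i in range(4)], ["s4"])
        assert out.scores[0] == pytest.approx(y.mean())

    def test_direction_agrees_with_gblup(self, kinship_and_trait):
        k, y, _, ids = kinship_and_trait
        a = gblup_predict(k, y[:150], ids[:150], ids[150:], ridge=1.0).scores
        b = kriging_simple_predict(k, y[:150], ids[:150], ids[150:]).scores
        assert stats.spearmanr(a, b).statistic > 0.7


class TestLOO:
    def test_matches_naive_per_subject_refit(self, kinship_and_trait):
        k, y, _, ids = kinship_and_trait
        n = 50
        sub = KinshipMatrix(ids[:n], k.values[:n, :n], k.n_snps_used)
        eff = loo_predict(sub, y[:n], "gblup", ridge=0.8).scores
        naive = np.array(
            [
                gblup_predict(
                    sub, np.delete(y[:n], j),
                    [ids[i] for i in range(n) if i != j], [ids[j]], ridge=0.8,
                ).scores[0]
                for j in range(n)
            ]
        )
        np.testing.assert_allclose(eff, naive, atol=1e-10)

    def test_subject_permutation_equivariance(self, kinship_and_trait):
        k, y, _, ids = kinship_and_trait
        n = 40
        rng = np.random.default_rng(1)
        perm = rng.permutation(n)
        sub = KinshipMatrix(ids[:n], k.values[:n, :n], k.n_snps_used)
        permed = KinshipMatrix(
            [ids[i] for i in perm], k.values[np.ix_(perm, perm)], k.n_snps_used
        )
        a = loo_predict(sub, y[:n], "gblup", ridge=1.0).scores
        b = loo_predict(permed, y[perm], "gblup", ridge=1.0).scores
        np.testing.assert_allclose(b, a[perm], atol=1e-10)

    def test_null_trait_gives_chance_auc(self, small_grm):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, small_grm.n_subjects)
        scores = loo_predict(small_grm, labels.astype(float), "gblup", 1.0).scores
        assert abs(auc(scores, labels) - 0.5) < 0.12

    def test_simple_method_and_small_n_guard(self, kinship_and_trait):
        k, y, _, ids = kinship_and_trait
        sub = KinshipMatrix(ids[:2], k.values[:2, :2], k.n_snps_used)
        with pytest.raises(ValueError, match="at least 3"):
            loo_predict(sub, y[:2], "gblup")
        sub10 = KinshipMatrix(ids[:10], k.values[:10, :10], k.n_snps_used)
        out = loo_predict(sub10, y[:10], "simple")
        assert out.scores.shape == (10,)


class TestCovariatePrediction:
    def test_genetics_only_mixing_reduces_to_gblup(self, small_cohort, small_grm):
        y = small_cohort.phenotypes["trait"].to_numpy()
        ids = small_grm.subject_ids
        cov = small_cohort.covariates
        a = predict_with_covariates(
            small_grm, cov, y[:150], ids[:150], ids[150:], mixing=(1.0, 0.0),
            ridge=1.0,
        ).scores
        b = gblup_predict(small_grm, y[:150], ids[:150], ids[150:], ridge=1.0).scores
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_covariate_driven_trait_prefers_covariate_kernel(self, small_cohort,
                                                             small_grm):
        rng = np.random.default_rng(3)
        cov = small_cohort.covariates
        ids = small_grm.subject_ids
        x = cov["age"].to_numpy(float)
        y = (x - x.mean()) / x.std() + 0.1 * rng.normal(size=len(x))
        labels = (y > y.mean()).astype(int)
        gen = gblup_predict(small_grm, y[:150], ids[:150], ids[150:], ridge=1.0)
        covp = predict_with_covariates(
            small_grm, cov, y[:150], ids[:150], ids[150:], mixing=(0.0, 1.0),
            ridge=1.0,
        )
        assert auc(covp.scores, labels[150:]) > auc(gen.scores, labels[150:])


class TestBaselines:
    def _toy(self, n=80, seed=4):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, (n, 30)).astype(float)
        labels = rng.integers(0, 2, n)
        d[:, 0] = labels * 2.0  # SNP 0 perfectly separates
        return make_genotypes(d), labels

    def test_naive_bayes_perfect_snp_dominates(self):
        g, labels = self._toy()
        model = NaiveBayesWGP().fit(g, labels)
        scores = model.predict(g).scores
        assert auc(scores, labels) == 1.0

    def test_naive_bayes_uninformative_snps_near_zero(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (400, 1)).astype(float)
        labels = rng.integers(0, 2, 400)
        model = NaiveBayesWGP().fit(make_genotypes(d), labels)
        llr = model.log_cond[1] - model.log_cond[0]
        assert np.abs(llr).max() < 0.3

    def test_naive_bayes_hand_computed_two_snp_example(self):
        # 4 train subjects: labels (0,0,1,1); SNP1 dosages (0,0,2,2),
        # SNP2 dosages (1,1,1,1). Add-one smoothing over 3 genotype bins:
        # class 0 SNP1: counts (2,0,0) -> probs (3,1,1)/5
        # class 1 SNP1: counts (0,0,2) -> probs (1,1,3)/5
        # SNP2 identical across classes -> LLR 0. Prior log-odds = log(3/3)=0.
        # test subject with SNP1=2, SNP2=1:
        #   score = log((3/5)/(1/5)) = log 3
        d = np.array([[0, 1], [0, 1], [2, 1], [2, 1.0]])
        g = make_genotypes(d)
        model = NaiveBayesWGP().fit(g, np.array([0, 0, 1, 1]))
        test = make_genotypes(np.array([[2.0, 1.0]]), subject_prefix="T")
        assert model.predict(test).scores[0] == pytest.approx(np.log(3.0))

    def test_naive_bayes_single_class_rejected(self):
        g, _ = self._toy()
        with pytest.raises(ValueError, match="both classes"):
            NaiveBayesWGP().fit(g, np.zeros(g.n_subjects))

    def test_lasso_extreme_penalty_constant_scores(self):
        g, labels = self._toy()
        model = LassoLogisticWGP(n_penalties=1)
        model.fit_predict(g, labels, g)
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(l1_ratio=1.0, C=1e-6, solver="liblinear").fit(
            np.nan_to_num(g.dosages), labels
        )
        assert np.all(lr.coef_ == 0)  # intercept-only at extreme penalty
        scores = lr.decision_function(np.nan_to_num(g.dosages))
        assert np.ptp(scores) == 0

    def test_lasso_recovers_strong_single_snp(self):
        g, labels = self._toy(n=120)
        model = LassoLogisticWGP(seed=0)
        scores = model.fit_predict(g, labels, g).scores
        coefs = np.abs(model.model.coef_.ravel())
        assert coefs[0] == coefs.max() > 0
        assert auc(scores, labels) == 1.0

    def test_svm_separable_toy_and_sign_flip(self):
        g, labels = self._toy()
        s1 = LinearSVMWGP().fit_predict(g, labels, g).scores
        assert auc(s1, labels) == 1.0
        s2 = LinearSVMWGP().fit_predict(g, 1 - labels, g).scores
        assert np.corrcoef(s1, s2)[0, 1] < -0.99
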