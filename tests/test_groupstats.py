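from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from tractage.groupstats import (
    bh_fdr,
    diagnosis_grouping,
    effect_pattern_similarity,
    gam_delta_r2,
    glm_bag_behavior,
    glm_group_effect,
    lmm_developmental,
    pds_categorize,
)

# a small fixed dataset for hand-computed oracles (n = 12)
AGE12 = np.array([8.1, 9.4, 10.2, 11.7, 12.3, 13.0, 13.8, 14.5, 15.1, 15.9, 16.4, 17.2])
SEX12 = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1.0])
BEH12 = np.array([0.3, -1.2, 0.8, 0.1, -0.5, 1.4, -0.9, 0.6, -0.2, 1.1, 0.4, -0.7])
BAG12 = np.array([0.5, -0.8, 1.1, 0.0, -0.3, 1.9, -1.2, 0.4, -0.6, 1.5, 0.2, -0.4])


class TestGlmBagBehavior:
    def test_t_matches_normal_equations_oracle(self):
        res = glm_bag_behavior(BAG12, BEH12, AGE12, SEX12)
        # oracle: direct matrix algebra via the normal equations
        X = np.column_stack([np.ones(12), BEH12, AGE12, SEX12])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ BAG12
        resid = BAG12 - X @ beta
        sigma2 = resid @ resid / (12 - 4)
        t = beta[1] / np.sqrt(sigma2 * XtX_inv[1, 1])
        assert res.stat == pytest.approx(t, abs=1e-10)
        assert res.coef == pytest.approx(beta[1], abs=1e-12)
        assert res.df == (8,)

    def test_null_behavior_t_small_on_average(self, rng):
        ts = []
        for _ in range(30):
            n = 60
            age = rng.uniform(8, 18, n)
            sex = rng.integers(0, 2, n)
            ts.append(
                glm_bag_behavior(
                    rng.normal(size=n), rng.normal(size=n), age, sex
                ).stat
            )
        assert abs(np.mean(ts)) < 0.5

    def test_perfect_association_huge_t(self, rng):
        n = 50
        b = rng.normal(size=n)
        res = glm_bag_behavior(b, b, rng.uniform(8, 18, n), rng.integers(0, 2, n))
        assert res.p < 1e-10

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            glm_bag_behavior(np.ones(5), np.ones(5), np.ones(5), np.ones(5))


class TestGroupEffect:
    def test_equal_means_no_noise_f_zero(self):
        bag = np.tile([1.0, 1.0, 1.0], 10)
        group = np.tile([0, 1, 2], 10)
        res = glm_group_effect(bag, group, adjusted=False)
        assert res.stat == pytest.approx(0.0, abs=1e-12)

    def test_two_group_tukey_equals_studentized_range_transform(self, rng):
        n = 40
        group = np.repeat([0, 1], n // 2)
        bag = rng.normal(size=n) + 0.8 * group
        res = glm_group_effect(bag, group, adjusted=False)
        # closed form: two-sample pooled t; Tukey p = sf(|t|*sqrt(2); 2, df)
        a, b = bag[group == 0], bag[group == 1]
        sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        df = n - 2
        se = np.sqrt(sp2 / df * (2 / (n // 2)))
        t = (a.mean() - b.mean()) / se
        expected = stats.studentized_range.sf(abs(t) * np.sqrt(2), 2, df)
        assert res.posthoc["p_tukey"].iloc[0] == pytest.approx(expected, abs=1e-8)
        # omnibus F equals t^2 for two groups
        assert res.stat == pytest.approx(t**2, abs=1e-8)

    def test_covariate_adjusted_means(self, rng):
        n = 300
        age = rng.uniform(8, 18, n)
        sex = rng.integers(0, 2, n)
        group = rng.integers(0, 3, n)
        bag = 0.2 * age - 0.5 * group + rng.normal(0, 0.3, n)
        res = glm_group_effect(bag, group, age, sex)
        means = res.adjusted_means
        assert means[0] > means[1] > means[2]
        assert res.p < 1e-6

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            glm_group_effect(
                rng.normal(size=10), np.array([0] * 9 + [1]), adjusted=False
            )

    def test_planted_monotone_liability_direction(self, rng):
        # lower deviation -> higher liability -> more diagnoses; the >=2
        # group should have the lowest adjusted mean BAG
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 600
            dev = r.normal(0, 1, n)
            liab = -0.5 * dev + np.sqrt(1 - 0.25) * r.normal(size=n)
            group = np.digitize(liab, np.quantile(liab, [0.75, 0.9]))
            age = r.uniform(8, 18, n)
            sex = r.integers(0, 2, n)
            bag = dev + r.normal(0, 0.8, n)
            res = glm_group_effect(bag, group, age, sex)
            hits += res.adjusted_means.idxmin() == 2
        assert hits >= 9


class TestGamDeltaR2:
    def test_null_bag_delta_r2_near_zero(self, rng):
        deltas = []
        for _ in range(10):
            n = 300
            age = rng.uniform(8, 18, n)
            sex = rng.integers(0, 2, n)
            y = 0.3 * age + rng.normal(0, 1, n)
            out = gam_delta_r2(y, rng.normal(size=n), age, sex)
            deltas.append(out.delta_r2_pct)
        assert abs(np.median(deltas)) < 0.1

    def test_saturated_outcome(self, rng):
        n = 300
        age = rng.uniform(8, 18, n)
        sex = rng.integers(0, 2, n)
        bag = rng.normal(size=n)
        out = gam_delta_r2(bag, bag, age, sex)
        # outcome equals the BAG exactly: added variance = 100% minus the
        # (tiny, spurious) covariate-only adjusted R^2
        assert out.delta_r2_pct == pytest.approx(100.0, abs=2.0)
        assert out.p < 1e-10

    def test_linear_age_effect_agrees_with_linear_model(self, rng):
        n = 500
        age = rng.uniform(8, 18, n)
        sex = rng.integers(0, 2, n)
        bag = rng.normal(size=n)
        y = 0.5 * age + 0.3 * bag + rng.normal(0, 1, n)
        gam = gam_delta_r2(y, bag, age, sex)
        # linear-fit oracle
        import statsmodels.api as sm

        Xn = sm.add_constant(np.column_stack([age, sex]))
        Xf = np.column_stack([Xn, bag])
        lin = 100 * (
            sm.OLS(y, Xf).fit().rsquared_adj - sm.OLS(y, Xn).fit().rsquared_adj
        )
        assert gam.delta_r2_pct == pytest.approx(lin, abs=0.2)

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            gam_delta_r2(np.ones(20), np.ones(20), np.ones(20), np.ones(20))


class TestLmm:
    def _two_visit_data(self, rng, n_subj=150, re_sd=1.0, beta1=0.3):
        subj = np.repeat(np.arange(n_subj), 2)
        tp = np.tile([0.0, 1.0], n_subj)
        age = rng.uniform(9, 12, n_subj)[subj] + 2 * tp
        sex = rng.integers(0, 2, n_subj)[subj]
        pred = rng.normal(size=2 * n_subj)
        u = re_sd * rng.normal(size=n_subj)
        y = beta1 * pred + 0.1 * age + u[subj] + rng.normal(0, 0.5, 2 * n_subj)
        return y, pred, age, sex, tp, subj

    def test_zero_between_subject_variance_matches_ols(self, rng):
        y, pred, age, sex, tp, subj = self._two_visit_data(rng, re_sd=0.0)
        res = lmm_developmental(y, pred, age, sex, tp, subj)
        assert res.singular
        assert res.re_variance < 0.05
        import statsmodels.api as sm
        import pandas as pd

        X = sm.add_constant(
            pd.DataFrame({"predictor": pred, "age": age, "sex": sex,
                          "timepoint": tp})
        )
        ols = sm.OLS(y, X).fit()
        assert res.coef == pytest.approx(ols.params["predictor"], abs=0.01)

    def test_parameter_recovery(self):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y, pred, age, sex, tp, subj = self._two_visit_data(
                rng, n_subj=500, beta1=0.3
            )
            res = lmm_developmental(y, pred, age, sex, tp, subj)
            errs.append(abs(res.coef - 0.3))
        assert np.mean(np.array(errs) <= 0.05) >= 0.8

    def test_fixed_effects_match_gls_closed_form(self, rng):
        y, pred, age, sex, tp, subj = self._two_visit_data(rng, n_subj=200)
        res = lmm_developmental(y, pred, age, sex, tp, subj)
        # GLS oracle with the fitted variance components, balanced design
        import pandas as pd
        import statsmodels.api as sm

        X = sm.add_constant(
            pd.DataFrame({"predictor": pred, "age": age, "sex": sex,
                          "timepoint": tp})
        ).to_numpy()
        tau2 = res.re_variance
        # residual variance from the fitted model's scale: refit to fetch it
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sm.MixedLM(y, X, groups=subj).fit(reml=True)
        sigma2 = m.scale
        blocks = []
        V1 = sigma2 * np.eye(2) + tau2
        Vinv1 = np.linalg.inv(V1)
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        for s in np.unique(subj):
            sel = subj == s
            Xs, ys = X[sel], y[sel]
            XtVX += Xs.T @ Vinv1 @ Xs
            XtVy += Xs.T @ Vinv1 @ ys
        beta_gls = np.linalg.solve(XtVX, XtVy)
        assert res.coef == pytest.approx(beta_gls[1], abs=1e-6)

    def test_single_visit_rejected(self, rng):
        with pytest.raises(ValueError):
            lmm_developmental(
                np.ones(4), np.ones(4), np.ones(4), np.ones(4), np.ones(4),
                np.arange(4),
            )


class TestPdsCategorize:
    @pytest.mark.parametrize(
        "sex,total,menarche,expected",
        [
            (1, 3, False, "prepubertal"),
            (1, 4, False, "early"),
            (1, 5, False, "early"),
            (1, 6, False, "mid"),
            (1, 8, False, "mid"),
            (1, 9, False, "late"),
            (1, 11, False, "late"),
            (1, 12, False, "postpubertal"),
            (0, 2, False, "prepubertal"),
            (0, 3, False, "early"),
            (0, 4, False, "mid"),
            (0, 8, False, "mid"),
            (0, 7, True, "late"),
            (0, 2, True, "late"),
            (0, 8, True, "postpubertal"),
        ],
    )
    def test_staging_rules(self, sex, total, menarche, expected):
        assert pds_categorize(sex, total, menarche) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pds_categorize(1, 2)
        with pytest.raises(ValueError):
            pds_categorize(0, 9)


class TestDiagnosisGrouping:
    def test_classes_and_transitions(self):
        out = diagnosis_grouping([0, 1, 3, 0], [0, 0, 2, 1])
        assert list(out["class_baseline"]) == [0, 1, 2, 0]
        assert list(out["transition"]) == ["HH", "PH", "PP", "HP"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            diagnosis_grouping([-1], [0])


class TestEffectPatternSimilarity:
    def test_identical_and_reversed(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        rho, _ = effect_pattern_similarity(a, a)
        assert rho == pytest.approx(1.0)
        rho, _ = effect_pattern_similarity(a, a[::-1])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        rho, p = effect_pattern_similarity(a, b)
        # brute force: enumerate all 720 permutations, recomputing rho with
        # scipy each time
        obs = abs(stats.spearmanr(a, b)[0])
        count = 0
        for perm in permutations(range(6)):
            r = stats.spearmanr(a[list(perm)], b)[0]
            count += abs(r) >= obs - 1e-12
        assert p == pytest.approx(count / 720, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            effect_pattern_similarity([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_large_n_uses_t_approximation(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        rho, p = effect_pattern_similarity(a, b)
        assert p == pytest.approx(stats.spearmanr(a, b)[1], abs=1e-12)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        # step-up: min over j >= i of m * p(j) / j, all equal 0.04 here
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
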