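import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tractage.scca import (
    SparseCCA,
    bootstrap_loadings,
    grid_search_sparsity,
    mode_specificity,
    permutation_test_modes,
    pmd_rank1,
    residualize,
    scca_fit,
    soft_threshold,
)
from tractage.simulate import CohortConfig, bag_feature_standins, simulate_cohort


def planted_cohort(n=2000, seed=0, noise=1.0):
    cc = CohortConfig(n_subjects=n, seed=seed)
    cohort, _, behavior, _ = simulate_cohort(cc, include_profiles=False)
    X = bag_feature_standins(cohort, cc, estimation_noise_sd=noise, seed=seed + 1)
    covs = cohort[["age", "sex"]].to_numpy()
    return cohort, residualize(X, covs), residualize(behavior, covs), cc


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self, rng):
        M = rng.normal(size=(100, 5))
        age = rng.uniform(8, 20, 100)
        out = residualize(M + 0.3 * age[:, None], age)
        for j in range(5):
            assert abs(np.corrcoef(np.asarray(out)[:, j], age)[0, 1]) < 1e-10

    def test_columns_z_scored(self, rng):
        out = np.asarray(residualize(rng.normal(3, 2, (80, 4)), rng.normal(size=80)))
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0), 1, atol=1e-8)

    def test_orthogonal_column_unchanged_up_to_zscore(self, rng):
        age = rng.uniform(8, 20, 500)
        col = rng.normal(size=500)
        col -= np.polyval(np.polyfit(age, col, 1), age)  # orthogonalize exactly
        out = np.asarray(residualize(col[:, None], age))[:, 0]
        expected = (col - col.mean()) / col.std()
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_column_linear_in_covariate_rejected(self, rng):
        age = rng.uniform(8, 20, 50)
        with pytest.raises(ValueError, match="constant column"):
            residualize((2 * age + 1)[:, None], age)

    def test_rank_deficient_design_rejected(self, rng):
        M = rng.normal(size=(30, 2))
        C = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank deficient"):
            residualize(M, C)


class TestSoftThreshold:
    def test_definition(self):
        np.testing.assert_allclose(
            soft_threshold([2.0, -0.3], 0.5), [1.5, 0.0]
        )

    def test_zero_threshold_is_identity(self, rng):
        a = rng.normal(size=20)
        np.testing.assert_allclose(soft_threshold(a, 0.0), a)

    def test_large_threshold_gives_zero(self, rng):
        a = rng.normal(size=20)
        assert np.all(soft_threshold(a, np.abs(a).max()) == 0)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30),
           st.floats(0, 5))
    @settings(deadline=None, max_examples=50)
    def test_shrinks_magnitudes(self, a, c):
        out = soft_threshold(a, c)
        assert np.all(np.abs(out) <= np.abs(a) + 1e-12)


class TestPmdRank1:
    def test_diagonal_matrix_leading_pair(self):
        u, v, d = pmd_rank1(np.diag([3.0, 1.0]), 1.0, 1.0)
        assert d == pytest.approx(3.0, abs=1e-8)
        assert abs(u[0]) == pytest.approx(1.0, abs=1e-8)
        assert abs(v[0]) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("shape", [(10, 8), (30, 51), (5, 5)])
    def test_unconstrained_matches_svd(self, shape, rng):
        Z = rng.normal(size=shape)
        u, v, d = pmd_rank1(Z, 1.0, 1.0)
        U, S, Vt = np.linalg.svd(Z)
        assert d == pytest.approx(S[0], abs=1e-6)
        sign = np.sign(u @ U[:, 0])
        np.testing.assert_allclose(u, sign * U[:, 0], atol=1e-6)
        np.testing.assert_allclose(v, sign * Vt[0], atol=1e-6)

    def test_very_small_c1_single_support(self, rng):
        Z = rng.normal(size=(12, 6))
        c1 = 1.0 / np.sqrt(12)  # L1 budget of exactly 1: one nonzero
        u, v, d = pmd_rank1(Z, c1, 1.0)
        support = np.flatnonzero(np.abs(u) > 1e-6)
        assert len(support) == 1
        # brute force over single-support solutions: best row of Z against v
        scores = np.abs(Z @ v)
        assert support[0] == int(np.argmax(scores))

    def test_constraints_satisfied(self, rng):
        for c1, c2 in [(0.3, 0.6), (0.5, 0.5), (0.9, 0.2)]:
            Z = rng.normal(size=(20, 15))
            u, v, d = pmd_rank1(Z, c1, c2)
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-8)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-8)
            # an L1 budget below 1 is infeasible given L2 = 1; the effective
            # budget is max(1, c * sqrt(dim))
            assert np.abs(u).sum() <= max(1.0, c1 * np.sqrt(20)) + 1e-6
            assert np.abs(v).sum() <= max(1.0, c2 * np.sqrt(15)) + 1e-6

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pmd_rank1(np.zeros((4, 4)), 1.0, 1.0)


class TestSparseCCAFit:
    def test_deflation_singular_values_non_increasing(self, rng):
        X = rng.normal(size=(300, 10))
        Y = rng.normal(size=(300, 12))
        model = scca_fit(X, Y, n_modes=4)
        assert np.all(np.diff(model.d_) <= 1e-9)

    def test_unconstrained_modes_match_svd_of_cross_product(self, rng):
        X = rng.normal(size=(400, 10))
        Y = rng.normal(size=(400, 13))
        model = scca_fit(X, Y, n_modes=3, c1=1.0, c2=1.0)
        U, S, Vt = np.linalg.svd(X.T @ Y)
        for k in range(3):
            assert model.d_[k] == pytest.approx(S[k], abs=1e-5)
            sign = np.sign(model.u_[:, k] @ U[:, k])
            np.testing.assert_allclose(model.u_[:, k], sign * U[:, k], atol=1e-5)

    def test_one_mode_plant_support_and_loadings_recovered(self):
        cohort, Xr, Yr, cc = planted_cohort(n=2000, seed=1)
        # one-mode view: X restricted to association tracts + noise tracts
        model = SparseCCA(n_modes=1, c1=0.6, c2=0.6).fit(Xr, Yr)
        lat = cohort["latent_association"].to_numpy()
        lat2 = cohort["latent_subcortical-limbic"].to_numpy()
        k = 0
        sc = model.x_scores_[:, k]
        match_lat = lat if abs(np.corrcoef(sc, lat)[0, 1]) > abs(
            np.corrcoef(sc, lat2)[0, 1]
        ) else lat2
        planted = np.array(
            [np.corrcoef(np.asarray(Xr)[:, j], match_lat)[0, 1]
             for j in range(Xr.shape[1])]
        )
        r = np.corrcoef(np.abs(model.x_loadings_[:, k]), np.abs(planted))[0, 1]
        assert r > 0.9

    def test_two_mode_plant_separates_systems(self):
        cohort, Xr, Yr, cc = planted_cohort(n=2000, seed=2)
        model = SparseCCA(n_modes=2, c1=0.8, c2=0.8).fit(Xr, Yr)
        lats = {
            "association": cohort["latent_association"].to_numpy(),
            "subcortical-limbic": cohort["latent_subcortical-limbic"].to_numpy(),
        }
        matches = []
        for k in range(2):
            cors = {
                name: abs(np.corrcoef(model.x_scores_[:, k], lat)[0, 1])
                for name, lat in lats.items()
            }
            best = max(cors, key=cors.get)
            assert cors[best] > 0.7
            matches.append(best)
        assert set(matches) == {"association", "subcortical-limbic"}

    def test_independent_data_small_r(self, rng):
        X = rng.normal(size=(2000, 10))
        Y = rng.normal(size=(2000, 12))
        model = scca_fit(X, Y, n_modes=1)
        assert model.R_[0] < 0.25

    def test_too_many_modes_rejected(self, rng):
        with pytest.raises(ValueError):
            scca_fit(rng.normal(size=(50, 3)), rng.normal(size=(50, 8)), n_modes=4)

    def test_sign_convention_block_sum_positive(self, rng):
        X = rng.normal(size=(300, 6))
        Y = rng.normal(size=(300, 8))
        block = np.arange(8) < 4
        model = SparseCCA(n_modes=2, sign_block=block).fit(X, Y)
        for k in range(2):
            assert model.v_[block, k].sum() >= 0


class TestGridSearch:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(120, 6))
        Y = 0.5 * X[:, :1] + rng.normal(size=(120, 5))
        a = grid_search_sparsity(X, Y, seed=3, n_resample=5)
        b = grid_search_sparsity(X, Y, seed=3, n_resample=5)
        assert a == b

    def test_sparse_signal_prefers_low_c1(self):
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            n = 300
            z = rng.normal(size=n)
            X = rng.normal(size=(n, 30))
            X[:, :3] += 1.5 * z[:, None]  # signal on 3 of 30 X-variables
            Y = np.column_stack(
                [z + rng.normal(0, 1, n) for _ in range(8)]
            )
            c1, c2 = grid_search_sparsity(X, Y, seed=seed, n_resample=5)
            hits += c1 <= 0.5
        assert hits >= 0.8 * n_rep

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search_sparsity(rng.normal(size=(20, 3)), rng.normal(size=(20, 3)))


class TestPermutationAndBootstrap:
    def test_permutation_preserves_marginals_and_detects_signal(self):
        cohort, Xr, Yr, _ = planted_cohort(n=800, seed=4)
        model = SparseCCA(n_modes=2, c1=0.8, c2=0.8).fit(Xr, Yr)
        out = permutation_test_modes(Xr, Yr, model, n_perm=99, seed=0)
        assert out["p"][0] == pytest.approx(1 / 100)
        assert np.all(out["p_fdr"] >= out["p"] - 1e-12)

    def test_null_data_nonsignificant(self, rng):
        X = rng.normal(size=(300, 8))
        Y = rng.normal(size=(300, 10))
        model = scca_fit(X, Y, n_modes=1)
        out = permutation_test_modes(X, Y, model, n_perm=99, seed=1)
        assert out["p"][0] > 0.05

    def test_bootstrap_detects_planted_loadings_and_zero_loadings(self):
        cohort, Xr, Yr, cc = planted_cohort(n=1000, seed=5)
        model = SparseCCA(n_modes=2, c1=0.8, c2=0.8,
                          sign_block=np.arange(51) < 20).fit(Xr, Yr)
        out = bootstrap_loadings(Xr, Yr, model, n_boot=100, seed=0)
        assert out["boot_y"].shape == (100, 51, 2)
        # every behavior variable carries signal in exactly one block;
        # each mode should flag mostly block variables as significant
        sig = out["y_significant"]
        assert sig.any()
        # CI bounds ordered
        assert np.all(out["y_ci"][..., 0] <= out["y_ci"][..., 1] + 1e-12)

    def test_bootstrap_ci_width_shrinks_to_zero_on_deterministic_data(self, rng):
        # a noiseless rank-1 linkage: every resample gives identical loadings
        n = 300
        z = rng.normal(size=n)
        X = np.column_stack([z, 2 * z, rng.normal(size=n)])
        Y = np.column_stack([3 * z, -z, rng.normal(size=n)])
        model = scca_fit(X, Y, n_modes=1)
        out = bootstrap_loadings(X, Y, model, n_boot=50, seed=0)
        widths = out["y_ci"][:2, 0, 1] - out["y_ci"][:2, 0, 0]
        assert np.all(widths < 0.05)


class TestModeSpecificity:
    def test_identical_distributions_not_specific(self, rng):
        a = rng.normal(0.5, 0.1, (200, 4))
        boot = np.stack([a, a], axis=-1)
        out = mode_specificity(boot)
        assert not out["specific"].any()
        np.testing.assert_allclose(out["cohens_d"], 0.0, atol=1e-12)

    def test_paired_d_definition(self, rng):
        # mean |loading| difference equal to the SD of differences -> d = 1
        n_boot = 5000
        base = rng.normal(2.0, 0.0, n_boot)
        diff = rng.normal(1.0, 1.0, n_boot)
        boot = np.stack(
            [np.column_stack([base + diff]), np.column_stack([base])], axis=-1
        )
        out = mode_specificity(boot, d_threshold=0.5)
        d = out["cohens_d"][0, 0, 1]
        assert d == pytest.approx(1.0, abs=0.05)
        assert out["specific"][0, 0]
        assert not out["specific"][0, 1]

    def test_planted_mode_exclusive_variables_flagged(self):
        cohort, Xr, Yr, cc = planted_cohort(n=1500, seed=6)
        model = SparseCCA(n_modes=2, c1=0.8, c2=0.8,
                          sign_block=np.arange(51) < 20).fit(Xr, Yr)
        out = bootstrap_loadings(Xr, Yr, model, n_boot=100, seed=0)
        spec = mode_specificity(out["boot_y"])["specific"]
        # identify which fitted mode is the cognition mode
        cog_mode = int(np.argmax(np.abs(model.y_loadings_[:20]).mean(axis=0)))
        psy_mode = 1 - cog_mode
        cog_rate = spec[:20, cog_mode].mean()
        psy_rate = spec[20:, psy_mode].mean()
        assert cog_rate > 0.8
        assert psy_rate > 0.8
        # no variable flagged specific to the wrong mode
        assert spec[:20, psy_mode].mean() < 0.1
        assert spec[20:, cog_mode].mean() < 0.1


def test_split_domain_consistency():
    """Refitting on cognition-only / psychopathology-only Y blocks yields
    brain loadings consistent with the full model (per planted mode)."""
    cohort, Xr, Yr, cc = planted_cohort(n=1500, seed=7)
    Yr = np.asarray(Yr)
    full = SparseCCA(n_modes=2, c1=0.8, c2=0.8).fit(Xr, Yr)
    cog = SparseCCA(n_modes=1, c1=0.8, c2=0.8).fit(Xr, Yr[:, :20])
    psy = SparseCCA(n_modes=1, c1=0.8, c2=0.8).fit(Xr, Yr[:, 20:])
    best_cog = max(
        abs(np.corrcoef(full.x_loadings_[:, k], cog.x_loadings_[:, 0])[0, 1])
        for k in range(2)
    )
    best_psy = max(
        abs(np.corrcoef(full.x_loadings_[:, k], psy.x_loadings_[:, 0])[0, 1])
        for k in range(2)
    )
    assert best_cog > 0.8
    assert best_psy > 0.8
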