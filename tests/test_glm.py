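"""Vertex-wise GLM engine, covariance maps, and demographics tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scnsurf import glm
from scnsurf.glm import (DesignError, chi_square_2x2, design, fit_glm,
                         interaction_map, residualize_covariates, scn_map,
                         seed_mean, thickness_group_map, thickness_psqi_map,
                         two_sample_t)
from scnsurf.mesh import SeedRegion


def brute_force_ols(y, X):
    """Independent normal-equations + explicit covariance oracle."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(xtx)
    t = beta / np.sqrt(np.diag(cov))
    return beta, t


class TestFitGlm:
    def test_noiseless_recovery_flags_infinite_t(self, rng):
        X = design(x1=rng.normal(size=12), x2=rng.normal(size=12))
        beta_true = np.array([1.0, -2.0, 0.5])
        Y = (X.matrix @ beta_true)[:, None] * np.ones((1, 4))
        sm = fit_glm(Y, X, "x1")
        np.testing.assert_allclose(sm.beta, -2.0, atol=1e-9)
        assert sm.infinite.all()
        assert np.isinf(sm.t).all()

    def test_matches_brute_force_oracle(self, rng):
        n, v = 12, 5
        X = design(a=rng.normal(size=n), b=rng.normal(size=n),
                   c=rng.normal(size=n))
        Y = rng.normal(size=(n, v))
        sm = fit_glm(Y, X, "b")
        col = X.column("b")
        for j in range(v):
            beta, t = brute_force_ols(Y[:, j], X.matrix)
            assert sm.beta[j] == pytest.approx(beta[col], abs=1e-9)
            assert sm.t[j] == pytest.approx(t[col], abs=1e-9)

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as smapi
        n = 25
        X = design(a=rng.normal(size=n), b=rng.normal(size=n))
        Y = rng.normal(size=(n, 3))
        ours = fit_glm(Y, X, "a")
        col = X.column("a")
        for j in range(3):
            fit = smapi.OLS(Y[:, j], X.matrix).fit()
            assert ours.beta[j] == pytest.approx(fit.params[col], abs=1e-10)
            assert ours.t[j] == pytest.approx(fit.tvalues[col], abs=1e-10)
        assert ours.df == n - 3

    def test_row_permutation_invariance(self, rng):
        n = 20
        X = design(a=rng.normal(size=n))
        Y = rng.normal(size=(n, 6))
        perm = rng.permutation(n)
        sm1 = fit_glm(Y, X, "a")
        sm2 = fit_glm(Y[perm], DesignMatrixPermuted(X, perm), "a")
        np.testing.assert_allclose(sm1.beta, sm2.beta, atol=1e-12)
        np.testing.assert_allclose(sm1.t, sm2.t, atol=1e-12)

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(DesignError, match="x2"):
            design(x1=x, x2=2 * x)

    def test_covariate_affine_invariance(self, rng):
        n = 30
        age = rng.uniform(20, 60, n)
        g = (np.arange(n) % 2).astype(float)
        Y = rng.normal(size=(n, 8))
        t1 = fit_glm(Y, design(g=g, age=age), "g").t
        t2 = fit_glm(Y, design(g=g, age=(age - age.mean()) / age.std()), "g").t
        np.testing.assert_allclose(t1, t2, atol=1e-8)


def DesignMatrixPermuted(X, perm):
    return glm.DesignMatrix(names=X.names, matrix=X.matrix[perm])


class TestResidualize:
    def test_idempotent_and_orthogonal(self, rng):
        n = 20
        cov = pd.DataFrame({"age": rng.uniform(20, 60, n),
                            "sex": rng.integers(0, 2, n).astype(float)})
        Y = rng.normal(size=(n, 10))
        R1 = residualize_covariates(Y, cov)
        R2 = residualize_covariates(R1, cov)
        np.testing.assert_allclose(R1, R2, atol=1e-9)
        for c in ("age", "sex"):
            assert np.abs(R1.T @ cov[c].to_numpy()).max() < 1e-8
        assert np.abs(R1.mean(axis=0)).max() < 1e-10

    def test_matches_per_vertex_regression_oracle(self, rng):
        n = 20
        cov = pd.DataFrame({"age": rng.uniform(20, 60, n),
                            "sex": rng.integers(0, 2, n).astype(float)})
        Y = rng.normal(size=(n, 10))
        R = residualize_covariates(Y, cov)
        X = np.column_stack([np.ones(n), cov["age"], cov["sex"]])
        for j in range(10):
            beta = np.linalg.solve(X.T @ X, X.T @ Y[:, j])
            np.testing.assert_allclose(R[:, j], Y[:, j] - X @ beta, atol=1e-9)

    def test_constant_covariate_rejected(self, rng):
        cov = pd.DataFrame({"age": np.full(10, 40.0)})
        with pytest.raises(DesignError, match="age"):
            residualize_covariates(rng.normal(size=(10, 3)), cov)


class TestSeedMean:
    def test_singleton_seed_is_that_column(self, rng):
        Y = rng.normal(size=(9, 20))
        s = SeedRegion("one", np.array([7]))
        np.testing.assert_array_equal(seed_mean(Y, s), Y[:, 7])

    def test_constant_rows_give_subject_constants(self):
        Y = np.outer(np.arange(5.0), np.ones(8))
        s = SeedRegion("all", np.arange(8))
        np.testing.assert_allclose(seed_mean(Y, s), np.arange(5.0))

    def test_matches_naive_loop_oracle(self, rng):
        Y = rng.normal(size=(6, 30))
        idx = np.array([2, 5, 11, 29])
        s = SeedRegion("s", idx)
        expected = [sum(Y[i, j] for j in idx) / len(idx) for i in range(6)]
        np.testing.assert_allclose(seed_mean(Y, s), expected, rtol=1e-12)


class TestScnMap:
    def test_self_correlation_vertex_flagged_infinite(self, rng):
        n = 16
        sv = rng.normal(size=n)
        Y = rng.normal(size=(n, 5))
        Y[:, 2] = sv
        sm = scn_map(Y, sv)
        assert sm.infinite[2] and np.isposinf(sm.t[2])
        assert sm.df == n - 2

    def test_t_equals_pearson_r_identity(self, rng):
        n = 24
        sv = rng.normal(size=n)
        Y = rng.normal(size=(n, 12))
        sm = scn_map(Y, sv)
        for j in range(12):
            r = np.corrcoef(sv, Y[:, j])[0, 1]
            t_from_r = r * np.sqrt((n - 2) / (1 - r ** 2))
            assert sm.t[j] == pytest.approx(t_from_r, abs=1e-9)

    def test_degenerate_seed_rejected(self, rng):
        with pytest.raises(ValueError, match="seed"):
            scn_map(rng.normal(size=(10, 3)), np.ones(10))

    def test_null_type_one_error_calibrated(self, rng):
        # white-noise null: fraction of vertices with p<0.05 near 0.05
        fracs = []
        for _ in range(20):
            sv = rng.normal(size=35)
            Y = rng.normal(size=(35, 642))
            sm = scn_map(Y, sv)
            fracs.append((sm.uncorrected_p("two-sided") < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)


class TestInteractionMap:
    def test_identical_groups_give_exact_zero(self, rng):
        half = rng.normal(size=(10, 6))
        sv_half = rng.normal(size=10)
        Y = np.vstack([half, half])
        sv = np.concatenate([sv_half, sv_half])
        g = np.repeat([0.0, 1.0], 10)
        sm = interaction_map(Y, sv, g, "group")
        np.testing.assert_allclose(sm.beta, 0.0, atol=1e-12)
        np.testing.assert_allclose(sm.t, 0.0, atol=1e-9)

    def test_equals_difference_of_per_group_slopes(self, rng):
        # exact saturated-model identity under 0/1 coding
        for _ in range(10):
            n = 30
            g = np.repeat([0.0, 1.0], n // 2)
            sv = rng.normal(size=n)
            Y = rng.normal(size=(n, 7))
            sm = interaction_map(Y, sv, g, "group")
            s_hc = scn_map(Y[g == 0], sv[g == 0]).beta
            s_pi = scn_map(Y[g == 1], sv[g == 1]).beta
            np.testing.assert_allclose(sm.beta, s_pi - s_hc, atol=1e-9)
            assert sm.df == n - 4

    def test_constant_moderator_rejected(self, rng):
        with pytest.raises(ValueError, match="moderator"):
            interaction_map(rng.normal(size=(12, 3)), rng.normal(size=12),
                            np.ones(12))

    def test_covariates_in_model_variant_reduces_df(self, rng):
        n = 24
        cov = pd.DataFrame({"age": rng.uniform(20, 60, n)})
        sm = interaction_map(rng.normal(size=(n, 3)), rng.normal(size=n),
                             np.repeat([0.0, 1.0], n // 2), "group",
                             covariates=cov)
        assert sm.df == n - 5


class TestThicknessMaps:
    def test_group_label_swap_flips_t_sign(self, rng):
        n = 30
        g = (np.arange(n) % 2).astype(float)
        age = rng.uniform(20, 60, n)
        sex = rng.integers(0, 2, n).astype(float)
        Y = rng.normal(2.5, 0.1, size=(n, 20))
        t_a = thickness_group_map(Y, g, age, sex).t
        t_b = thickness_group_map(Y, 1 - g, age, sex).t
        np.testing.assert_allclose(t_a, -t_b, atol=1e-9)

    def test_group_map_df_and_null_calibration(self, rng):
        fracs = []
        for _ in range(20):
            n = 70
            g = np.repeat([0.0, 1.0], 35)
            age = rng.uniform(20, 60, n)
            sex = rng.integers(0, 2, n).astype(float)
            Y = rng.normal(2.5, 0.1, size=(n, 500))
            sm = thickness_group_map(Y, g, age, sex)
            assert sm.df == n - 5
            fracs.append((sm.uncorrected_p("two-sided") < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.012)

    def test_psqi_partial_r_matches_two_stage_oracle(self, rng):
        n = 40
        psqi = rng.integers(0, 22, n).astype(float)
        age = rng.uniform(20, 60, n)
        sex = rng.integers(0, 2, n).astype(float)
        Y = rng.normal(2.5, 0.1, size=(n, 15))
        sm = thickness_psqi_map(Y, psqi, age, sex)
        # oracle: residualize both sides on nuisance, then plain Pearson r
        Z = np.column_stack([np.ones(n), age, sex, Y.mean(axis=1)])
        proj = np.eye(n) - Z @ np.linalg.pinv(Z)
        p_res = proj @ psqi
        for j in range(15):
            y_res = proj @ Y[:, j]
            r = np.corrcoef(p_res, y_res)[0, 1]
            assert sm.extra["partial_r"][j] == pytest.approx(r, abs=1e-9)

    def test_psqi_null_correlation_near_zero(self, rng):
        n = 2000
        psqi = rng.integers(0, 22, n).astype(float)
        Y = rng.normal(2.5, 0.1, size=(n, 5))
        sm = thickness_psqi_map(Y, psqi, rng.uniform(20, 60, n),
                                rng.integers(0, 2, n).astype(float))
        assert np.abs(sm.extra["partial_r"]).max() < 0.08


class TestSummaryTests:
    def test_psqi_table_value_pooled_matches_printed_magnitude(self):
        # the reference demographic table prints one-tailed p = 4.52e-23; pooled
        # variance from the rounded summaries lands on that magnitude, Welch not
        pooled = two_sample_t(12.57, 3.93, 35, 2.26, 1.36, 35, tails=1,
                              variance="pooled")
        assert pooled["df"] == 68
        assert abs(np.log10(pooled["p"]) - np.log10(4.52e-23)) < 0.5
        welch = two_sample_t(12.57, 3.93, 35, 2.26, 1.36, 35, tails=1,
                             variance="welch")
        assert welch["p"] > 1e-20  # Welch clearly does not reproduce it

    def test_age_table_value(self):
        res = two_sample_t(39.3, 8.6, 35, 34.9, 10.7, 35, tails=2)
        assert res["p"] == pytest.approx(0.067, abs=0.01)

    def test_identical_summaries(self):
        res = two_sample_t(5.0, 1.0, 20, 5.0, 1.0, 20, tails=2)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            two_sample_t(1, 1, 10, 0, 1, 10, tails=3)
        with pytest.raises(ValueError):
            two_sample_t(1, 0.0, 10, 0, 1, 10)

    def test_gender_chi_square_matches_printed(self):
        res = chi_square_2x2(5, 30, 9, 26)
        assert round(res["p"], 2) == 0.23

    def test_proportional_table_is_exact_null(self):
        res = chi_square_2x2(10, 20, 5, 10)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 10)

    def test_matches_permutation_oracle(self, rng):
        # counts large enough that the discrete permutation null is close
        # to the continuous chi-square reference distribution
        a, b, c, d = 35, 65, 45, 55
        res = chi_square_2x2(a, b, c, d)
        # permutation null: shuffle group labels, recompute chi2
        labels = np.repeat([0, 1], [a + b, c + d])
        outcome = np.concatenate([np.repeat([1, 0], [a, b]),
                                  np.repeat([1, 0], [c, d])])
        n_perm, exceed, ties = 10_000, 0, 0
        stat = res["chi2"]
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            aa = int(((perm == 0) & (outcome == 1)).sum())
            bb = int(((perm == 0) & (outcome == 0)).sum())
            cc = int(((perm == 1) & (outcome == 1)).sum())
            dd = int(((perm == 1) & (outcome == 0)).sum())
            s = chi_square_2x2(aa, bb, cc, dd)["chi2"]
            if s > stat + 1e-9:
                exceed += 1
            elif abs(s - stat) <= 1e-9:
                ties += 1
        # the continuous chi-square p approximates the discrete null's
        # mid-p (half weight on the observed statistic's atom)
        p_perm = (exceed + 0.5 * ties) / n_perm
        assert res["p"] == pytest.approx(p_perm, abs=0.02)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_interaction_identity_property(seed):
    """The seed x group coefficient equals the PI-minus-HC slope difference
    for any data, to floating tolerance."""
    rng = np.random.default_rng(seed)
    n = 16
    g = np.repeat([0.0, 1.0], n // 2)
    sv = rng.normal(size=n)
    Y = rng.normal(size=(n, 3))
    sm = interaction_map(Y, sv, g, "group")
    diff = scn_map(Y[g == 1], sv[g == 1]).beta - scn_map(Y[g == 0], sv[g == 0]).beta
    np.testing.assert_allclose(sm.beta, diff, atol=1e-9)
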