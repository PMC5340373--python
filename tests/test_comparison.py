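import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mnc import (
    MultilevelNormativeModel,
    PatientProfile,
    SimulationConfig,
    one_sided_decision,
    simulate_norm_data,
    t2_norm,
    univariate_comparisons,
)
from mnc.comparison import compare_profile
from mnc.errors import InputError, NumericalError


def equicorr(p, var=30.0, rho=1.0 / 3.0):
    C = np.full((p, p), var * rho)
    np.fill_diagonal(C, var)
    return C


class TestT2Norm:
    def test_patient_at_predicted_profile(self):
        y = np.full(5, 20.0)
        t2, p_value = t2_norm(y, y, equicorr(5), n=1500, df2=14929)
        assert t2 == 0.0
        assert p_value == 1.0

    def test_reported_statistic_is_significant(self):
        """An F statistic of 4.32 at (9, 30902) df has tail mass below
        0.001."""
        assert stats.f.sf(4.32, 9, 30902) < 0.001

    def test_p1_reduces_to_squared_normative_t(self):
        """With a single test, T2 = (x - yhat)^2 / C * n/(n+1) and its
        two-sided F p-value equals the two-sided t p-value at the same df."""
        n, df2, C = 120, 115, np.array([[9.0]])
        x, y_hat = np.array([17.0]), np.array([20.0])
        t2, p_value = t2_norm(x, y_hat, C, n=n, df2=df2)
        t_stat = (x[0] - y_hat[0]) / np.sqrt(C[0, 0] * (n + 1) / n)
        assert t2 == pytest.approx(t_stat**2, rel=1e-12)
        assert p_value == pytest.approx(2 * stats.t.sf(abs(t_stat), df2), rel=1e-12)

    def test_congruence_invariance(self):
        """T2 is invariant under any common nonsingular linear map applied
        to x, yhat and C congruently."""
        rng = np.random.default_rng(3)
        p = 4
        C = equicorr(p)
        x = rng.normal(20, 5, p)
        y_hat = np.full(p, 20.0)
        T = rng.normal(size=(p, p)) + 2 * np.eye(p)
        t2a, pa = t2_norm(x, y_hat, C, n=200, df2=500)
        t2b, pb = t2_norm(T @ x, T @ y_hat, T @ C @ T.T, n=200, df2=500)
        assert t2b == pytest.approx(t2a, rel=1e-9)
        assert pb == pytest.approx(pa, rel=1e-9)

    def test_p_value_decreases_along_ray(self):
        p = 3
        C = equicorr(p)
        y_hat = np.zeros(p)
        direction = np.array([1.0, -0.5, 0.25])
        pvals = [
            t2_norm(lam * direction, y_hat, C, n=500, df2=1000)[1]
            for lam in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a > b for a, b in zip(pvals, pvals[1:]))

    def test_alternative_df_scaling_agrees_for_large_norm_groups(self):
        """Feeding the adjusted df into the scaling constants (instead of
        only the F denominator) changes nothing material when the norm
        group is large."""
        rng = np.random.default_rng(5)
        x = rng.normal(18, 3, 5)
        y_hat = np.full(5, 20.0)
        t2a, pa = t2_norm(x, y_hat, equicorr(5), n=1500, df2=14929)
        t2b, pb = t2_norm(
            x, y_hat, equicorr(5), n=1500, df2=14929, df_scaling="adjusted"
        )
        assert t2b == pytest.approx(t2a, rel=5e-3)
        assert pb == pytest.approx(pa, rel=0.1)
        with pytest.raises(ValueError, match="df_scaling"):
            t2_norm(x, y_hat, equicorr(5), 1500, 14929, df_scaling="bogus")

    def test_singular_covariance_names_pair(self):
        C = equicorr(3)
        C[0, 1] = C[1, 0] = C[0, 0]  # tests 1 and 2 perfectly correlated
        C[2, 2] = 31.0
        with pytest.raises(NumericalError, match=r"\(1, 2\)"):
            t2_norm(np.zeros(3), np.ones(3), C, n=100, df2=200)

    def test_nonfinite_patient_scores_rejected(self):
        with pytest.raises(InputError):
            t2_norm(np.array([1.0, np.nan]), np.zeros(2), equicorr(2), 100, 200)
        with pytest.raises(InputError):
            PatientProfile(scores=np.array([1.0, np.inf]))


class TestUnivariate:
    def test_score_at_norm_is_midway(self):
        y = np.full(4, 20.0)
        uni = univariate_comparisons(y, y, equicorr(4), n=1500, df2=14929)
        assert (uni["t"] == 0).all()
        np.testing.assert_allclose(uni["p_one_sided"], 0.5)
        assert not uni["significant"].any()

    def test_classical_single_case_t_from_single_study_fit(self):
        """Fitted to one complete study without covariates or between
        variance, the univariate comparison reproduces the classical
        normative t with the sample mean and ML variance."""
        rng = np.random.default_rng(12)
        n, p = 60, 3
        scores = rng.normal(10, 4, size=(n, p))
        rows = [
            (1, j + 1, 0.0, 1.0, 0.0, t + 1, scores[j, t])
            for j in range(n)
            for t in range(p)
        ]
        frame = pd.DataFrame(
            rows, columns=["study", "ID", "age", "gender", "education", "test", "score"]
        )
        res = MultilevelNormativeModel(
            frame, covariates=(), estimate_between=False
        ).fit()
        x = np.array([4.0, 10.0, 16.0])
        uni = univariate_comparisons(
            x, res.predict_profile(()), res.combined_covariance,
            n=res.n_participants, df2=res.adjusted_df(),
        )
        mean = scores.mean(axis=0)
        ml_var = scores.var(axis=0)
        t_expected = (x - mean) / np.sqrt(ml_var * (n + 1) / n)
        np.testing.assert_allclose(uni["t"], t_expected, rtol=1e-4)

    def test_bonferroni_threshold_is_alpha_over_p(self):
        rng = np.random.default_rng(0)
        p = 10
        x = rng.normal(20, 3, p)
        uni = univariate_comparisons(
            x, np.full(p, 20.0), equicorr(p), n=1500, df2=14929, alpha=0.05
        )
        np.testing.assert_array_equal(
            uni["significant_bonferroni"], uni["p_one_sided"] <= 0.005
        )
        np.testing.assert_array_equal(
            uni["significant"], uni["p_one_sided"] <= 0.05
        )

    def test_bonferroni_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.integers(2, 8)
            x = rng.normal(0, 2, p)
            uni = univariate_comparisons(
                x, np.zeros(p), equicorr(p, var=4.0), n=300, df2=600
            )
            assert uni["significant_bonferroni"].sum() <= uni["significant"].sum()


class TestDecisionRules:
    def test_negative_sum_and_small_p_is_deviating(self):
        """The reported case: summed standardized deviation -0.76 with
        p < 0.001 satisfies both one-sided criteria."""
        assert one_sided_decision(-0.76, 0.0005)

    def test_positive_sum_never_deviates(self):
        assert not one_sided_decision(0.3, 1e-9)

    def test_large_p_never_deviates(self):
        assert not one_sided_decision(-2.0, 0.5)

    def test_threshold_boundary(self):
        assert one_sided_decision(-0.1, 0.10)
        assert not one_sided_decision(-0.1, 0.100001)

    def test_compare_profile_assembles_consistent_result(self):
        rng = np.random.default_rng(8)
        p = 5
        C = equicorr(p)
        x = rng.normal(16, 3, p)
        y_hat = np.full(p, 20.0)
        res = compare_profile(x, y_hat, C, n=1500, df2=14929)
        np.testing.assert_allclose(res.deviations, x - y_hat)
        np.testing.assert_allclose(
            res.standardized_deviations, (x - y_hat) / np.sqrt(np.diag(C))
        )
        assert res.sum_std_dev == pytest.approx(res.standardized_deviations.sum())
        assert res.df1 == p
        assert "T2(5, 14929)" in res.summary()

    def test_null_calibration_with_true_parameters(self):
        """Drawing patients from the model itself, the two-sided rule at
        alpha = 0.05 and the one-sided two-criterion rule (p <= 0.10 plus
        negative sum) both reject ~5% of the time."""
        rng = np.random.default_rng(314)
        p, n_rep = 10, 4000
        C = equicorr(p)
        L = np.linalg.cholesky(C)
        y_hat = np.full(p, 20.0)
        two, one = 0, 0
        for _ in range(n_rep):
            x = y_hat + L @ rng.standard_normal(p)
            r = compare_profile(x, y_hat, C, n=1500, df2=14929)
            two += r.decision_two_sided
            one += r.decision_one_sided
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert two / n_rep == pytest.approx(0.05, abs=3 * se)
        assert one / n_rep == pytest.approx(0.05, abs=3 * se)


class TestPrediction:
    def test_average_participant_gets_intercepts(self):
        cfg = SimulationConfig(seed=1)
        res = MultilevelNormativeModel(simulate_norm_data(cfg)).fit()
        y_hat = res.predict_profile({"age": 0.0, "gender": 0.0, "education": 0.0})
        np.testing.assert_allclose(y_hat, res.gamma[:, 0])

    def test_covariate_effects_add_linearly(self):
        """With the generating fixed effects, a patient 10 years older,
        male (+1), one education level up is predicted at
        20 - 1.25 + 0.5 + 1.25 = 20.5 on every test."""
        from mnc.results import MultilevelNormativeResults

        gamma = np.column_stack([
            np.full(10, 20.0), np.full(10, -0.125),
            np.full(10, 0.5), np.full(10, 1.25),
        ])
        res = MultilevelNormativeResults(
            gamma=gamma, sigma_within=np.eye(10), sigma_between=np.zeros(10),
            llf=0.0, converged=True, n_obs=15000, n_participants=1500,
            n_studies=30, covariates=("age", "gender", "education"),
        )
        y_hat = res.predict_profile({"age": 10.0, "gender": 1.0, "education": 1.0})
        np.testing.assert_allclose(y_hat, 20.5)

    def test_extrapolation_warns(self):
        cfg = SimulationConfig(p=3, n_studies=6, n_per_study=10, seed=3)
        res = MultilevelNormativeModel(simulate_norm_data(cfg)).fit()
        with pytest.warns(UserWarning, match="extrapolates"):
            res.predict_profile({"age": 1000.0, "gender": 1.0, "education": 0.0})

    def test_compare_requires_profile_when_covariates_present(self):
        cfg = SimulationConfig(p=3, n_studies=6, n_per_study=10, seed=3)
        res = MultilevelNormativeModel(simulate_norm_data(cfg)).fit()
        with pytest.raises(ValueError, match="PatientProfile"):
            res.compare(np.zeros(3))
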