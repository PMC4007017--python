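import numpy as np
import pytest

from bimocon import fixtures
from bimocon.sem import (
    PathModel,
    SampleMoments,
    SingularPathModelError,
    UnidentifiedModelError,
    cfi,
    fit_baseline,
    fit_ml,
    gfi,
    implied_covariance,
    information_criteria,
    ml_discrepancy,
    model_from_ground_truth,
    rmsea,
)
from bimocon.synth import ConnectivityGroundTruth, simulate_roi_observations


def _complete_dag(p):
    """Just-identified recursive model: every earlier variable feeds every later."""
    names = tuple(f"x{i+1}" for i in range(p))
    paths = tuple(
        (names[j], names[i]) for i in range(p) for j in range(i)
    )
    return PathModel(names, paths)


def _random_recursive_truth(p, rng, density=0.6, scale=0.6):
    A = np.zeros((p, p))
    for i in range(p):
        for j in range(i):
            if rng.random() < density:
                A[i, j] = rng.uniform(-scale, scale)
    return ConnectivityGroundTruth(
        variables=tuple(f"x{i+1}" for i in range(p)),
        path_matrix=A,
        disturbance_var=rng.uniform(0.5, 1.5, size=p),
    )


class TestImpliedCovariance:
    def test_no_paths_returns_disturbance_matrix(self):
        m = PathModel(("a", "b", "c"), ())
        psi = np.array([1.0, 2.0, 3.0])
        sigma = implied_covariance(m, psi)
        assert np.allclose(sigma, np.diag(psi))

    def test_two_variable_closed_form(self):
        m = PathModel(("x", "y"), (("x", "y"),))
        sigma = implied_covariance(m, np.array([0.5, 1.0, 1.0]))
        assert np.allclose(sigma, [[1.0, 0.5], [0.5, 1.25]])

    def test_monte_carlo_oracle_random_recursive_model(self, rng):
        truth = _random_recursive_truth(5, rng)
        model = model_from_ground_truth(truth)
        params = np.concatenate(
            [[c for _, _, c in truth.edges()], truth.disturbance_var]
        )
        obs = simulate_roi_observations(truth, 1_000_000, seed=3)
        S = np.cov(obs.to_numpy(), rowvar=False)
        assert np.abs(S - implied_covariance(model, params)).max() < 0.01

    def test_unit_gain_cycle_named_in_error(self):
        m = PathModel(("x", "y", "z"), (("x", "y"), ("y", "x")))
        with pytest.raises(SingularPathModelError, match="loop gain 1.0"):
            implied_covariance(m, np.array([1.0, 1.0, 1.0, 1.0, 1.0]))

    def test_nonpositive_disturbance_rejected(self):
        m = PathModel(("x", "y"), ())
        with pytest.raises(ValueError, match="positive"):
            implied_covariance(m, np.array([1.0, -0.5]))


class TestMlDiscrepancy:
    def test_saturated_zero(self, rng):
        X = rng.normal(size=(50, 4))
        S = np.cov(X, rowvar=False)
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form(self):
        assert ml_discrepancy(np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(
            1.0 - np.log(2.0)
        )

    def test_equals_twice_gaussian_kl_divergence(self, rng):
        # independent oracle: F(S, Sigma) = 2 KL(N(0,S) || N(0,Sigma)),
        # computed here via eigendecompositions rather than determinants
        for _ in range(5):
            L1 = rng.normal(size=(4, 4))
            L2 = rng.normal(size=(4, 4))
            S = L1 @ L1.T + 0.5 * np.eye(4)
            sigma = L2 @ L2.T + 0.5 * np.eye(4)
            w_s = np.linalg.eigvalsh(S)
            w_o = np.linalg.eigvalsh(sigma)
            kl = 0.5 * (
                np.trace(np.linalg.inv(sigma) @ S)
                - 4
                + np.sum(np.log(w_o)) - np.sum(np.log(w_s))
            )
            assert ml_discrepancy(S, sigma) == pytest.approx(2 * kl, rel=1e-10)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(20):
            L1 = rng.normal(size=(3, 3))
            L2 = rng.normal(size=(3, 3))
            S = L1 @ L1.T + 0.3 * np.eye(3)
            sigma = L2 @ L2.T + 0.3 * np.eye(3)
            assert ml_discrepancy(S, sigma) >= 0.0

    def test_non_positive_definite_reports_eigenvalue(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            ml_discrepancy(bad, np.eye(2))


class TestFitMl:
    def test_just_identified_equals_per_equation_ols(self, rng):
        # independent oracle: solve each equation's normal equations on the
        # centered data; the ML fit of the complete DAG must reproduce them
        truth = _random_recursive_truth(4, rng, density=1.0)
        obs = simulate_roi_observations(truth, 600, seed=8)
        X = obs.to_numpy() - obs.to_numpy().mean(0)
        model = _complete_dag(4)
        fit = fit_ml(model, SampleMoments.from_observations(obs))
        assert fit.chi_square < 1e-6
        assert fit.df == 0
        for i in range(1, 4):
            beta_ols = np.linalg.lstsq(X[:, :i], X[:, i], rcond=None)[0]
            for k, (frm, to) in enumerate(model.paths):
                if to == f"x{i+1}":
                    j = int(frm[1:]) - 1
                    assert fit.estimates[k] == pytest.approx(beta_ols[j], abs=1e-6)

    def test_figure_topology_has_19_degrees_of_freedom(self):
        for truth in fixtures.all_ground_truths().values():
            model = model_from_ground_truth(truth)
            assert model.p == 10
            assert model.n_free == 36
            assert model.df == 19

    def test_parameter_recovery_within_three_se(self, chain4_truth):
        model = model_from_ground_truth(chain4_truth)
        true = np.array([c for _, _, c in chain4_truth.edges()])
        obs = simulate_roi_observations(chain4_truth, 5000, seed=21)
        fit = fit_ml(model, SampleMoments.from_observations(obs))
        est = fit.path_estimates()
        se = fit.se[: len(true)]
        assert np.all(np.abs(est - true) < 3 * se)
        assert fit.converged

    def test_chi_square_is_scaled_discrepancy(self, chain4_truth):
        model = model_from_ground_truth(chain4_truth)
        obs = simulate_roi_observations(chain4_truth, 200, seed=2)
        fit = fit_ml(model, SampleMoments.from_observations(obs))
        assert fit.chi_square == pytest.approx((fit.moments.N - 1) * fit.f_min)
        assert fit.chi_square >= 0

    def test_freeing_a_parameter_never_increases_chi_square(self, chain4_truth):
        obs = simulate_roi_observations(chain4_truth, 400, seed=13)
        moments = SampleMoments.from_observations(obs)
        nested = model_from_ground_truth(chain4_truth)
        fit_nested = fit_ml(nested, moments)
        for extra in [("x1", "x3"), ("x1", "x4"), ("x2", "x4")]:
            fuller = nested.with_path(*extra)
            fit_full = fit_ml(fuller, moments)
            assert fit_full.chi_square <= fit_nested.chi_square + 1e-6

    def test_saturated_model_perfect_fit(self, rng):
        obs = rng.normal(size=(100, 4)) @ rng.normal(size=(4, 4))
        moments = SampleMoments.from_observations(obs)
        fit = fit_ml(_complete_dag(4), moments)
        assert fit.f_min < 1e-10
        assert fit.df == 0
        assert fit.gfi == pytest.approx(1.0, abs=1e-6)
        assert np.isnan(fit.rmsea)

    def test_standardized_coefficients_invariant_to_rescaling(self, chain4_truth):
        # refitting on the correlation-scaled problem must reproduce the
        # standardized coefficients computed from the fitted covariance
        model = model_from_ground_truth(chain4_truth)
        obs = simulate_roi_observations(chain4_truth, 500, seed=4)
        fit_raw = fit_ml(model, SampleMoments.from_observations(obs))
        scaled = obs / obs.std(ddof=1)
        fit_scaled = fit_ml(model, SampleMoments.from_observations(scaled))
        assert np.abs(fit_raw.standardized() - fit_scaled.standardized()).max() < 1e-4

    def test_underidentified_reciprocal_block_raises(self, rng):
        # a two-variable feedback loop with no instruments: 5 free
        # parameters against 6 moments but an unidentifiable submodel
        import pandas as pd

        model = PathModel(("x", "y", "z"), (("x", "y"), ("y", "x")))
        obs = pd.DataFrame(rng.normal(size=(300, 3)), columns=["x", "y", "z"])
        with pytest.raises(UnidentifiedModelError):
            fit_ml(model, SampleMoments.from_observations(obs))

    def test_low_n_fit_warns_but_is_emitted(self, rng):
        truth = fixtures.ground_truth("elderly", "in_phase")
        model = model_from_ground_truth(truth)
        obs = simulate_roi_observations(truth, 20, seed=1)
        with pytest.warns(UserWarning, match="unreliable"):
            fit = fit_ml(model, SampleMoments.from_observations(obs))
        assert fit.chi_square >= 0.0

    def test_non_positive_definite_moments_rejected(self):
        import pandas as pd

        model = PathModel(("a", "b", "c"), ())
        X = np.zeros((5, 3))
        X[:, 0] = [1, 2, 3, 4, 5]
        X[:, 1] = X[:, 0] * 2  # collinear
        X[:, 2] = [5, 4, 3, 2, 1]
        with pytest.raises(ValueError, match="positive definite"):
            fit_ml(model, SampleMoments.from_observations(
                pd.DataFrame(X, columns=["a", "b", "c"])
            ))


class TestFitIndices:
    def test_rmsea_zero_when_chi_square_below_df(self):
        # the printed battery of the best-fitting 10-ROI model: chi2(19) =
        # 8.686 at N = 20 yields RMSEA 0.000
        assert rmsea(8.686, 19, 20) == 0.0

    def test_cfi_one_when_model_beats_its_df(self):
        assert cfi(8.686, 19, 350.0, 45) == 1.0

    def test_cfi_interior_value(self):
        assert cfi(40.0, 19, 250.0, 45) == pytest.approx(1 - 21.0 / 205.0)

    def test_gfi_perfect_when_implied_equals_sample(self, rng):
        L = rng.normal(size=(4, 4))
        S = L @ L.T + 0.5 * np.eye(4)
        assert gfi(S, S) == pytest.approx(1.0)

    def test_rmsea_undefined_at_zero_df(self):
        assert np.isnan(rmsea(0.0, 0, 20))

    def test_baseline_is_independence_model(self, rng):
        X = rng.normal(size=(200, 3)) @ np.array(
            [[1.0, 0.0, 0.0], [0.6, 0.8, 0.0], [0.3, 0.2, 0.9]]
        )
        moments = SampleMoments.from_observations(X)
        chi2_b, df_b = fit_baseline(moments)
        S = moments.S
        f_direct = ml_discrepancy(S, np.diag(np.diag(S)))
        assert chi2_b == pytest.approx((moments.N - 1) * f_direct)
        assert df_b == 3


class TestInformationCriteria:
    def test_zero_chi_square_zero_parameters(self):
        assert information_criteria(0.0, 0, 20) == (0.0, 0.0)

    def test_nested_difference_identity(self):
        a1, b1 = information_criteria(30.0, 10, 50)
        a2, b2 = information_criteria(22.0, 13, 50)
        assert a2 - a1 == pytest.approx((22.0 - 30.0) + 2 * 3)
        assert b2 - b1 == pytest.approx((22.0 - 30.0) + 3 * np.log(50))

    def test_sign_agrees_with_likelihood_based_aic(self, rng):
        # independent oracle: Gaussian log-likelihoods of the saturated and
        # independence models computed directly from the data
        X = rng.normal(size=(150, 4)) @ (np.eye(4) + 0.5 * np.tril(np.ones((4, 4)), -1))
        n, p = X.shape
        Xc = X - X.mean(0)
        S_ml = Xc.T @ Xc / n

        def loglik(sigma):
            return -0.5 * n * (
                p * np.log(2 * np.pi)
                + np.linalg.slogdet(sigma)[1]
                + np.trace(S_ml @ np.linalg.inv(sigma))
            )

        t_sat = p * (p + 1) // 2
        aic_lik_sat = -2 * loglik(S_ml) + 2 * t_sat
        aic_lik_ind = -2 * loglik(np.diag(np.diag(S_ml))) + 2 * p

        moments = SampleMoments.from_observations(X)
        chi2_b, _ = fit_baseline(moments)
        aic_sat, _ = information_criteria(0.0, t_sat, n)
        aic_ind, _ = information_criteria(chi2_b, p, n)
        assert np.sign(aic_ind - aic_sat) == np.sign(aic_lik_ind - aic_lik_sat)
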