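"""Sweep operator, incomplete-data EM, conditional draws, and imputation."""

import numpy as np
import pytest
from scipy import optimize, stats

from embimpute import (
    EMConfig,
    ImputationParams,
    SyntheticConfig,
    apply_transform,
    bootstrap_em,
    conditional_draw,
    em_fit,
    generate,
    impute,
    inverse_transform,
    mcar_mask,
    reverse_sweep,
    sweep,
)
from embimpute.em_core import MVNParams
from embimpute.errors import (
    DegenerateDataError,
    SingularMatrixError,
    ValidationError,
)


def _random_psd(rng, p):
    a = rng.normal(size=(p, p))
    return a @ a.T + p * np.eye(p)


class TestSweep:
    def test_scalar_closed_form(self):
        np.testing.assert_allclose(sweep(np.array([[2.0]]), 0), [[-0.5]])

    @pytest.mark.parametrize("p", [2, 3, 4, 6, 8])
    def test_all_pivots_equal_negated_inverse(self, p):
        rng = np.random.default_rng(p)
        for _ in range(5):
            a = _random_psd(rng, p)
            b = a.copy()
            for k in range(p):
                b = sweep(b, k)
            np.testing.assert_allclose(b, -np.linalg.inv(a), rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("p", [2, 5, 8])
    def test_reverse_sweep_is_inverse(self, p):
        rng = np.random.default_rng(100 + p)
        a = _random_psd(rng, p)
        for k in range(p):
            np.testing.assert_allclose(reverse_sweep(sweep(a, k), k), a, atol=1e-10)

    def test_result_stays_symmetric(self):
        a = _random_psd(np.random.default_rng(0), 5)
        b = sweep(a, 2)
        np.testing.assert_allclose(b, b.T, atol=1e-12)

    def test_zero_pivot_names_index(self):
        a = np.eye(3)
        a[1, 1] = 0.0
        with pytest.raises(SingularMatrixError) as err:
            sweep(a, 1)
        assert err.value.index == 1


class TestTransforms:
    @pytest.mark.parametrize(
        "kind,values",
        [("sqrt", [0.0, 9.0, 2.5]), ("log", [0.5, 2.0, 40.0]), ("none", [-1.0, 3.0])],
    )
    def test_round_trip(self, kind, values):
        x = np.array(values)
        np.testing.assert_allclose(
            inverse_transform(apply_transform(x, kind), kind), x, rtol=1e-12
        )

    def test_sqrt_example(self):
        assert apply_transform(np.array([9.0]), "sqrt")[0] == 3.0

    def test_domain_violations(self):
        with pytest.raises(ValidationError):
            apply_transform(np.array([-1.0]), "sqrt")
        with pytest.raises(ValidationError):
            apply_transform(np.array([0.0]), "log")


class TestEMFit:
    def test_complete_data_is_mle_in_one_iteration(self, mvn_matrix):
        fit = em_fit(mvn_matrix, EMConfig())
        np.testing.assert_allclose(fit.mu, mvn_matrix.mean(axis=0), rtol=1e-10)
        np.testing.assert_allclose(
            fit.sigma, np.cov(mvn_matrix, rowvar=False, bias=True), rtol=1e-8
        )
        assert fit.diagnostics.n_iter == 1
        ll = stats.multivariate_normal.logpdf(mvn_matrix, fit.mu, fit.sigma).sum()
        assert abs(fit.loglik - ll) < 1e-6

    def test_bivariate_monotone_matches_factored_mle(self):
        # oracle: factor the likelihood as f(x) * f(y|x); each piece has a
        # closed-form MLE (marginal moments of x, complete-case regression)
        rng = np.random.default_rng(11)
        n, nc = 90, 55
        x = rng.normal(2.0, 1.5, n)
        y = 1.0 + 0.8 * x + rng.normal(0.0, 0.7, n)
        y[nc:] = np.nan
        fit = em_fit(np.column_stack([x, y]), EMConfig(tol=1e-10, max_iter=5000))

        mx, sxx = x.mean(), x.var()
        xc, yc = x[:nc], y[:nc]
        beta = np.cov(xc, yc, bias=True)[0, 1] / xc.var()
        alpha = yc.mean() - beta * xc.mean()
        sres = np.mean((yc - alpha - beta * xc) ** 2)
        expected = [mx, alpha + beta * mx, sxx, sres + beta**2 * sxx, beta * sxx]
        got = [fit.mu[0], fit.mu[1], fit.sigma[0, 0], fit.sigma[1, 1], fit.sigma[0, 1]]
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_mcar_loglik_matches_direct_maximization(self):
        # oracle: numerically maximize the observed-data likelihood over
        # (mu, chol(Sigma)) with a generic optimizer
        rng = np.random.default_rng(5)
        cov = _random_psd(rng, 3) / 3
        X = rng.multivariate_normal([0.5, -1.0, 2.0], cov, size=30)
        X[rng.random(X.shape) < 0.2] = np.nan
        X[0] = [0.1, -0.8, 1.9]  # keep at least one complete row
        fit = em_fit(X, EMConfig(tol=1e-12, max_iter=10_000))

        def negll(theta):
            mu = theta[:3]
            L = np.zeros((3, 3))
            L[np.tril_indices(3)] = theta[3:]
            sigma = L @ L.T
            ll = 0.0
            for row in X:
                o = ~np.isnan(row)
                if not o.any():
                    continue  # a fully missing row carries no information
                sub = sigma[np.ix_(o, o)]
                try:
                    ll += stats.multivariate_normal.logpdf(row[o], mu[o], sub)
                except np.linalg.LinAlgError:
                    return 1e12
            return -ll

        L0 = np.linalg.cholesky(fit.sigma + 1e-6 * np.eye(3))
        x0 = np.concatenate([fit.mu, L0[np.tril_indices(3)]])
        x0 = x0 + 0.05 * rng.normal(size=x0.size)  # start away from the EM answer
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"maxiter": 20_000, "fatol": 1e-10, "xatol": 1e-8})
        assert fit.loglik >= -res.fun - 1e-6

    @pytest.mark.parametrize("init", ["listwise_deletion", "identity"])
    def test_loglik_monotone_and_init_irrelevant(self, init):
        rng = np.random.default_rng(9)
        X = rng.multivariate_normal([0, 0, 0], _random_psd(rng, 3), size=80)
        X[rng.random(X.shape) < 0.25] = np.nan
        fit = em_fit(X, EMConfig(init=init, tol=1e-8, max_iter=5000))
        trace = np.array(fit.diagnostics.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()
        # both starting points reach the same stationary point
        other = em_fit(X, EMConfig(init="identity", tol=1e-8, max_iter=5000))
        np.testing.assert_allclose(fit.mu, other.mu, atol=1e-4)

    def test_too_few_observations_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, 1.0]])
        with pytest.raises(DegenerateDataError):
            em_fit(X)


class TestConditionalDraw:
    def test_diagonal_covariance_ignores_observed(self):
        pars = MVNParams(np.array([1.0, 2.0]), np.diag([4.0, 9.0]), 0.0)
        rng = np.random.default_rng(0)
        draws = np.array(
            [conditional_draw(np.array([100.0, np.nan]), pars, rng)[1] for _ in range(4000)]
        )
        assert abs(draws.mean() - 2.0) < 3 * 3.0 / np.sqrt(4000)

    def test_bivariate_regression_mean(self):
        rho, s1, s2 = 0.6, 2.0, 5.0
        sigma = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
        pars = MVNParams(np.array([1.0, -1.0]), sigma, 0.0)
        rng = np.random.default_rng(1)
        x1 = 3.0
        expected = -1.0 + rho * (s2 / s1) * (x1 - 1.0)
        draws = np.array(
            [conditional_draw(np.array([x1, np.nan]), pars, rng)[1] for _ in range(6000)]
        )
        cond_sd = s2 * np.sqrt(1 - rho**2)
        assert abs(draws.mean() - expected) < 4 * cond_sd / np.sqrt(6000)

    def test_monte_carlo_moments_match_closed_form(self):
        rng = np.random.default_rng(3)
        sigma = _random_psd(rng, 3)
        mu = np.array([1.0, -2.0, 0.5])
        pars = MVNParams(mu, sigma, 0.0)
        row = np.array([0.7, np.nan, np.nan])
        n = 50_000
        draws = np.array([conditional_draw(row, pars, rng)[1:] for _ in range(n)])
        soo = sigma[0, 0]
        cmean = mu[1:] + sigma[1:, 0] * (0.7 - mu[0]) / soo
        ccov = sigma[1:, 1:] - np.outer(sigma[1:, 0], sigma[0, 1:]) / soo
        np.testing.assert_allclose(
            draws.mean(axis=0), cmean, atol=4 * np.sqrt(ccov.diagonal().max() / n)
        )
        np.testing.assert_allclose(
            np.cov(draws, rowvar=False), ccov, rtol=0.06, atol=0.06 * np.abs(ccov).max()
        )

    def test_observed_entries_untouched(self):
        pars = MVNParams(np.zeros(3), np.eye(3), 0.0)
        row = np.array([5.0, np.nan, -3.0])
        out = conditional_draw(row, pars, np.random.default_rng(0))
        assert out[0] == 5.0 and out[2] == -3.0 and not np.isnan(out[1])


class TestBootstrap:
    def test_identity_resample_equals_em_fit(self, mvn_matrix, monkeypatch):
        class FakeRng:
            def integers(self, low, high, size):
                return np.arange(size)

        boot = bootstrap_em(mvn_matrix, EMConfig(), FakeRng())
        fit = em_fit(mvn_matrix, EMConfig())
        np.testing.assert_allclose(boot.mu, fit.mu)
        np.testing.assert_allclose(boot.sigma, fit.sigma)

    def test_seeded_rng_reproducible(self, mvn_matrix):
        a = bootstrap_em(mvn_matrix, EMConfig(), np.random.default_rng(5))
        b = bootstrap_em(mvn_matrix, EMConfig(), np.random.default_rng(5))
        np.testing.assert_array_equal(a.mu, b.mu)

    def test_spread_shrinks_with_n(self):
        # bootstrap standard error of the mean should scale roughly 1/sqrt(n)
        rng = np.random.default_rng(2)
        cov = _random_psd(rng, 3)
        spreads = {}
        for n in (50, 500):
            X = rng.multivariate_normal([0, 0, 0], cov, size=n)
            mus = np.array(
                [bootstrap_em(X, EMConfig(), np.random.default_rng(1000 + b)).mu
                 for b in range(120)]
            )
            spreads[n] = mus.std(axis=0).mean()
        ratio = spreads[50] / spreads[500]
        assert 2.0 < ratio < 5.0  # ideal sqrt(10) ~ 3.16


@pytest.fixture(scope="module")
def masked_panel():
    ds = generate(SyntheticConfig(n_proteins=5, seed=31))
    masked, _ = mcar_mask(ds, 150, seed=17)
    return masked


class TestImpute:
    def test_m1_point_equals_single_draw(self, masked_panel):
        res = impute(masked_panel, ImputationParams(m=1, seed=3))
        np.testing.assert_array_equal(res.summary["median"], res.summary["min"])
        np.testing.assert_array_equal(res.summary["median"], res.summary["max"])

    def test_observed_cells_identical_across_completions(self, masked_panel):
        res = impute(masked_panel, ImputationParams(m=4, seed=3))
        obs = masked_panel.records["Value"].notna()
        for table in res.completed:
            np.testing.assert_array_equal(
                table.loc[obs, "Value"].to_numpy(),
                masked_panel.records.loc[obs, "Value"].to_numpy(),
            )

    def test_point_within_range(self, masked_panel):
        res = impute(masked_panel, ImputationParams(m=7, seed=5))
        assert (res.summary["median"] >= res.summary["min"]).all()
        assert (res.summary["median"] <= res.summary["max"]).all()

    def test_bit_reproducible(self, masked_panel):
        a = impute(masked_panel, ImputationParams(m=3, seed=9))
        b = impute(masked_panel, ImputationParams(m=3, seed=9))
        np.testing.assert_array_equal(a.summary["median"], b.summary["median"])
        for ta, tb in zip(a.completed, b.completed):
            np.testing.assert_array_equal(ta["Value"], tb["Value"])

    def test_beats_per_protein_mean_imputation(self, masked_panel):
        res = impute(masked_panel, ImputationParams(m=10, seed=13))
        s = res.summary
        rmse_emb = np.sqrt(np.mean((s["median"] - s["truth"]) ** 2))
        obs = masked_panel.records[masked_panel.records["Value"].notna()]
        means = obs.groupby("Protein")["Value"].mean()
        naive = s["Protein"].map(means)
        rmse_naive = np.sqrt(np.mean((naive - s["truth"]) ** 2))
        assert rmse_emb < rmse_naive

    def test_sqrt_transform_keeps_values_nonnegative(self, masked_panel):
        res = impute(
            masked_panel, ImputationParams(m=3, seed=5, transform={"*": "sqrt"})
        )
        assert (res.summary["min"] >= 0).all()

    def test_no_missing_cells_rejected(self):
        ds = generate(SyntheticConfig(n_proteins=2, seed=1))
        with pytest.raises(ValidationError):
            impute(ds, ImputationParams(m=1))
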