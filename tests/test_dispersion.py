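"""Overdispersion estimation: exact bundling, grid-search oracles,
Cox-Reid behavior, parameter recovery and the dispersion-mean trend."""

import numpy as np
import pytest

import gpcount as gp
from gpcount import (
    DesignSpec,
    bundle,
    estimate_theta,
    fit_gene,
    fit_trend,
    gene_loglik,
    moments_start,
)

THETA_FIXTURE = np.array([0.0, 12, 1, 7, 0, 9, 2, 15.0])


class TestBundle:
    def test_tabulation(self):
        b = bundle([0, 0, 0, 1], [2.0, 2.0, 2.0, 2.0])
        assert b.total == 4
        order = np.argsort(b.y)
        np.testing.assert_array_equal(b.y[order], [0, 1])
        np.testing.assert_array_equal(b.m[order], [3, 1])

    def test_dense_fallback_when_no_compression(self):
        y = np.arange(10.0)
        mu = np.linspace(1, 5, 10)
        b = bundle(y, mu)
        assert len(b.y) == 10
        np.testing.assert_array_equal(b.m, np.ones(10))

    @pytest.mark.parametrize("theta", [0.01, 0.1, 1.0])
    def test_bundled_equals_dense_likelihood(self, theta, rng):
        """The bundled evaluation is exact, not an approximation."""
        n = 1000
        group = np.repeat([0, 1], n // 2)
        mu = np.where(group == 0, 2.0, 5.0)
        y = rng.integers(0, 7, size=n).astype(float)
        b = bundle(y, mu)
        assert len(b.y) <= 7 * 2
        dense = gene_loglik(y, mu, theta)
        assert b.loglik(theta) == pytest.approx(dense, rel=1e-10)

    def test_multiplicities_sum_to_cells(self, rng):
        y = rng.integers(0, 4, 50).astype(float)
        mu = np.full(50, 3.0)
        b = bundle(y, mu)
        assert b.m.sum() == 50


class TestMomentsStart:
    def test_exact_fit_gives_zero(self):
        assert moments_start([3, 3, 3], [3.0, 3.0, 3.0]) == 0.0

    def test_direct_arithmetic(self):
        assert moments_start([0, 4], [2.0, 2.0]) == pytest.approx(0.5)

    def test_sanity_band_on_simulated_draws(self):
        rng = np.random.default_rng(5)
        mu = 8.0
        y = rng.poisson(rng.gamma(1 / 0.4, 0.4 * mu, size=100))
        t0 = moments_start(y, np.full(100, y.mean()))
        assert 0.1 <= t0 <= 1.2


class TestEstimateTheta:
    def test_underdispersed_hits_zero_boundary(self):
        y = np.array([5.0, 5, 5, 5])
        b = bundle(y, np.full(4, 5.0))
        th, ok = estimate_theta(b, cox_reid=False)
        assert th == 0.0 and ok

    def test_matches_grid_search_oracle(self):
        X = DesignSpec(np.ones((8, 1)))
        fit, _ = fit_gene(THETA_FIXTURE, X, cox_reid=False)
        b = bundle(THETA_FIXTURE, fit.mu)
        grid = np.exp(np.linspace(np.log(1e-8), np.log(1e6), 10_000))
        oracle = grid[int(np.argmax([b.loglik(t) for t in grid]))]
        th, _ = estimate_theta(b, X, cox_reid=False, mu_dense=fit.mu)
        assert th == pytest.approx(oracle, rel=5e-3)  # 3 significant digits

    def test_cox_reid_increases_theta_on_fixture(self):
        """The adjustment compensates the downward bias from estimating
        beta: both objectives evaluated on the same means."""
        X = DesignSpec(np.ones((8, 1)))
        fit, _ = fit_gene(THETA_FIXTURE, X, cox_reid=False)
        b = bundle(THETA_FIXTURE, fit.mu)
        th_plain, _ = estimate_theta(b, X, cox_reid=False, mu_dense=fit.mu)
        th_cr, _ = estimate_theta(b, X, cox_reid=True, mu_dense=fit.mu)
        assert th_cr >= th_plain

    def test_objective_at_least_moments_start(self):
        X = DesignSpec(np.ones((8, 1)))
        fit, _ = fit_gene(THETA_FIXTURE, X, cox_reid=False)
        b = bundle(THETA_FIXTURE, fit.mu)
        th, _ = estimate_theta(b, cox_reid=False)
        t0 = moments_start(THETA_FIXTURE, fit.mu)
        assert b.loglik(th) >= b.loglik(t0) - 1e-10

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 12, 40).astype(float)
        mu = np.full(40, y.mean())
        th1, _ = estimate_theta(bundle(y, mu), cox_reid=False)
        perm = rng.permutation(40)
        th2, _ = estimate_theta(bundle(y[perm], mu[perm]), cox_reid=False)
        assert th1 == pytest.approx(th2, rel=1e-9)


class TestFitGene:
    def test_zero_mode_equals_poisson_fit(self):
        y = np.array([1, 4, 0, 2, 6.0])
        X = DesignSpec(np.ones((5, 1)))
        fits = list(gp.fit_all_genes(iter([y[None, :].astype(int)]), X,
                                     np.ones(5), theta_mode="zero"))
        fit, th = fits[0]
        direct = gp.fit_beta(y, X, np.zeros(5), theta=0.0)
        assert th == 0.0
        np.testing.assert_allclose(fit.beta, direct.beta, rtol=1e-12)

    def test_single_gene_theta_recovery(self):
        """n=2000 intercept-only gene at theta=0.7, mu=8: the ML estimate
        lands within +-3 SE of the truth."""
        cfg = gp.SimConfig(n_genes=1, n_cells=2000,
                           beta=np.array([[np.log(8.0)]]),
                           design=np.ones((2000, 1)), theta=0.7, seed=21)
        counts, X, sf, _ = gp.simulate_counts(cfg)
        _, th = fit_gene(counts[0], DesignSpec(X))
        assert 0.55 <= th <= 0.85

    def test_joint_fit_attains_direct_search_likelihood(self, rng):
        """(beta, theta) from the alternating scheme is as good as a 2-d
        direct search, on random small instances."""
        from scipy import optimize

        X = DesignSpec(np.ones((30, 1)))
        for _ in range(25):
            theta_true = float(rng.uniform(0.05, 1.5))
            mu_true = float(rng.uniform(2, 20))
            y = rng.poisson(rng.gamma(1 / theta_true, theta_true * mu_true, 30))
            if np.all(y == 0):
                continue
            fit, th = fit_gene(y, X, cox_reid=False)
            attained = gene_loglik(y, fit.mu, th)

            def neg(params):
                b0, log_t = params
                mu = np.exp(np.clip(b0, -30, 30)) * np.ones(30)
                return -gene_loglik(y, mu, float(np.exp(log_t)))

            res = optimize.minimize(neg, [np.log(y.mean() + 0.5), 0.0],
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-9, "fatol": 1e-11,
                                             "maxiter": 4000})
            assert attained >= -res.fun - 1e-4

    def test_scale_consistency(self):
        """Doubling all size factors (and hence mu) leaves theta-hat within
        estimator noise: paired simulations drawn from the same stream."""
        X = DesignSpec(np.ones((500, 1)))
        thetas = []
        for scale in (1.0, 2.0):
            rng = np.random.default_rng(31)
            mu = scale * 6.0
            y = rng.poisson(rng.gamma(1 / 0.4, 0.4 * mu, 500))
            _, th = fit_gene(y, X, offsets=np.full(500, np.log(scale)))
            thetas.append(th)
        assert 0.7 <= thetas[1] / thetas[0] <= 1.4


class TestParameterRecovery:
    def test_median_theta_ratio_with_cox_reid(self):
        """300 genes x 500 cells over theta in {0.1, 0.5, 1}: the median of
        theta-hat / theta-true stays in [0.8, 1.2] with Cox-Reid on, and the
        unadjusted estimates sit systematically lower."""
        ratios_cr, ratios_plain = [], []
        X = DesignSpec(np.column_stack([np.ones(500),
                                        np.repeat([0.0, 1.0], 250)]),
                       ["Intercept", "group"])
        for i, theta in enumerate([0.1, 0.5, 1.0]):
            cfg = gp.SimConfig(
                n_genes=100, n_cells=500,
                beta=np.column_stack([np.full(100, np.log(6.0)),
                                      np.full(100, 0.3)]),
                design=X.X, theta=theta, seed=41 + i,
            )
            counts, _, sf, _ = gp.simulate_counts(cfg)
            for row in counts:
                _, th = fit_gene(row, X, cox_reid=True)
                ratios_cr.append(th / theta)
                _, th0 = fit_gene(row, X, cox_reid=False)
                ratios_plain.append(th0 / theta)
        med = float(np.median(ratios_cr))
        assert 0.8 <= med <= 1.2
        assert float(np.median(ratios_plain)) < med  # directional bias check


class TestFitTrend:
    def test_constant_theta_gives_constant_trend(self):
        trend = fit_trend(np.full(50, 0.3), np.linspace(1, 100, 50))
        np.testing.assert_allclose(trend, 0.3)

    def test_flat_relationship_recovered(self, rng):
        n = 300
        theta = rng.uniform(0.25, 0.35, n)
        means = np.exp(rng.uniform(0, 5, n))
        trend = fit_trend(theta, means)
        assert np.max(np.abs(trend - 0.3)) < 0.1  # small vs theta spread

    def test_monotone_relationship_gives_monotone_trend(self):
        n = 200
        means = np.exp(np.linspace(0, 5, n))
        theta = 0.1 + 0.2 * np.linspace(0, 5, n) / 5
        trend = fit_trend(theta, means)
        order = np.argsort(means)
        assert np.all(np.diff(trend[order]) >= -1e-12)

    def test_few_genes_constant_median_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            trend = fit_trend(np.array([0.2, 0.4, 0.6]), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(trend, 0.4)

    def test_strictly_positive_output(self):
        trend = fit_trend(np.zeros(40), np.linspace(1, 10, 40))
        assert np.all(trend >= 1e-8)
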