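"""IRLS coefficient estimation: closed forms, oracle equivalence,
monotone deviance, and chunking invariance."""

import numpy as np
import pytest
from scipy import optimize

import gpcount as gp
from gpcount import DesignSpec, fit_all_genes, fit_beta, gene_loglik, initialize_beta


def _one_hot_two_group(n_a, n_b):
    X = np.zeros((n_a + n_b, 2))
    X[:n_a, 0] = 1.0
    X[n_a:, 1] = 1.0
    return DesignSpec(X, ["a", "b"])


class TestDesignSpec:
    def test_rank_deficient_names_columns(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="collinear columns.*slope"):
            DesignSpec(X, ["int", "slope", "slope2"])

    def test_requires_residual_df(self):
        with pytest.raises(ValueError, match="residual"):
            DesignSpec(np.eye(3), ["a", "b", "c"])

    def test_formula_treatment_coding(self):
        import pandas as pd

        meta = pd.DataFrame({"grp": ["c", "t", "t", "c", "x"], "age": [1, 2, 3, 4, 5]})
        spec = gp.design_from_formula("~ grp + age", meta)
        assert spec.names == ["Intercept", "grp[t]", "grp[x]", "age"]
        np.testing.assert_array_equal(spec.X[:, 1], [0, 1, 1, 0, 0])
        np.testing.assert_array_equal(spec.X[:, 3], meta["age"])


class TestInitializeBeta:
    @pytest.mark.parametrize("y, expected", [([0, 0, 0], np.log(0.5)),
                                             ([3, 3, 3], np.log(3.5))])
    def test_intercept_only(self, y, expected):
        b = initialize_beta(y, np.ones((3, 1)), np.zeros(3))
        assert b[0] == pytest.approx(expected, rel=1e-12)

    def test_saturated_one_hot_matches_least_squares(self):
        y = np.array([1, 5, 0, 9])
        X = _one_hot_two_group(2, 2)
        s = np.array([1.0, 2.0, 1.0, 0.5])
        b = initialize_beta(y, X, np.log(s))
        z = np.log((y + 0.5) / s)
        assert b[0] == pytest.approx(z[:2].mean(), rel=1e-10)
        assert b[1] == pytest.approx(z[2:].mean(), rel=1e-10)


class TestFitBeta:
    @pytest.mark.parametrize("theta", [0.0, 0.7])
    def test_intercept_mle_is_log_mean(self, theta):
        """The GP score at an intercept-only design vanishes at mu = ybar
        for every theta."""
        fit = fit_beta([1, 2, 3], np.ones((3, 1)), theta=theta)
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-8)
        assert fit.converged

    def test_intercept_with_size_factors(self):
        fit = fit_beta([1, 2, 3], np.ones((3, 1)),
                       offsets=np.log([1.0, 1.0, 2.0]), theta=0.0)
        assert fit.beta[0] == pytest.approx(np.log(6 / 4), abs=1e-8)

    def test_one_hot_groups_recover_weighted_means_poisson(self):
        """For a partition design at theta=0 the fitted mu equals each
        group's size-factor-weighted mean count, exactly."""
        y = np.array([2, 4, 3, 10, 14, 12, 11])
        s = np.array([1.0, 2.0, 1.0, 1.0, 1.0, 2.0, 1.0])
        X = _one_hot_two_group(3, 4)
        fit = fit_beta(y, X, np.log(s), theta=0.0)
        mu_a = y[:3].sum() / s[:3].sum()
        mu_b = y[3:].sum() / s[3:].sum()
        np.testing.assert_allclose(fit.mu / s, np.r_[[mu_a] * 3, [mu_b] * 4],
                                   rtol=1e-8)

    def test_one_hot_groups_recover_means_overdispersed(self):
        """With unit size factors the NB score vanishes at the per-group
        sample means for any fixed theta."""
        y = np.array([2, 4, 3, 10, 14, 12, 11])
        X = _one_hot_two_group(3, 4)
        fit = fit_beta(y, X, theta=0.2)
        np.testing.assert_allclose(
            fit.mu, np.r_[[y[:3].mean()] * 3, [y[3:].mean()] * 4], rtol=1e-8
        )

    def test_fit_invariants(self):
        y = np.array([0, 3, 1, 8, 2, 5])
        X = DesignSpec(np.column_stack([np.ones(6), np.arange(6.0)]))
        s = np.array([0.8, 1.1, 1.0, 1.3, 0.9, 1.0])
        fit = fit_beta(y, X, np.log(s), theta=0.4)
        np.testing.assert_allclose(fit.mu, s * np.exp(X.X @ fit.beta), rtol=1e-12)
        assert fit.deviance == pytest.approx(
            float(np.sum(gp.gp_unit_deviance(y, fit.mu, 0.4))), rel=1e-12
        )
        assert fit.df_residual == 4

    def test_deviance_non_increasing_over_iterations(self, rng):
        for _ in range(10):
            n = 25
            X = DesignSpec(np.column_stack([np.ones(n), rng.normal(size=n)]))
            y = rng.poisson(np.exp(1.0 + 0.5 * X.X[:, 1]))
            fit = fit_beta(y, X, theta=0.3)
            trace = np.array(fit.dev_trace)
            assert np.all(np.diff(trace) <= 1e-10)

    def test_size_factor_equivariance(self):
        """Scaling all size factors by k shifts only the intercept by -log k."""
        y = np.array([3, 0, 7, 2, 9, 4])
        X = DesignSpec(np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1.0]]))
        s = np.array([1.0, 0.7, 1.2, 0.9, 1.4, 1.0])
        f1 = fit_beta(y, X, np.log(s), theta=0.3)
        f2 = fit_beta(y, X, np.log(3.0 * s), theta=0.3)
        assert f2.beta[0] - f1.beta[0] == pytest.approx(-np.log(3.0), abs=1e-8)
        assert f2.beta[1] == pytest.approx(f1.beta[1], abs=1e-8)

    def test_all_zero_gene_short_circuit(self):
        fit = fit_beta([0, 0, 0, 0], np.ones((4, 1)), theta=0.5)
        assert fit.all_zero and fit.converged
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)
        assert np.all(fit.mu < 1e-12)

    def test_oracle_equivalence_direct_maximization(self, rng):
        """beta-hat matches derivative-free likelihood maximization on
        random small instances (<= 2 coefficients)."""
        worst = 0.0
        for _ in range(50):
            n = rng.integers(10, 25)
            p = rng.integers(1, 3)
            cols = [np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)]
            X = DesignSpec(np.column_stack(cols))
            beta_true = rng.normal(1.0, 0.5, p)
            theta = float(rng.uniform(0.0, 1.0))
            y = rng.poisson(np.exp(np.clip(X.X @ beta_true, -5, 5)))
            if np.all(y == 0):
                continue
            fit = fit_beta(y, X, theta=theta)

            def negll(b):
                mu = np.exp(np.clip(X.X @ b, -30, 30))
                return -gene_loglik(y, mu, theta)

            res = optimize.minimize(negll, fit.beta + 0.3, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10,
                                             "maxiter": 5000})
            worst = max(worst, float(np.max(np.abs(fit.beta - res.x))))
        assert worst < 1e-4

    def test_nonfinite_counts_error(self):
        with pytest.raises(ValueError):
            fit_beta([1.0, np.nan, 2.0], np.ones((3, 1)))


class TestFitAllGenes:
    def test_single_gene_equals_fit_beta(self):
        y = np.array([[0, 3, 1, 8, 2]])
        X = DesignSpec(np.ones((5, 1)))
        sf = np.ones(5)
        (fit, th), = list(fit_all_genes(iter([y]), X, sf, theta_mode="zero"))
        direct = fit_beta(y[0], X, np.zeros(5), theta=0.0)
        np.testing.assert_allclose(fit.beta, direct.beta, rtol=1e-12)
        assert th == 0.0

    @pytest.mark.parametrize("chunk_size", [1, 7, 20])
    def test_chunking_invariance(self, chunk_size, rng):
        counts = rng.poisson(5, size=(20, 15))
        X = DesignSpec(np.ones((15, 1)))
        sf = np.exp(rng.normal(0, 0.2, 15))

        def chunks(size):
            for g0 in range(0, 20, size):
                yield counts[g0 : g0 + size]

        ref = [f.beta for f, _ in
               fit_all_genes(chunks(20), X, sf, theta_mode="estimate")]
        out = [f.beta for f, _ in
               fit_all_genes(chunks(chunk_size), X, sf, theta_mode="estimate")]
        np.testing.assert_allclose(np.array(out), np.array(ref), atol=1e-10)

    def test_fixed_vector_beta_recovery(self):
        """Simulated matrix at known theta: intercept errors stay within
        3 standard errors from the observed Fisher information."""
        n_genes, n_cells, theta = 200, 300, 0.5
        cfg = gp.SimConfig(
            n_genes=n_genes, n_cells=n_cells,
            beta=np.full((n_genes, 1), np.log(8.0)),
            design=np.ones((n_cells, 1)), theta=theta, seed=11,
        )
        counts, X, sf, truth = gp.simulate_counts(cfg)
        fits = list(fit_all_genes(iter([counts]), DesignSpec(X), sf,
                                  theta_mode="fixed-vector",
                                  theta_values=np.full(n_genes, theta)))
        b0 = np.array([f.beta[0] for f, _ in fits])
        # observed information for the intercept: sum mu/(1+theta mu)
        se = np.array([
            1.0 / np.sqrt(np.sum(f.mu / (1 + theta * f.mu))) for f, _ in fits
        ])
        mae = np.mean(np.abs(b0 - np.log(8.0)))
        assert mae < 3.0 * np.mean(se)

    def test_dimension_mismatch_errors(self):
        X = DesignSpec(np.ones((5, 1)))
        with pytest.raises(ValueError, match="chunk"):
            list(fit_all_genes(iter([np.ones((2, 4), dtype=int)]), X, np.ones(5)))
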