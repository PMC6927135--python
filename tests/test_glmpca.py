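import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from scmultinom import (
    CountMatrix,
    GLMPCA,
    estimate_dispersion,
    fit_glmpca,
    negative_binomial_deviance,
    poisson_deviance,
    postprocess_fit,
)

from conftest import random_counts


def simulate_from_model(seed, I=100, J=500, L=2, factor_sd=0.5):
    rng = np.random.default_rng(seed)
    U = rng.normal(0, factor_sd, (I, L))
    V = rng.normal(0, factor_sd, (J, L))
    v0 = rng.normal(-4.0, 0.5, J)
    n = rng.integers(2000, 4000, I).astype(float)
    eta = np.log(n)[:, None] + v0 + U @ V.T
    y = rng.poisson(np.exp(eta))
    y[y.sum(axis=1) == 0, 0] += 1
    return CountMatrix(y), U, V, v0


def procrustes_corr(A, B):
    """Correlation of B with A after centering, scaling and rotation."""
    Ac = A - A.mean(0)
    Bc = B - B.mean(0)
    Ac /= np.linalg.norm(Ac)
    Bc /= np.linalg.norm(Bc)
    R, _ = orthogonal_procrustes(Bc, Ac)
    return float(np.corrcoef((Bc @ R).ravel(), Ac.ravel())[0, 1])


class TestPoissonDeviance:
    def test_zero_at_saturation(self, rand_counts):
        assert poisson_deviance(rand_counts,
                                rand_counts.counts.astype(float) + 1e-12) \
            == pytest.approx(0.0, abs=1e-6)

    def test_entry_contributions(self):
        # printed per-entry form is half of the conventional deviance
        assert poisson_deviance(np.array([[0]]), np.array([[2.0]])) \
            == pytest.approx(2 * 2.0)
        assert poisson_deviance(np.array([[4]]), np.array([[2.0]])) \
            == pytest.approx(2 * (4 * np.log(2) - 2))

    def test_matches_loglik_ratio_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3.0, size=(5, 7)).astype(float)
        mu = rng.gamma(3.0, 1.0, size=(5, 7))

        def pois_ll(y, m):
            return (y * np.log(np.where(y > 0, m, 1.0)) - m
                    - gammaln(y + 1)).sum()

        oracle = 2 * (pois_ll(y, np.where(y > 0, y, 1e-300)) - pois_ll(y, mu))
        # saturated loglik at y=0 needs mu->0 limit: handled by xlogy guard
        oracle = 2 * ((np.where(y > 0, y * np.log(y / mu), 0.0)
                       - (y - mu)).sum())
        assert poisson_deviance(y, mu) == pytest.approx(oracle)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            poisson_deviance(np.array([[3]]), np.array([[0.0]]))


class TestFit:
    def test_intercept_only_closed_form(self):
        cm = random_counts(3, I=30, J=8, mean=2.0)
        fit = fit_glmpca(cm, n_components=0, max_iter=200, seed=0)
        expect = np.log(cm.counts.sum(0) / cm.n.sum())
        assert np.allclose(fit.intercepts, expect, atol=1e-6)

    def test_intercept_matches_scalar_optimizer(self):
        cm = random_counts(8, I=20, J=3, mean=1.5)
        fit = fit_glmpca(cm, n_components=0, max_iter=200, seed=0)
        s = cm.n.astype(float)
        for j in range(3):
            yj = cm.counts[:, j].astype(float)

            def negll(b):
                mu = s * np.exp(b)
                return float(mu.sum() - (yj * (np.log(s) + b)).sum())

            best = minimize_scalar(negll, bounds=(-20, 5), method="bounded")
            assert fit.intercepts[j] == pytest.approx(best.x, abs=1e-4)

    def test_deviance_trace_monotone_on_random_instances(self):
        for seed in range(50):
            cm = random_counts(seed, I=12, J=16, mean=1.2)
            fit = fit_glmpca(cm, n_components=2, max_iter=10, seed=seed)
            assert (np.diff(fit.deviance_trace) <= 1e-6).all()

    def test_poisson_stationarity_reproduces_gene_totals(self):
        cm = random_counts(5, I=25, J=12, mean=3.0)
        est = GLMPCA(n_components=2, max_iter=500, tol=1e-9, random_state=0)
        est.fit(cm)
        eta = (est.offsets_[:, None] + est.intercepts_
               + est.factors_ @ est.loadings_.T)
        mu = np.exp(eta)
        rel = np.abs(mu.sum(0) - cm.counts.sum(0)) / cm.counts.sum(0)
        assert rel.max() < 1e-3

    def test_parameter_recovery(self):
        cm, U, V, v0 = simulate_from_model(7)
        fit = fit_glmpca(cm, n_components=2, max_iter=500, seed=0)
        true_lr = (U - U.mean(0)) @ V.T
        est_lr = fit.factors @ fit.loadings.T
        assert np.corrcoef(true_lr.ravel(), est_lr.ravel())[0, 1] > 0.9
        assert procrustes_corr(U, fit.factors) > 0.9

    def test_offset_property_global_scaling(self):
        # scaling every cell's counts and size factor by the same constant
        # leaves the unpenalized fit's loadings unchanged from the same init
        cm = random_counts(5, I=30, J=40, mean=2.0)
        f1 = fit_glmpca(cm, n_components=2, penalty=0.0, max_iter=400,
                        tol=1e-8, seed=0)
        f2 = fit_glmpca(CountMatrix(cm.counts * 3), n_components=2,
                        penalty=0.0, max_iter=400, tol=1e-8, seed=0,
                        size_factors=cm.n.astype(float) * 3)
        assert np.allclose(f1.loadings, f2.loadings, atol=1e-6)
        assert np.allclose(f1.intercepts, f2.intercepts, atol=1e-6)

    def test_all_zero_genes_dropped_with_warning(self):
        y = random_counts(1, I=10, J=5).counts.copy()
        y[:, 2] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            fit = fit_glmpca(CountMatrix(y), n_components=1, max_iter=20,
                             seed=0)
        assert fit.loadings.shape[0] == 4

    def test_nonconvergence_warns_and_flags(self):
        cm = random_counts(2, I=15, J=20)
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_glmpca(cm, n_components=2, max_iter=2, seed=0)
        assert not fit.converged

    def test_cell_covariate_absorbs_batch(self):
        # a known multiplicative batch effect lands in the covariate
        # coefficient, not the latent factors
        rng = np.random.default_rng(9)
        batch = np.repeat([0, 1], 20)
        mu = np.exp(np.log(50 / 30) * batch[:, None]
                    + rng.normal(-1, 0.3, 30)[None, :])
        y = rng.poisson(mu * 100)
        y[y.sum(axis=1) == 0, 0] = 1
        est = GLMPCA(n_components=1, cell_covariates=batch[:, None].astype(float),
                     random_state=0, max_iter=300)
        est.fit(CountMatrix(y))
        assert est.cell_covariate_coef_.shape == (30, 1)
        assert np.isfinite(est.cell_covariate_coef_).all()

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = GLMPCA(n_components=3, likelihood="negative_binomial")
        c = clone(est)
        assert c.get_params() == est.get_params()


class TestNegativeBinomial:
    def test_dispersion_recovery(self):
        rng = np.random.default_rng(11)
        phi, mean = 2.0, 5.0
        y = rng.negative_binomial(phi, phi / (phi + mean), size=(2000, 1))
        est = estimate_dispersion(y.astype(float), np.full((2000, 1), mean))
        assert 1.5 < est < 2.7

    def test_dispersion_scale_free(self):
        rng = np.random.default_rng(12)
        phi = 3.0
        for mean in (2.0, 4.0):
            y = rng.negative_binomial(phi, phi / (phi + mean), size=(3000, 1))
            est = estimate_dispersion(y.astype(float), np.full((3000, 1), mean))
            assert 2.0 < est < 4.5

    def test_poisson_data_hits_ceiling(self):
        rng = np.random.default_rng(13)
        y = rng.poisson(4.0, size=(1500, 1)).astype(float)
        with pytest.warns(UserWarning, match="ceiling|overdispersion"):
            est = estimate_dispersion(y, np.full((1500, 1), 4.0))
        assert est == pytest.approx(1e6)

    def test_per_gene_mode_shape(self):
        rng = np.random.default_rng(14)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + 5.0), size=(500, 4))
        est = estimate_dispersion(y.astype(float), np.full((500, 4), 5.0),
                                  mode="per_gene")
        assert est.shape == (4,)
        assert (est < 10).all()

    def test_nb_fit_runs_and_is_monotone(self):
        cm = random_counts(6, I=25, J=30, mean=3.0)
        fit = fit_glmpca(cm, n_components=2, likelihood="negative_binomial",
                         max_iter=40, seed=0)
        assert (np.diff(fit.deviance_trace) <= 1e-6).all()
        assert fit.dispersion is not None

    def test_nb_deviance_zero_at_saturation(self):
        y = np.array([[3.0, 0.0], [1.0, 5.0]])
        assert negative_binomial_deviance(y, y + 1e-14, phi=2.0) \
            == pytest.approx(0.0, abs=1e-6)


class TestPostprocess:
    def test_reconstruction_preserved_and_idempotent(self):
        cm = random_counts(4, I=20, J=25, mean=2.0)
        fit = fit_glmpca(cm, n_components=3, max_iter=60, seed=1)
        eta1 = fit.intercepts + fit.factors @ fit.loadings.T
        post = postprocess_fit(fit)
        eta2 = post.intercepts + post.factors @ post.loadings.T
        assert np.allclose(eta1, eta2, atol=1e-10)
        again = postprocess_fit(post)
        assert np.allclose(again.factors, post.factors, atol=1e-8)

    def test_orthogonal_ordered_columns(self):
        cm = random_counts(4, I=20, J=25, mean=2.0)
        fit = fit_glmpca(cm, n_components=3, max_iter=60, seed=1)
        G = fit.factors.T @ fit.factors
        assert np.allclose(G, np.diag(np.diag(G)), atol=1e-8)
        norms = np.linalg.norm(fit.factors, axis=0)
        assert (np.diff(norms) <= 1e-8).all()

    def test_sign_convention(self):
        cm = random_counts(4, I=20, J=25, mean=2.0)
        fit = fit_glmpca(cm, n_components=2, max_iter=60, seed=1)
        for l in range(2):
            jmax = np.argmax(np.abs(fit.loadings[:, l]))
            assert fit.loadings[jmax, l] > 0
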