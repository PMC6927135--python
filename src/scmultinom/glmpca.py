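"""GLM-PCA: generalized principal component analysis for count matrices.

PCA maximizes a Gaussian likelihood of the (transformed) data around a
low-rank mean. GLM-PCA keeps the low-rank idea but swaps the Gaussian for a
count likelihood acting through a log link:

    y_ij ~ Poi(mu_ij)   or   y_ij ~ NB(mu_ij; phi),
    log mu_ij = log s_i + v_j1 + sum_l u_il v_jl

with per-cell size factors s_i entering as offsets (so raw counts are
modeled directly, with no normalization step), a gene-specific intercept
induced by constraining the first factor element to 1, optional cell- and
gene-level covariates, and a small L2 penalty on the latent blocks for
numerical stability. The Poisson likelihood approximates the multinomial
sampling model; the negative binomial approximates the overdispersed
Dirichlet-multinomial.

Optimization is blockwise Fisher scoring over latent dimensions: for each
dimension the gene loadings are updated holding factors fixed (independent
one-parameter GLM steps per gene) and then the cell factors holding
loadings fixed. Steps that would increase the penalized deviance are halved
(up to 10 times) and reverted if still failing, so the recorded deviance
trace is monotone non-increasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .count_model import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GLMPCA",
    "GlmpcaFit",
    "fit_glmpca",
    "poisson_deviance",
    "negative_binomial_deviance",
    "estimate_dispersion",
]

_PHI_CEILING = 1e6
_ETA_MAX = 80.0  # exp() stays finite in float64


def _xlogy(x: np.ndarray, ratio_num: np.ndarray, ratio_den) -> np.ndarray:
    """x * log(num/den) with the 0*log(0) = 0 convention on x."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x > 0, x * np.log(np.where(x > 0, ratio_num, 1.0)
                                         / ratio_den), 0.0)
    return out


def _counts_of(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.counts.astype(float)
    return np.asarray(counts, dtype=float)


def poisson_deviance(counts, mu: np.ndarray) -> float:
    """Poisson deviance 2*sum[y log(y/mu) - (y - mu)].

    Twice the log-likelihood ratio of the saturated model to the fitted
    means; zero iff mu = y elementwise.
    """
    y = _counts_of(counts)
    mu = np.asarray(mu, dtype=float)
    if ((mu <= 0) & (y > 0)).any():
        raise ValueError("mu must be positive wherever y > 0")
    return float(2.0 * (_xlogy(y, y, mu) - (y - mu)).sum())


def negative_binomial_deviance(counts, mu: np.ndarray, phi: float) -> float:
    """NB deviance 2*sum[y log(y/mu) - (y+phi) log((y+phi)/(mu+phi))]."""
    y = _counts_of(counts)
    mu = np.asarray(mu, dtype=float)
    if ((mu <= 0) & (y > 0)).any():
        raise ValueError("mu must be positive wherever y > 0")
    term = _xlogy(y, y, mu) - (y + phi) * np.log((y + phi) / (mu + phi))
    return float(2.0 * term.sum())


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    return float((gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
                  + phi * np.log(phi / (phi + mu))
                  + y * np.log(mu / (phi + mu) + 1e-300)).sum())


def estimate_dispersion(counts, mu: np.ndarray, mode: str = "shared"):
    """Maximum-likelihood NB shape phi at fixed means.

    Parameterization: var[y] = mu + mu^2/phi, so large phi is Poisson-like.
    Underdispersed data push phi to a ceiling of 1e6 (with a warning).
    ``mode='per_gene'`` returns a vector, one phi per column.
    """
    y = _counts_of(counts)
    mu = np.asarray(mu, dtype=float)

    def _fit_one(yv, muv):
        def negll(log_phi):
            return -_nb_loglik(yv, muv, np.exp(log_phi))

        res = minimize_scalar(negll, bounds=(np.log(1e-4), np.log(_PHI_CEILING)),
                              method="bounded", options={"xatol": 1e-6})
        # flat likelihood toward phi -> inf means no overdispersion at all
        if negll(np.log(_PHI_CEILING)) <= res.fun + 1e-4:
            return _PHI_CEILING
        return float(np.exp(res.x))

    if mode == "shared":
        phi = _fit_one(y, mu)
        if phi >= _PHI_CEILING * 0.99:
            warnings.warn("no overdispersion detected; phi capped at ceiling")
            phi = _PHI_CEILING
        return phi
    if mode == "per_gene":
        phis = np.array([_fit_one(y[:, j], mu[:, j]) for j in range(y.shape[1])])
        capped = phis >= _PHI_CEILING * 0.99
        if capped.any():
            warnings.warn(f"{int(capped.sum())} genes at phi ceiling "
                          "(no overdispersion)")
            phis[capped] = _PHI_CEILING
        return phis
    raise ValueError(f"mode must be 'shared' or 'per_gene', got {mode!r}")


@dataclass
class GlmpcaFit:
    """Fitted GLM-PCA decomposition (latent blocks only; covariates on the
    estimator)."""

    factors: np.ndarray          # cells x L
    loadings: np.ndarray         # genes x L
    intercepts: np.ndarray       # per-gene v_j1
    offsets: np.ndarray          # log s_i per cell
    dispersion: float | np.ndarray | None
    deviance_trace: np.ndarray
    converged: bool
    cell_ids: np.ndarray | None = None
    gene_ids: np.ndarray | None = None


class _State:
    """Dense working state: eta = offset + A @ B.T over all columns."""

    def __init__(self, A: np.ndarray, B: np.ndarray, offsets: np.ndarray):
        self.A = A
        self.B = B
        self.offsets = offsets
        self.H = A @ B.T

    def mu(self) -> np.ndarray:
        eta = np.clip(self.offsets[:, None] + self.H, -_ETA_MAX, _ETA_MAX)
        return np.exp(eta)

    def rank1_update(self, col: int, side: str, delta: np.ndarray) -> None:
        if side == "B":
            self.H += np.outer(self.A[:, col], delta)
            self.B[:, col] += delta
        else:
            self.H += np.outer(delta, self.B[:, col])
            self.A[:, col] += delta


class GLMPCA(TransformerMixin, BaseEstimator):
    """Generalized PCA under a Poisson or negative-binomial likelihood.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent dimensions L (the gene intercept is extra and
        always present). 0 gives an intercept-only fit.
    likelihood : {'poisson', 'negative_binomial'}
        Poisson approximates the multinomial sampling model; negative
        binomial the overdispersed Dirichlet-multinomial.
    penalty : float, default 1.0
        L2 penalty lambda on the latent factor and loading blocks
        (intercepts and covariate coefficients are unpenalized).
    max_iter : int, default 1000
        Maximum number of full sweeps over all columns.
    tol : float, default 1e-4
        Convergence: relative change of penalized deviance per sweep.
    dispersion_mode : {'shared', 'per_gene'}
        How the NB shape is estimated (re-estimated every 5 sweeps).
    size_factors : array-like or None
        Per-cell offsets s_i; defaults to total UMI counts n_i.
    cell_covariates : (cells, p) array, optional
        Known per-cell regressors (e.g. one-hot batch with reference level
        dropped); each gets an unpenalized per-gene coefficient.
    gene_covariates : (genes, q) array, optional
        Known per-gene regressors; each gets an unpenalized per-cell
        coefficient.
    random_state : int, default 0
        Seed for factor/loading initialization.

    Attributes
    ----------
    factors_ : (cells, L) array
        Latent factors U, post-processed to orthogonal columns ordered by
        decreasing contribution, analogous to PC scores.
    loadings_ : (genes, L) array
        Latent loadings V.
    intercepts_ : (genes,) array
    deviance_trace_ : per-sweep penalized deviance (monotone non-increasing)
    dispersion_ : NB shape phi (None for Poisson)
    converged_ : bool
    """

    def __init__(self, n_components: int = 2, likelihood: str = "poisson",
                 penalty: float = 1.0, max_iter: int = 1000, tol: float = 1e-4,
                 dispersion_mode: str = "shared", size_factors=None,
                 cell_covariates=None, gene_covariates=None,
                 random_state: int = 0):
        self.n_components = n_components
        self.likelihood = likelihood
        self.penalty = penalty
        self.max_iter = max_iter
        self.tol = tol
        self.dispersion_mode = dispersion_mode
        self.size_factors = size_factors
        self.cell_covariates = cell_covariates
        self.gene_covariates = gene_covariates
        self.random_state = random_state

    # -- likelihood pieces ---------------------------------------------------

    def _deviance(self, y: np.ndarray, mu: np.ndarray, phi) -> float:
        if self.likelihood == "poisson":
            return float(2.0 * (_xlogy(y, y, mu) - (y - mu)).sum())
        term = _xlogy(y, y, mu) - (y + phi) * np.log((y + phi) / (mu + phi))
        return float(2.0 * term.sum())

    def _score_weight(self, y, mu, phi):
        """Score d(loglik)/d(eta) and expected information per entry."""
        if self.likelihood == "poisson":
            return y - mu, mu
        f = phi / (phi + mu)
        return (y - mu) * f, mu * f

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        counts = X if isinstance(X, CountMatrix) else CountMatrix(X)
        if self.n_components < 0:
            raise ValueError("n_components must be >= 0")
        if self.likelihood not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")

        gene_tot = counts.counts.sum(axis=0)
        if (gene_tot == 0).any():
            msg = (f"dropping {int((gene_tot == 0).sum())} all-zero genes "
                   "(log intercept undefined)")
            logger.warning(msg)
            warnings.warn(msg)
            counts = counts.subset_genes(gene_tot > 0)
        yv = counts.counts.astype(float)
        I, J = yv.shape
        L = self.n_components

        s = (counts.n.astype(float) if self.size_factors is None
             else np.asarray(self.size_factors, dtype=float))
        if s.shape != (I,) or (s <= 0).any():
            raise ValueError("size_factors must be positive, one per cell")
        offsets = np.log(s)

        Xc = (np.zeros((I, 0)) if self.cell_covariates is None
              else np.asarray(self.cell_covariates, dtype=float))
        Zg = (np.zeros((J, 0)) if self.gene_covariates is None
              else np.asarray(self.gene_covariates, dtype=float))
        p, q = Xc.shape[1], Zg.shape[1]

        # column layout: [intercept | cell covariates | gene covariates | latent]
        rng = np.random.default_rng(self.random_state)
        sd0 = 1e-2 / np.sqrt(max(L, 1))
        A = np.concatenate([
            np.ones((I, 1)), Xc, np.zeros((I, q)),
            rng.normal(0.0, sd0, (I, L))], axis=1)
        B = np.concatenate([
            np.log(yv.sum(axis=0) / s.sum())[:, None],
            np.zeros((J, p)), Zg,
            rng.normal(0.0, sd0, (J, L))], axis=1)
        n_cols = 1 + p + q + L
        latent = list(range(1 + p + q, n_cols))
        # which side of each column is free, and whether it is penalized
        upd_B = [True] * (1 + p) + [False] * q + [True] * L
        upd_A = [False] * (1 + p) + [True] * q + [True] * L
        pen = [0.0] * (1 + p + q) + [self.penalty] * L

        state = _State(A, B, offsets)
        phi = _PHI_CEILING if self.likelihood == "negative_binomial" else None

        def penalized(mu):
            d = self._deviance(yv, mu, phi)
            if latent:
                d += self.penalty * (float((A[:, latent] ** 2).sum())
                                     + float((B[:, latent] ** 2).sum()))
            return d

        dev = penalized(state.mu())
        trace = [dev]
        converged = False
        for sweep in range(self.max_iter):
            for col in range(n_cols):
                for side in ("B", "A"):
                    if side == "B" and not upd_B[col]:
                        continue
                    if side == "A" and not upd_A[col]:
                        continue
                    dev = self._update_column(state, yv, col, side, pen[col],
                                              phi, dev, penalized)
            if (self.likelihood == "negative_binomial"
                    and (sweep + 1) % 5 == 0):
                phi = estimate_dispersion(yv, state.mu(), self.dispersion_mode)
                dev = penalized(state.mu())
            if not np.isfinite(dev):
                raise FloatingPointError(
                    f"non-finite deviance at sweep {sweep + 1}")
            trace.append(dev)
            prev = trace[-2]
            if abs(prev - dev) / (0.1 + abs(prev)) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"GLM-PCA did not converge in {self.max_iter} sweeps")
        if self.likelihood == "negative_binomial":
            phi = estimate_dispersion(yv, state.mu(), self.dispersion_mode)

        U = A[:, latent].copy()
        V = B[:, latent].copy()
        v0 = B[:, 0].copy()
        U, V, v0 = _orthonormalize(U, V, v0)

        self.factors_ = U
        self.loadings_ = V
        self.intercepts_ = v0
        self.offsets_ = offsets
        self.dispersion_ = phi
        self.deviance_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.cell_ids_ = counts.cell_ids
        self.gene_ids_ = counts.gene_ids
        self.n_features_in_ = J
        self.cell_covariate_coef_ = B[:, 1:1 + p].copy()
        self.gene_covariate_coef_ = A[:, 1 + p:1 + p + q].copy()
        return self.factors_

    def _update_column(self, state, yv, col, side, lam, phi, dev, penalized):
        mu = state.mu()
        score, w = self._score_weight(yv, mu, phi)
        if side == "B":
            a = state.A[:, col]
            cur = state.B[:, col]
            grad = score.T @ a - lam * cur
            info = w.T @ (a ** 2) + lam
        else:
            b = state.B[:, col]
            cur = state.A[:, col]
            grad = score @ b - lam * cur
            info = w @ (b ** 2) + lam
        info = np.maximum(info, 1e-10)
        delta = grad / info
        step = 1.0
        for _ in range(11):
            state.rank1_update(col, side, step * delta)
            new_dev = penalized(state.mu())
            if new_dev <= dev + 1e-10:
                return new_dev
            state.rank1_update(col, side, -step * delta)  # revert
            step *= 0.5
        return dev  # no acceptable step; leave column unchanged

    def transform(self, X) -> np.ndarray:
        """Project new cells onto the fitted loadings (V, intercepts fixed).

        Runs damped Fisher scoring per cell on its factor vector; only
        sensible for Poisson fits without gene covariates.
        """
        check_is_fitted(self, "loadings_")
        counts = X if isinstance(X, CountMatrix) else CountMatrix(X)
        if counts.n_genes != self.n_features_in_:
            raise ValueError("gene set mismatch")
        yv = counts.counts.astype(float)
        offs = np.log(counts.n.astype(float))
        V, v0 = self.loadings_, self.intercepts_
        L = V.shape[1]
        U = np.zeros((yv.shape[0], L))
        phi = self.dispersion_
        for _ in range(50):
            eta = np.clip(offs[:, None] + v0[None, :] + U @ V.T,
                          -_ETA_MAX, _ETA_MAX)
            mu = np.exp(eta)
            score, w = self._score_weight(yv, mu, phi)
            grad = score @ V - self.penalty * U
            info = w @ (V ** 2) + self.penalty
            step = grad / np.maximum(info, 1e-10)
            U += step
            if np.abs(step).max() < 1e-6:
                break
        return U


def _orthonormalize(U, V, v0):
    """Identifiability post-processing; eta = v0 + U V' is unchanged.

    Centers the factor columns into the intercept, then rotates so factor
    columns are orthogonal and ordered by the singular values of the implied
    contribution, with a deterministic sign (largest-|loading| positive).
    """
    if U.shape[1] == 0:
        return U, V, v0
    m = U.mean(axis=0)
    v0 = v0 + V @ m
    Uc = U - m
    Qu, Ru = np.linalg.qr(Uc)
    Qv, Rv = np.linalg.qr(V)
    uu, ss, vvt = np.linalg.svd(Ru @ Rv.T)
    Unew = Qu @ (uu * ss)
    Vnew = Qv @ vvt.T
    for l in range(Vnew.shape[1]):
        jmax = np.argmax(np.abs(Vnew[:, l]))
        if Vnew[jmax, l] < 0:
            Vnew[:, l] *= -1
            Unew[:, l] *= -1
    return Unew, Vnew, v0


def postprocess_fit(fit: GlmpcaFit) -> GlmpcaFit:
    """Re-apply the identifiability normalization to a fit (idempotent)."""
    U, V, v0 = _orthonormalize(fit.factors.copy(), fit.loadings.copy(),
                               fit.intercepts.copy())
    return GlmpcaFit(U, V, v0, fit.offsets, fit.dispersion,
                     fit.deviance_trace, fit.converged, fit.cell_ids,
                     fit.gene_ids)


def fit_glmpca(counts, n_components: int = 2, likelihood: str = "poisson",
               penalty: float = 1.0, max_iter: int = 1000, tol: float = 1e-4,
               seed: int = 0, **kwargs) -> GlmpcaFit:
    """Functional wrapper around :class:`GLMPCA`; returns a :class:`GlmpcaFit`."""
    est = GLMPCA(n_components=n_components, likelihood=likelihood,
                 penalty=penalty, max_iter=max_iter, tol=tol,
                 random_state=seed, **kwargs)
    est.fit(counts)
    return GlmpcaFit(est.factors_, est.loadings_, est.intercepts_,
                     est.offsets_, est.dispersion_, est.deviance_trace_,
                     est.converged_, est.cell_ids_, est.gene_ids_)
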