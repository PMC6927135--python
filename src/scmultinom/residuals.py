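"""Null-model residual transforms for UMI counts.

Centering and scaling log-normalized expression to z-scores is exactly the
Pearson residual of a Gaussian null model of constant expression per gene.
Replacing that Gaussian null with the multinomial sampling model (via its
binomial marginals) yields deviance and Pearson residuals that account for
varying total counts per cell and need no pseudocount. PCA on these residual
matrices is a fast approximation to GLM-PCA on the raw counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .count_model import (
    CountMatrix,
    NormalizationConfig,
    NullFit,
    fit_null,
    log_cpm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResidualMatrix",
    "NullResiduals",
    "deviance_residuals",
    "pearson_residuals",
    "log_cpm_zscores",
    "standardize_residuals",
]


@dataclass
class ResidualMatrix:
    """Real-valued cells × genes residual matrix plus its generating null."""

    values: np.ndarray
    kind: str  # deviance | pearson | zscore
    null: NullFit | None
    standardized: bool
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _drop_genes(counts: CountMatrix, bad: np.ndarray, reason: str,
                strict: bool) -> CountMatrix:
    if not bad.any():
        return counts
    ids = list(counts.gene_ids[bad])
    if strict:
        raise ValueError(f"{reason}: {ids}")
    msg = f"dropping {int(bad.sum())} genes ({reason})"
    logger.warning(msg)
    warnings.warn(msg)
    return counts.subset_genes(~bad)


def _binomial_deviance_terms(y: np.ndarray, n: np.ndarray,
                             mu: np.ndarray) -> np.ndarray:
    """Per-entry 2*[y log(y/mu) + (n-y) log((n-y)/(n-mu))], 0*log0 = 0."""
    n = np.broadcast_to(n[:, None], y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        ny = n - y
        t2 = np.where(ny > 0, ny * np.log(np.where(ny > 0, ny, 1.0) / (n - mu)),
                      0.0)
    return 2.0 * (t1 + t2)


def deviance_residuals(counts: CountMatrix, strict: bool = False,
                       standardize: bool = False) -> ResidualMatrix:
    """Binomial-approximation deviance residuals under the pooled null.

    ``r_ij = sign(y - mu) * sqrt(2 y log(y/mu) + 2 (n-y) log((n-y)/(n-mu)))``
    with ``mu_ij = n_i * pi_hat_j``. The squared residuals of a gene sum to
    its binomial deviance. All-zero genes have no defined null mean and are
    dropped (error if ``strict``).
    """
    counts = _drop_genes(counts, counts.counts.sum(axis=0) == 0,
                         "all-zero genes have undefined null mean", strict)
    null = fit_null(counts)
    y = counts.counts.astype(float)
    dev = np.clip(_binomial_deviance_terms(y, counts.n.astype(float), null.mu),
                  0.0, None)
    r = np.sign(y - null.mu) * np.sqrt(dev)
    out = ResidualMatrix(r, "deviance", null, False, counts.cell_ids,
                         counts.gene_ids)
    return standardize_residuals(out) if standardize else out


def pearson_residuals(counts: CountMatrix, strict: bool = False,
                      standardize: bool = False) -> ResidualMatrix:
    """Binomial Pearson residuals ``(y - mu) / sqrt(mu - mu^2/n)`` under the
    pooled null."""
    counts = _drop_genes(counts, counts.counts.sum(axis=0) == 0,
                         "all-zero genes have undefined null mean", strict)
    null = fit_null(counts)
    n = counts.n.astype(float)[:, None]
    var = null.mu - null.mu ** 2 / n
    if (var <= 0).any():
        raise ValueError("degenerate binomial variance (mu = n); "
                         "a single gene carries a cell's entire count")
    r = (counts.counts - null.mu) / np.sqrt(var)
    out = ResidualMatrix(r, "pearson", null, False, counts.cell_ids,
                         counts.gene_ids)
    return standardize_residuals(out) if standardize else out


def log_cpm_zscores(counts: CountMatrix,
                    cfg: NormalizationConfig | None = None,
                    strict: bool = False) -> ResidualMatrix:
    """Gaussian-null residuals of log-CPM: per-gene z-scores.

    Each gene is centered and scaled by its MLE (1/I denominator) mean and
    standard deviation; zero-variance genes are dropped.
    """
    q = log_cpm(counts, cfg)
    sd = q.std(axis=0)  # ddof=0: Gaussian MLE
    bad = sd == 0
    if bad.any():
        counts = _drop_genes(counts, bad, "zero-variance genes", strict)
        q, sd = q[:, ~bad], sd[~bad]
    z = (q - q.mean(axis=0)) / sd
    return ResidualMatrix(z, "zscore", None, True, counts.cell_ids,
                          counts.gene_ids)


def standardize_residuals(res: ResidualMatrix,
                          strict: bool = False) -> ResidualMatrix:
    """Scale each gene's residuals to unit standard deviation (no centering)."""
    sd = res.values.std(axis=0)
    bad = sd == 0
    values, gene_ids = res.values, res.gene_ids
    if bad.any():
        if strict:
            raise ValueError(f"zero-sd genes: {list(gene_ids[bad])}")
        msg = f"dropping {int(bad.sum())} zero-sd genes before standardizing"
        logger.warning(msg)
        warnings.warn(msg)
        values, gene_ids, sd = values[:, ~bad], gene_ids[~bad], sd[~bad]
    return ResidualMatrix(values / sd, res.kind, res.null, True,
                          res.cell_ids, gene_ids)


_KINDS = {"deviance": deviance_residuals, "pearson": pearson_residuals}


class NullResiduals(TransformerMixin, BaseEstimator):
    """Transform raw UMI counts into null-model residuals.

    Fitting learns the pooled relative abundances ``pi_hat_j`` (and, for
    ``kind='zscore'``, per-gene log-CPM means and standard deviations) from
    the training counts; transforming applies the corresponding residual
    formula using each cell's own total count.

    Parameters
    ----------
    kind : {'deviance', 'pearson', 'zscore'}
        Residual family. ``deviance`` and ``pearson`` use the binomial
        approximation to the multinomial null; ``zscore`` is the classical
        Gaussian null on log-CPM.
    standardize : bool, default False
        Scale each gene's residuals to unit standard deviation (the
        standard deviations are learned at fit time).
    strict : bool, default False
        Raise instead of dropping uninformative genes (all-zero for the
        count nulls, zero-variance for z-scores).
    c, m : float
        Pseudocount and scale of the log-CPM transform (z-scores only).
    """

    def __init__(self, kind: str = "deviance", standardize: bool = False,
                 strict: bool = False, c: float = 1.0, m: float = 1e6):
        self.kind = kind
        self.standardize = standardize
        self.strict = strict
        self.c = c
        self.m = m

    def _as_counts(self, X) -> CountMatrix:
        if isinstance(X, CountMatrix):
            return X
        return CountMatrix(X)

    def fit(self, X, y=None):
        if self.kind not in ("deviance", "pearson", "zscore"):
            raise ValueError(f"unknown residual kind {self.kind!r}")
        counts = self._as_counts(X)
        res = self._compute(counts)
        self.n_features_in_ = counts.n_genes
        self.gene_ids_ = res.gene_ids
        self.keep_mask_ = np.isin(counts.gene_ids, res.gene_ids)
        if self.kind == "zscore":
            q = log_cpm(counts.subset_genes(self.keep_mask_),
                        NormalizationConfig(self.c, self.m))
            self.mean_, self.scale_ = q.mean(axis=0), q.std(axis=0)
        else:
            self.pi_ = res.null.pi_pooled
        if self.standardize:
            self.residual_scale_ = None  # set from training residuals below
            raw = res.values
            self.residual_scale_ = raw.std(axis=0)
        return self

    def _compute(self, counts: CountMatrix) -> ResidualMatrix:
        if self.kind == "zscore":
            return log_cpm_zscores(
                counts, NormalizationConfig(self.c, self.m), strict=self.strict)
        return _KINDS[self.kind](counts, strict=self.strict)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "keep_mask_")
        counts = self._as_counts(X)
        if counts.n_genes != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} genes, got {counts.n_genes}")
        n = counts.n.astype(float)
        y = counts.counts[:, self.keep_mask_].astype(float)
        if self.kind == "zscore":
            q = log_cpm(counts, NormalizationConfig(self.c, self.m))
            vals = (q[:, self.keep_mask_] - self.mean_) / self.scale_
        else:
            mu = np.outer(n, self.pi_)
            if self.kind == "deviance":
                dev = np.clip(_binomial_deviance_terms(y, n, mu), 0.0, None)
                vals = np.sign(y - mu) * np.sqrt(dev)
            else:
                vals = (y - mu) / np.sqrt(mu - mu ** 2 / n[:, None])
        if self.standardize and self.kind != "zscore":
            scale = self.residual_scale_.copy()
            scale[scale == 0] = 1.0
            vals = vals / scale
        return vals

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "gene_ids_")
        return np.asarray(self.gene_ids_, dtype=object)
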