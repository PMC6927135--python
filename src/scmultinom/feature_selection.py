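"""Feature selection by binomial deviance.

A gene whose relative abundance is constant across cells fits the pooled
multinomial null perfectly; genes with genuine variation fit it poorly. The
binomial deviance of each gene against that null is available in closed form
and ranks genes on raw counts — no normalization, pseudocount, or log
transform enters. Highly-expressed and highly-variable baselines are
provided for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .count_model import CountMatrix, cpm, log_cpm, mle_relative_abundance
from .residuals import _binomial_deviance_terms

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRanking",
    "DevianceGeneSelector",
    "gene_deviance",
    "rank_genes",
    "ranking_concordance",
]

METHODS = ("deviance", "highly_expressed", "highly_variable")


@dataclass(frozen=True)
class GeneRanking:
    """Per-gene statistic plus the descending order it induces.

    Ties are broken by original gene index (ascending) so rankings are
    reproducible.
    """

    statistic: np.ndarray
    method: str
    order: np.ndarray
    gene_ids: np.ndarray

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def gene_deviance(counts: CountMatrix) -> np.ndarray:
    """Closed-form binomial deviance of each gene against the pooled null.

    ``D_j = 2 sum_i [ y_ij log(y_ij / (n_i pi_hat_j))
                      + (n_i - y_ij) log((n_i - y_ij) / (n_i (1 - pi_hat_j))) ]``

    ``D_j >= 0`` with equality iff ``y_ij / n_i`` is constant across cells.
    All-zero genes get ``D_j = 0`` (constant at zero) so ranking length is
    stable across methods.
    """
    pi = mle_relative_abundance(counts, pooled=True)
    nz = pi > 0
    D = np.zeros(counts.n_genes)
    if nz.any():
        n = counts.n.astype(float)
        y = counts.counts[:, nz].astype(float)
        mu = np.outer(n, pi[nz])
        D[nz] = np.clip(_binomial_deviance_terms(y, n, mu), 0.0, None).sum(axis=0)
    if (~nz).any():
        logger.warning("%d all-zero genes assigned deviance 0", int((~nz).sum()))
    return D


def _statistic(counts: CountMatrix, method: str, hvg_on_log: bool) -> np.ndarray:
    if method == "deviance":
        return gene_deviance(counts)
    if method == "highly_expressed":
        return counts.counts.mean(axis=0).astype(float)
    if method == "highly_variable":
        if hvg_on_log:
            return log_cpm(counts).var(axis=0)
        x = cpm(counts)
        mean = x.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = np.where(mean > 0, x.var(axis=0) / mean ** 2, 0.0)
        return cv2
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def rank_genes(counts: CountMatrix, method: str = "deviance",
               k: int | None = None, hvg_on_log: bool = False) -> GeneRanking:
    """Rank genes by informativeness, optionally truncated to the top ``k``.

    deviance: binomial deviance D_j; highly_expressed: mean raw count;
    highly_variable: squared coefficient of variation of CPM (variance of
    log-CPM with ``hvg_on_log=True``).
    """
    stat = _statistic(counts, method, hvg_on_log)
    if not np.isfinite(stat).all():
        raise ValueError("non-finite gene statistic")
    order = np.lexsort((np.arange(len(stat)), -stat))
    if k is not None:
        if not (0 < k <= counts.n_genes):
            raise ValueError(f"k must be in [1, {counts.n_genes}], got {k}")
        order = order[:k]
    return GeneRanking(stat, method, order, counts.gene_ids)


def ranking_concordance(r1: GeneRanking, r2: GeneRanking) -> float:
    """Spearman rank correlation between two rankings' statistics."""
    if len(r1.statistic) != len(r2.statistic) or not np.array_equal(
            r1.gene_ids, r2.gene_ids):
        raise ValueError("rankings cover different gene sets")
    rho = stats.spearmanr(r1.statistic, r2.statistic).statistic
    return float(rho)


class DevianceGeneSelector(SelectorMixin, BaseEstimator):
    """Select the top-k informative genes from a raw UMI count matrix.

    A drop-in sklearn feature selector: ``fit`` computes the per-gene
    statistic (binomial deviance by default) and ``transform`` keeps the
    ``k`` highest-ranked genes.

    Attributes
    ----------
    statistic_ : ndarray of shape (n_genes,)
        The per-gene ranking statistic.
    ranking_ : GeneRanking
        Full descending order with deterministic tie-breaks.
    """

    def __init__(self, k: int = 1500, method: str = "deviance",
                 hvg_on_log: bool = False):
        self.k = k
        self.method = method
        self.hvg_on_log = hvg_on_log

    def fit(self, X, y=None):
        counts = X if isinstance(X, CountMatrix) else CountMatrix(X)
        self.ranking_ = rank_genes(counts, self.method,
                                   hvg_on_log=self.hvg_on_log)
        if not (0 < self.k <= counts.n_genes):
            raise ValueError(f"k must be in [1, {counts.n_genes}], got {self.k}")
        self.statistic_ = self.ranking_.statistic
        self.n_features_in_ = counts.n_genes
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_.top(self.k)] = True
        return mask

    def transform(self, X):
        mask = self._get_support_mask()
        if isinstance(X, CountMatrix):
            return X.subset_genes(mask)
        return np.asarray(X)[:, mask]
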