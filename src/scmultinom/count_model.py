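"""Multinomial null model for UMI count matrices.

A droplet protocol captures a small multinomial sample of each cell's
transcripts: cell *i* yields ``n_i`` total UMIs distributed over genes with
relative abundances ``pi_ij``. Everything in this module follows from that
sampling model: relative-abundance estimators (MLE and Dirichlet-MAP),
counts-per-million and its log transform, the closed-form probability of a
zero count, the negative gene-gene correlation induced by the sum constraint,
and exact down-sampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NullFit",
    "NormalizationConfig",
    "SizeFactorMode",
    "mle_relative_abundance",
    "map_relative_abundance",
    "cpm",
    "log_cpm",
    "zero_probability",
    "multinomial_gene_correlation",
    "downsample",
    "zero_fraction",
    "fit_null",
]


class SizeFactorMode(str, Enum):
    total_counts = "total_counts"
    total_counts_over_m = "total_counts_over_m"
    user_supplied = "user_supplied"


@dataclass(frozen=True)
class NormalizationConfig:
    """Pseudocount/scale configuration for log-CPM style transforms.

    ``c`` is the pseudocount added inside the log; ``m`` the scale constant
    (1e6 gives counts per million). The pseudocount is equivalent to a
    symmetric Dirichlet prior with per-cell concentration ``alpha_i =
    (c/m) * n_i`` — see :func:`log_cpm`.
    """

    c: float = 1.0
    m: float = 1e6
    size_factor_mode: SizeFactorMode = SizeFactorMode.total_counts

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError(f"pseudocount c must be > 0, got {self.c}")
        if not (self.m > 0):
            raise ValueError(f"scale m must be > 0, got {self.m}")


def _as_dense_int(counts) -> np.ndarray:
    if sp.issparse(counts):
        counts = counts.toarray()
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise ValueError(f"counts must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.array_equal(arr, rounded):
            raise ValueError("counts must be integers")
        arr = rounded.astype(np.int64)
    else:
        arr = arr.astype(np.int64, copy=False)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


@dataclass
class CountMatrix:
    """Cells × genes matrix of non-negative integer UMI counts.

    Rows are cells, columns genes. ``n`` caches per-cell totals. Cells with
    zero total count are rejected at construction because every estimator
    divides by ``n_i``.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    n: np.ndarray = field(init=False)

    def __init__(self, counts, cell_ids: Sequence[str] | None = None,
                 gene_ids: Sequence[str] | None = None):
        self.counts = _as_dense_int(counts)
        I, J = self.counts.shape
        if cell_ids is None:
            cell_ids = [f"cell{i}" for i in range(I)]
        if gene_ids is None:
            gene_ids = [f"gene{j}" for j in range(J)]
        self.cell_ids = np.asarray(cell_ids, dtype=object)
        self.gene_ids = np.asarray(gene_ids, dtype=object)
        if len(self.cell_ids) != I:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {I} cells")
        if len(self.gene_ids) != J:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {J} genes")
        if len(set(self.cell_ids)) != I:
            raise ValueError("cell_ids must be unique")
        if len(set(self.gene_ids)) != J:
            raise ValueError("gene_ids must be unique")
        self.n = self.counts.sum(axis=1)
        if (self.n == 0).any():
            bad = list(self.cell_ids[self.n == 0])
            raise ValueError(f"cells with zero total counts: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        return CountMatrix(self.counts[:, mask_or_idx], self.cell_ids,
                           self.gene_ids[mask_or_idx])


@dataclass(frozen=True)
class NullFit:
    """Null model of constant composition: pooled abundances and fitted means.

    ``pi_pooled[j] = sum_i y_ij / sum_i n_i`` and ``mu[i, j] = n_i *
    pi_pooled[j]``.
    """

    pi_pooled: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        s = float(self.pi_pooled.sum())
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"pooled abundances sum to {s}, not 1")


def fit_null(counts: CountMatrix) -> NullFit:
    """Fit the constant-composition null model (pooled MLE + fitted means)."""
    pi = mle_relative_abundance(counts, pooled=True)
    mu = np.outer(counts.n, pi)
    return NullFit(pi_pooled=pi, mu=mu)


def mle_relative_abundance(counts: CountMatrix, pooled: bool = False) -> np.ndarray:
    """Maximum-likelihood relative abundances.

    Per-cell: ``pi_ij = y_ij / n_i`` (rows sum to 1). Pooled: ``pi_j =
    sum_i y_ij / sum_i n_i``, the MLE under the null of constant composition
    across cells.
    """
    if pooled:
        return counts.counts.sum(axis=0) / counts.n.sum()
    return counts.counts / counts.n[:, None]


def map_relative_abundance(counts: CountMatrix, alpha) -> np.ndarray:
    """Dirichlet-multinomial MAP relative abundances.

    With a symmetric Dirichlet(alpha_i) prior the posterior mode is
    ``(alpha_i + y_ij) / (J*alpha_i + n_i)``, a weighted average of the
    uniform prior mean 1/J and the MLE with weight ``w_i = J*alpha_i /
    (J*alpha_i + n_i)``. ``alpha = 0`` recovers the MLE exactly.
    """
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (counts.n_cells,)).copy()
    if (alpha < 0).any():
        raise ValueError("alpha must be non-negative")
    J = counts.n_genes
    return (alpha[:, None] + counts.counts) / (J * alpha + counts.n)[:, None]


def cpm(counts: CountMatrix) -> np.ndarray:
    """Counts per million: ``(y_ij / n_i) * 1e6``. Zeros stay zero."""
    return mle_relative_abundance(counts) * 1e6


def log_cpm(counts: CountMatrix, cfg: NormalizationConfig | None = None) -> np.ndarray:
    """Pseudocounted log transform ``log2(c + pi_hat_ij * m)``.

    With c=1 and m=1e6 this is the standard log2(1 + CPM). Within a dataset
    the result equals ``log2(pi_map_ij) + C`` for the MAP estimator at
    ``alpha_i = (c/m) * n_i``, C constant across cells and genes — the
    pseudocount is a disguised Dirichlet prior.
    """
    if cfg is None:
        cfg = NormalizationConfig()
    return np.log2(cfg.c + mle_relative_abundance(counts) * cfg.m)


def zero_probability(mu, n=None, model: str = "binomial", phi: float | None = None):
    """Probability of observing a zero count at expected count ``mu``.

    binomial (exact multinomial marginal): ``(1 - mu/n)**n``;
    poisson: ``exp(-mu)``;
    negative_binomial with shape ``phi`` (variance mu + mu^2/phi):
    ``(phi / (phi + mu))**phi``.
    """
    mu = np.asarray(mu, dtype=float)
    if (mu < 0).any():
        raise ValueError("mu must be non-negative")
    if model == "binomial":
        if n is None:
            raise ValueError("binomial model requires n")
        n = np.asarray(n, dtype=float)
        if (mu > n).any():
            raise ValueError("mu must not exceed n under the binomial model")
        return (1.0 - mu / n) ** n
    if model == "poisson":
        return np.exp(-mu)
    if model == "negative_binomial":
        if phi is None or phi <= 0:
            raise ValueError("negative_binomial model requires shape phi > 0")
        return (phi / (phi + mu)) ** phi
    raise ValueError(f"unknown model {model!r}")


def multinomial_gene_correlation(pi_j: float, pi_k: float) -> float:
    """Correlation between two genes' counts under multinomial sampling.

    The sum-to-``n_i`` constraint induces ``-sqrt(pi_j pi_k) /
    sqrt((1-pi_j)(1-pi_k))``: always negative, -1 in the two-gene case.
    """
    if not (pi_j > 0 and pi_k > 0 and pi_j + pi_k <= 1):
        raise ValueError(
            f"require pi_j, pi_k > 0 and pi_j + pi_k <= 1; got {pi_j}, {pi_k}")
    return -np.sqrt(pi_j * pi_k) / np.sqrt((1 - pi_j) * (1 - pi_k))


def downsample(counts: CountMatrix, target: int, seed: int) -> CountMatrix:
    """Down-sample every cell to exactly ``target`` total UMIs.

    Samples ``target`` molecules without replacement from each cell's UMIs
    (multivariate hypergeometric), so retained totals are exact. Cells with
    fewer than ``target`` UMIs are dropped with a warning.
    """
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    keep = counts.n >= target
    if not keep.all():
        dropped = int((~keep).sum())
        msg = f"downsample: dropping {dropped} cells with fewer than {target} UMIs"
        logger.warning(msg)
        warnings.warn(msg)
    rng = np.random.default_rng(seed)
    sub = counts.counts[keep]
    out = np.empty_like(sub)
    for i in range(sub.shape[0]):
        out[i] = rng.multivariate_hypergeometric(sub[i], target)
    return CountMatrix(out, counts.cell_ids[keep], counts.gene_ids)


def zero_fraction(counts: CountMatrix, axis: str = "per_cell") -> np.ndarray:
    """Fraction of exactly-zero entries per cell or per gene."""
    zeros = counts.counts == 0
    if axis == "per_cell":
        return zeros.mean(axis=1)
    if axis == "per_gene":
        return zeros.mean(axis=0)
    raise ValueError(f"axis must be 'per_cell' or 'per_gene', got {axis!r}")
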