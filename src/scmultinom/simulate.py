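"""Synthetic UMI count generators with multinomial sampling structure.

Each generator draws per-cell totals ``n_i`` and relative-abundance vectors
``pi_i`` on the simplex, then samples counts multinomially — the same
"competition to be counted" mechanism that produces the zero patterns of
real droplet data. Four presets cover the study conditions used throughout
the package's tests: a negative-control null (constant composition), a
Dirichlet-multinomial overdispersed null, a cluster-plus-batch design, and
a three-gene-class design for feature-selection benchmarking.

Conceptual true transcript totals ``t_i`` (~200,000 for a mammalian cell,
far above the 1000-10,000 UMIs actually captured) are recorded in the truth
object but play no role in sampling: the multinomial needs only pi and n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .count_model import CountMatrix

__all__ = [
    "SimTruth",
    "SimResult",
    "simulate_null",
    "simulate_dirichlet_multinomial",
    "simulate_clusters_batches",
    "simulate_feature_selection",
]

TRUE_TOTAL_TRANSCRIPTS = 200_000


@dataclass
class SimTruth:
    """Ground truth of a simulation: labels and generating parameters."""

    cluster_labels: np.ndarray | None = None
    batch_labels: np.ndarray | None = None
    gene_class: np.ndarray | None = None
    true_pi: np.ndarray | None = None       # cells x genes, rows on simplex
    true_totals: np.ndarray | None = None   # conceptual t_i


@dataclass
class SimResult:
    counts: CountMatrix
    truth: SimTruth
    seed: int


def _draw_counts(rng: np.random.Generator, n: np.ndarray,
                 pi: np.ndarray) -> np.ndarray:
    """Multinomial draw per cell; pi may be one shared row or per-cell rows."""
    I = len(n)
    if pi.ndim == 1:
        pi = np.broadcast_to(pi, (I, len(pi)))
    out = np.empty((I, pi.shape[1]), dtype=np.int64)
    for i in range(I):
        out[i] = rng.multinomial(n[i], pi[i])
    return out


def _check_simplex(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError(f"pi sums to {pi.sum()}, not 1")
    if (pi < 0).any():
        raise ValueError("pi must be non-negative")
    return pi


def simulate_null(I: int = 2000, pi: np.ndarray | None = None,
                  n_range: tuple[int, int] = (1000, 3000),
                  seed: int = 0) -> SimResult:
    """Negative-control null: constant composition across cells.

    Defaults follow the droplet negative-control regime: J = 10^4 genes
    with uniform pi_j = 1e-4 and totals uniform on [1000, 3000], which
    yields roughly 74-90% zeros per gene. No cluster structure exists.
    """
    if pi is None:
        pi = np.full(10_000, 1e-4)
    pi = _check_simplex(pi)
    lo, hi = n_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid n_range {n_range}")
    rng = np.random.default_rng(seed)
    n = rng.integers(lo, hi + 1, size=I)
    counts = _draw_counts(rng, n, pi)
    truth = SimTruth(true_pi=np.broadcast_to(pi, (I, len(pi))).copy(),
                     true_totals=np.full(I, TRUE_TOTAL_TRANSCRIPTS))
    return SimResult(CountMatrix(counts), truth, seed)


def simulate_dirichlet_multinomial(I: int = 500, pi_base: np.ndarray | None = None,
                                   alpha: float = 0.1,
                                   n_range: tuple[int, int] = (1000, 3000),
                                   seed: int = 0) -> SimResult:
    """Overdispersed null: per-cell composition drawn from a Dirichlet.

    Each cell draws ``pi_i ~ Dirichlet(alpha * J * pi_base)`` then counts
    multinomially; small ``alpha`` means strong extra-multinomial variance.
    Large ``alpha`` recovers the plain multinomial null.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if pi_base is None:
        pi_base = np.full(2000, 1 / 2000)
    pi_base = _check_simplex(pi_base)
    J = len(pi_base)
    rng = np.random.default_rng(seed)
    lo, hi = n_range
    n = rng.integers(lo, hi + 1, size=I)
    conc = alpha * J * pi_base
    pis = rng.dirichlet(conc, size=I)
    counts = _draw_counts(rng, n, pis)
    truth = SimTruth(true_pi=pis, true_totals=np.full(I, TRUE_TOTAL_TRANSCRIPTS))
    return SimResult(CountMatrix(counts), truth, seed)


def simulate_clusters_batches(seed: int = 0, n_clusters: int = 3,
                              cells_per_cluster: int = 50,
                              n_genes: int = 5000,
                              n_informative: int = 500,
                              batch_totals: tuple[int, int] = (1000, 2000),
                              effect_sd: float = 1.0,
                              gene_batch_effect_sd: float = 0.0) -> SimResult:
    """Cluster-structured counts with a depth batch effect.

    Defaults: 150 cells in 3 clusters of 50, 5000 genes of which 500 are
    differentially expressed across clusters; two batches with per-cell
    totals 1000 and 2000 and equal cluster membership in each batch
    (25 cells per cluster per batch).

    Informative genes receive per-cluster log-normal(0, effect_sd)
    abundance multipliers (renormalized to the simplex). Baseline
    abundances are log-normal(0, 2) to mimic the skewed expression
    distribution of real data. ``gene_batch_effect_sd`` adds an optional
    multiplicative gene-level batch effect (off by default; the primary
    batch effect is the total-count difference).
    """
    rng = np.random.default_rng(seed)
    I = n_clusters * cells_per_cluster
    half = cells_per_cluster // 2

    clusters = np.repeat(np.arange(n_clusters), cells_per_cluster)
    batches = np.tile(np.r_[np.zeros(half, int),
                            np.ones(cells_per_cluster - half, int)], n_clusters)
    n = np.where(batches == 0, batch_totals[0], batch_totals[1])

    base = np.exp(rng.normal(0.0, 2.0, n_genes))
    base /= base.sum()
    informative = rng.choice(n_genes, size=n_informative, replace=False)
    gene_class = np.full(n_genes, "noise", dtype=object)
    gene_class[informative] = "informative"

    cluster_pi = np.tile(base, (n_clusters, 1))
    for c in range(n_clusters):
        mult = np.exp(rng.normal(0.0, effect_sd, n_informative))
        cluster_pi[c, informative] *= mult
        cluster_pi[c] /= cluster_pi[c].sum()

    pis = cluster_pi[clusters]
    if gene_batch_effect_sd > 0:
        bmult = np.exp(rng.normal(0.0, gene_batch_effect_sd, (2, n_genes)))
        pis = pis * bmult[batches]
        pis /= pis.sum(axis=1, keepdims=True)

    counts = _draw_counts(rng, n, pis)
    truth = SimTruth(cluster_labels=clusters, batch_labels=batches,
                     gene_class=gene_class, true_pi=pis,
                     true_totals=np.full(I, TRUE_TOTAL_TRANSCRIPTS))
    return SimResult(CountMatrix(counts), truth, seed)


def simulate_feature_selection(seed: int = 0, I: int = 250,
                               n_low: int = 800, n_high_const: int = 100,
                               n_high_var: int = 100,
                               high_to_low_ratio: float = 50.0,
                               fold_change: float = 4.0,
                               variable_mean_ratio: float = 0.8,
                               n_range: tuple[int, int] = (2000, 5000)) -> SimResult:
    """Three gene classes: lowly expressed, high-constant, high-variable.

    High-constant genes sit at ``high_to_low_ratio`` times the low-class
    abundance in every cell. High-variable genes swing by ``fold_change``
    between two random halves of the cells, with across-cell mean abundance
    ``variable_mean_ratio`` times the constant-high level — comparable in
    pooled expression but slightly below, as a gene alternating between
    high and lower states is. Only the variable class violates the
    constant-composition null, so deviance should prefer it while mean
    expression ranks the constant class first.
    """
    rng = np.random.default_rng(seed)
    J = n_low + n_high_const + n_high_var
    gene_class = np.array(["low"] * n_low + ["high_constant"] * n_high_const
                          + ["high_variable"] * n_high_var, dtype=object)
    base = np.ones(J)
    base[gene_class != "low"] = high_to_low_ratio

    groups = rng.permutation(I) < I // 2
    hv = np.where(gene_class == "high_variable")[0]
    up_in_group1 = rng.random(len(hv)) < 0.5

    pis = np.tile(base, (I, 1))
    # amplitude chosen so the across-cell mean is variable_mean_ratio * high
    amp = (variable_mean_ratio * high_to_low_ratio
           / ((fold_change + 1.0 / fold_change) / 2.0))
    for g, up1 in zip(hv, up_in_group1):
        fc = np.where(groups == up1, fold_change, 1.0 / fold_change)
        pis[:, g] = amp * fc
    pis /= pis.sum(axis=1, keepdims=True)

    lo, hi = n_range
    n = rng.integers(lo, hi + 1, size=I)
    counts = _draw_counts(rng, n, pis)
    truth = SimTruth(cluster_labels=groups.astype(int), gene_class=gene_class,
                     true_pi=pis, true_totals=np.full(I, TRUE_TOTAL_TRANSCRIPTS))
    return SimResult(CountMatrix(counts), truth, seed)
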