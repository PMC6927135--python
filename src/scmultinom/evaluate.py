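"""Downstream assessment: PCA embedding, k-means, ARI, silhouette, and
zero-fraction diagnostics.

The harness reproduces the standard clustering benchmark at synthetic
scale: transform a count matrix (residuals, z-scores, or GLM-PCA), embed to
L dimensions, cluster with k-means, and score against ground-truth labels
with the adjusted Rand index and silhouette coefficient. A diagnostic
reports how strongly each embedding dimension tracks the per-cell fraction
of zeros and log total counts — the nuisance covariates that dominate PCA
on log-normalized data.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .count_model import CountMatrix, zero_fraction
from .feature_selection import rank_genes
from .glmpca import GLMPCA
from .residuals import (
    ResidualMatrix,
    deviance_residuals,
    log_cpm_zscores,
    pearson_residuals,
)
from .simulate import SimResult

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "pca_embed",
    "cluster_kmeans",
    "adjusted_rand_index",
    "silhouette_score",
    "dimension_zero_correlation",
    "run_comparison_grid",
]


@dataclass
class Embedding:
    """Cells × L latent coordinates with provenance of the transform."""

    coords: np.ndarray
    method: str
    source: str = ""


def pca_embed(matrix: ResidualMatrix | np.ndarray, L: int) -> Embedding:
    """PCA scores of a transformed matrix (centered per gene, no rescaling)."""
    X = matrix.values if isinstance(matrix, ResidualMatrix) else np.asarray(matrix)
    if L > min(X.shape):
        raise ValueError(f"L={L} exceeds min(cells, genes)={min(X.shape)}")
    pca = PCA(n_components=L, svd_solver="full")
    coords = pca.fit_transform(X)
    src = matrix.kind if isinstance(matrix, ResidualMatrix) else "matrix"
    return Embedding(coords, "pca", src)


def cluster_kmeans(emb: Embedding, k: int, seed: int = 0,
                   n_restarts: int = 10) -> np.ndarray:
    """k-means++ labels, best of ``n_restarts`` by within-cluster SS."""
    X = emb.coords
    if not (2 <= k <= X.shape[0]):
        raise ValueError(f"k must be in [2, {X.shape[0]}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(X)


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement; 1 iff identical partitions."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    return float(metrics.adjusted_rand_score(a, b))


def silhouette_score(emb: Embedding, labels) -> float:
    """Mean silhouette (b-a)/max(a,b) under Euclidean distance."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(metrics.silhouette_score(emb.coords, labels))


def dimension_zero_correlation(emb: Embedding,
                               counts: CountMatrix) -> pd.DataFrame:
    """Pearson r of each embedding dimension with per-cell zero fraction and
    with log total UMIs."""
    zf = zero_fraction(counts, "per_cell")
    logn = np.log(counts.n.astype(float))
    if emb.coords.shape[0] != counts.n_cells:
        raise ValueError("embedding and counts have different cell numbers")
    rows = []
    for l in range(emb.coords.shape[1]):
        d = emb.coords[:, l]
        if d.std() == 0:
            warnings.warn(f"dimension {l} has zero variance; correlation = 0")
            rows.append((l, 0.0, 0.0))
            continue
        rows.append((l,
                     float(np.corrcoef(d, zf)[0, 1]),
                     float(np.corrcoef(d, logn)[0, 1])))
    return pd.DataFrame(rows, columns=["dimension", "r_zero_fraction",
                                       "r_log_total"])


_TRANSFORMS = ("glmpca", "deviance_pca", "pearson_pca", "logcpm_pca")


def _embed(counts: CountMatrix, transform: str, L: int, seed: int,
           glmpca_kwargs: dict | None = None) -> Embedding:
    if transform == "glmpca":
        kw = dict(n_components=L, random_state=seed, max_iter=500)
        kw.update(glmpca_kwargs or {})
        est = GLMPCA(**kw)
        return Embedding(est.fit_transform(counts), "glmpca", "counts")
    if transform == "deviance_pca":
        return pca_embed(deviance_residuals(counts), L)
    if transform == "pearson_pca":
        return pca_embed(pearson_residuals(counts), L)
    if transform == "logcpm_pca":
        return pca_embed(log_cpm_zscores(counts), L)
    raise ValueError(f"unknown transform {transform!r}")


def run_comparison_grid(sim: SimResult,
                        fs_methods=("deviance", "highly_variable"),
                        n_genes=(300,),
                        transforms=("glmpca", "deviance_pca", "logcpm_pca"),
                        dims=(10,),
                        cluster_numbers=(2, 3, 4),
                        seed: int = 0,
                        n_restarts: int = 10,
                        filter_within_truth: float | None = None,
                        glmpca_kwargs: dict | None = None) -> pd.DataFrame:
    """Cross-product benchmark: feature selection × transform × L × k.

    Each combination is scored by ARI against the simulation's true cluster
    labels and by the silhouette of the inferred labels. Infeasible
    combinations (more genes requested than exist) are skipped with a
    logged reason. ``filter_within_truth=0.25`` keeps only rows whose
    cluster number is within 25% of the true number.
    """
    truth = sim.truth.cluster_labels
    if truth is None:
        raise ValueError("simulation carries no cluster labels")
    k_true = len(np.unique(truth))
    master = np.random.default_rng(seed)
    rows = []
    for fs, ng, tr, L, k in itertools.product(fs_methods, n_genes, transforms,
                                              dims, cluster_numbers):
        if ng > sim.counts.n_genes:
            logger.info("skip: %d genes requested, %d available", ng,
                        sim.counts.n_genes)
            continue
        sub_seed = int(master.integers(2 ** 31))
        ranking = rank_genes(sim.counts, fs, k=ng)
        kept = sim.counts.counts[:, ranking.top(ng)]
        # cells with no counts in the selected genes are uninformative
        full = kept.sum(axis=1) > 0
        if not full.all():
            logger.info("dropping %d cells empty after feature selection",
                        int((~full).sum()))
        sub = CountMatrix(kept[full], sim.counts.cell_ids[full],
                          sim.counts.gene_ids[ranking.top(ng)])
        emb = _embed(sub, tr, L, sub_seed, glmpca_kwargs)
        labels = cluster_kmeans(emb, k, seed=sub_seed, n_restarts=n_restarts)
        rows.append(dict(seed=sub_seed, fs_method=fs, n_genes=ng,
                         dr_method=tr, L=L, k=k,
                         ari=adjusted_rand_index(truth[full], labels),
                         silhouette=silhouette_score(emb, labels)))
    out = pd.DataFrame(rows)
    if filter_within_truth is not None and len(out):
        lo = k_true * (1 - filter_within_truth)
        hi = k_true * (1 + filter_within_truth)
        out = out[(out.k >= lo) & (out.k <= hi)].reset_index(drop=True)
    return out
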