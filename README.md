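# scmultinom

Multinomial models for single-cell RNA-seq UMI counts: feature selection by
binomial deviance, null-model residual transforms, and GLM-PCA dimension
reduction — with simulation generators and a clustering benchmark harness.

## The problem

A droplet scRNA-seq protocol captures only a small fraction of each cell's
transcripts. Cell *i* yields *n*<sub>*i*</sub> total UMIs (typically
1000–10,000, against roughly 200,000 transcripts in the cell), distributed
across genes in proportion to their relative abundances
*π*<sub>*ij*</sub>. The observed counts *y*<sub>*ij*</sub> are therefore a
multinomial sample: the marginal of a single gene is
Binomial(*n*<sub>*i*</sub>, *π*<sub>*ij*</sub>), its zero probability is
(1 − *π*<sub>*ij*</sub>)<sup>*n*<sub>*i*</sub></sup>, and the abundant exact
zeros in UMI data are exactly what this sampling model predicts — no
zero-inflation component is needed.

The standard pipeline — counts per million, log2(1 + CPM), per-gene
z-scores, PCA — fights this data-generating mechanism. The pseudocount
transform log2(*c* + *π̂*<sub>*ij*</sub>·*m*) equals (up to a global
constant) the log of a Dirichlet MAP estimate with per-cell prior
concentration *α*<sub>*i*</sub> = (*c*/*m*)·*n*<sub>*i*</sub>; with CPM's
weak prior, a single count at depth 3000 maps to log2(334) ≈ 8.4 while
zeros stay at 0, carving an artificial gap that makes the data look
zero-inflated and letting the per-cell zero fraction drive the first
principal component.

This package implements the count-native alternatives:

- **Deviance feature selection** — the closed-form binomial deviance of each
  gene against the null of constant expression,
  *D*<sub>*j*</sub> = 2 Σ<sub>*i*</sub> [ *y*<sub>*ij*</sub> log(*y*<sub>*ij*</sub>/*n*<sub>*i*</sub>*π̂*<sub>*j*</sub>) +
  (*n*<sub>*i*</sub> − *y*<sub>*ij*</sub>) log((*n*<sub>*i*</sub> − *y*<sub>*ij*</sub>)/(*n*<sub>*i*</sub>(1 − *π̂*<sub>*j*</sub>))) ],
  computed on raw counts.
- **Deviance and Pearson residuals** of the same null — PCA-ready matrices
  that replace log-CPM z-scores.
- **GLM-PCA** — low-rank factorization of the log mean,
  *y*<sub>*ij*</sub> ~ Poi(*s*<sub>*i*</sub> exp(*u*<sub>*i*</sub>ʹ*v*<sub>*j*</sub>))
  (or negative binomial with shape *φ*), with size-factor offsets, gene
  intercepts, optional covariates, and an L2 penalty, fit by blockwise
  Fisher scoring over latent dimensions.

The main entry points are sklearn-style estimators (`DevianceGeneSelector`,
`NullResiduals`, `GLMPCA`) that compose with sklearn pipelines, plus
plain functions and a CLI (`scmultinom simulate|select|residuals|glmpca|benchmark`).

## Worked example

```python
import numpy as np
from scmultinom import (simulate_clusters_batches, GLMPCA, DevianceGeneSelector,
                        pca_embed, log_cpm_zscores, deviance_residuals,
                        cluster_kmeans, adjusted_rand_index, Embedding)

sim = simulate_clusters_batches(seed=0)   # 150 cells, 3 clusters, 2 batches
truth = sim.truth.cluster_labels

est = GLMPCA(n_components=2, random_state=0)
emb_glm = Embedding(est.fit_transform(sim.counts), "glmpca")
emb_dev = pca_embed(deviance_residuals(sim.counts), 2)
emb_log = pca_embed(log_cpm_zscores(sim.counts), 2)
for name, emb in [("glmpca", emb_glm), ("deviance-PCA", emb_dev),
                  ("logCPM-PCA", emb_log)]:
    labels = cluster_kmeans(emb, 3, seed=0)
    print(name, round(adjusted_rand_index(truth, labels), 3))

sel = DevianceGeneSelector(k=500).fit(sim.counts)
hit = np.isin(np.where(sel.get_support())[0],
              np.where(sim.truth.gene_class == "informative")[0])
print("informative genes among top 500 by deviance:", int(hit.sum()))
```

prints

```
glmpca 1.0
deviance-PCA 1.0
logCPM-PCA 0.15
informative genes among top 500 by deviance: 85
```

With two batches differing only in sequencing depth (totals 1000 vs 2000),
k-means on GLM-PCA factors or on deviance-residual PCA recovers the three
true clusters perfectly (adjusted Rand index 1.0), while PCA on log-CPM
z-scores is dominated by the depth/zero-fraction artifact (ARI 0.15). The
top-500 deviance genes contain 85 of the 500 truly differentially expressed
genes, more than the highly-variable-gene baseline finds on the same data.

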