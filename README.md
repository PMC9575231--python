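# schicnd

Normalization, de-noising, and gene-level scoring of **single-cell Hi-C**
(scHi-C) data.

scHi-C assays measure 3D genome organization one cell at a time, producing
per-cell contact matrices that are extremely sparse, dominated by a strong
genomic-distance (band) bias, and confounded by sequencing depth and batch
effects.  This package provides the band-based toolchain needed to turn such
data into cell-type structure and gene-level signals:

* **Band transformation and I/O** — sparse long-format contacts, binning,
  published sparse-cell filters, per-band `cells x locus-pairs` matrices,
  pseudo-bulk aggregation.
* **Scaling normalizers** — CellScale (library size), BandScale (per-band
  depth), and **BandNorm**:

      C_r^{cv} = (Y_r^{cv} / L^{cv}) * alpha(v),   alpha(v) = (1/N) sum_c L^{cv}

  which removes each cell's depth and decay profile and restores a common
  band-dependent decay estimate.
* **A zero-inflated negative-binomial variational autoencoder** fitted
  independently per pooled band group: counts are modeled as
  `ZINB(d_c * eta(z_c, s_c), delta_v, omega(z_c, s_c))` with latent cell
  state `z_c ~ N(0, I_K)`, a log-normal cell/band size factor `d_c`, per-band
  dispersion, and a dropout network — yielding per-cell latent embeddings and
  de-noised, dropout-free expected contacts.  Inference is amortized
  variational inference in pure NumPy with analytic gradients (verified
  against finite differences).
* **scGAD scores** — per cell and gene, the ratio of within-gene-body
  contacts to equal-length flanking windows, standardized per cell; plus the
  slope-1 tangent threshold for "high" scores, one-sample signed-rank tests,
  Seurat-style one-vs-rest marker detection, two-group differential tests,
  and Fisher overlap tests.
* **Evaluation metrics** — ARI, silhouette, seeded K-means, Louvain with a
  resolution binary-searched to a target cluster count, iLISI batch-mixing
  scores, SNN-Jaccard cell similarity, and cell-type dendrograms.
* **A synthetic-data generator** with power-law decay, planted cell-type
  domains, log-normal library sizes, band-wise batch effects, Bernoulli
  dropout, and planted marker genes — every experiment in the test suite is
  generated on the fly with recorded ground truth.

## Worked example

```python
from schicnd import (SyntheticConfig, simulate_cells, band_norm,
                     vectorize_cells, pca_project, kmeans_labels,
                     adjusted_rand_index, mean_silhouette)

cfg = SyntheticConfig(seed=11)          # 3 cell types x 100 cells, 60 bins
table, meta, truth = simulate_cells(cfg)
print(f"{len(table.df)} contact records, {len(meta.df)} cells")

normed, factors = band_norm(table)
print(f"alpha(1) = {factors.alpha('chr1', 1):.2f}  "
      f"alpha(10) = {factors.alpha('chr1', 10):.2f}")

X = pca_project(vectorize_cells(normed).matrix.toarray(), 50)
labels = meta.df["cell_type"].to_numpy()
pred = kmeans_labels(X, 3, seed=0)
print(f"ARI vs planted types: {adjusted_rand_index(labels, pred):.3f}")
print(f"silhouette of planted types: {mean_silhouette(X, labels):.3f}")
```

Output:

```
177688 contact records, 300 cells
alpha(1) = 455.84  alpha(10) = 24.68
ARI vs planted types: 1.000
silhouette of planted types: 0.164
```

`alpha(v)` is the cross-cell mean contact count of band `v` — the common
decay profile BandNorm restores (here it drops from ~456 at 1 Mb separation
to ~25 at 10 Mb).  The adjusted Rand index of 1.0 says K-means on the top 50
principal components of the normalized matrix recovers the three planted
cell types exactly; the silhouette is positive but modest, as expected for
high-dimensional sparse data where clusters are separable yet not tight.

The same pipeline is available from the shell:

```sh
schic simulate --out sim --seed 11
printf 'chr1\t60000000\n' > sizes.tsv
schic normalize --contacts sim/contacts.tsv --resolution 1000000 \
      --chrom-sizes sizes.tsv --method bandnorm \
      --out bandnorm.tsv --factors-out factors.tsv
schic scvi3d --contacts sim/contacts.tsv --resolution 1000000 \
      --chrom-sizes sizes.tsv --latent-dim 10 --seed 7 \
      --embedding-out embedding.tsv
schic scgad --contacts bandnorm.tsv --resolution 1000000 \
      --chrom-sizes sizes.tsv --genes sim/genes.bed --scores-out gad.tsv
schic evaluate --embedding embedding.tsv --metadata sim/metadata.tsv \
      --metrics ari,silhouette --out metrics.tsv
```

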