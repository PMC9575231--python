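# Methods

## Band transformation

A single-cell Hi-C experiment yields, per cell `c` and chromosome, a
symmetric `D x D` contact matrix whose entry `(i, j)` counts interactions
between genomic bins `i` and `j`.  Only the upper triangle is kept.  The
*band* `v = j - i` collects all locus pairs at the same genomic distance;
band `v` has `m_v = D - v` pairs, denoted `A(v)`.  Because contact frequency
decays strongly and systematically with distance (polymer behavior of
chromatin), every method in this package operates band by band.  The
diagonal `v = 0` is excluded throughout: its entries follow a visibly
different distribution and carry no pairwise-distance information, so all
modeling uses `v >= 1`.

Raw counts are written `Y_r^{cv}` for pair `r in A(v)` in cell `c`; the cell
band total is `L^{cv} = sum_r Y_r^{cv}`.

## Scaling normalizers

* **CellScale** divides each cell by its total count and multiplies by a
  common target (10,000).  It removes library size only; the distance decay
  remains confounded between cells.
* **BandScale** divides each entry by the cell's band mean
  `L^{cv} / m_v`.  This removes both depth and the cell's decay profile —
  including any biologically meaningful decay differences.
* **BandNorm** computes

      C_r^{cv} = (Y_r^{cv} / L^{cv}) * alpha(v),
      alpha(v) = (1/N) * sum_c L^{cv},

  i.e. BandScale's depth removal followed by restoring a *common*
  band-dependent decay estimate, the cross-cell mean band total.  `N` is the
  number of retained cells: cells with `L^{cv} = 0` count in the denominator
  of `alpha(v)` (they simply contribute zero), and their band stays all
  zero.  Factors `alpha(v)` are computed per chromosome and can be frozen
  and re-applied to held-out cells; with frozen factors the output of a cell
  is exactly invariant to rescaling its counts.

Normalization never mixes chromosomes, and outputs are real-valued — no
re-rounding is applied.

## The zero-inflated negative-binomial band model

Counts of one (pooled) band group are modeled per cell with a hierarchical
generative process:

* latent cell state `z_c ~ Normal(0, I_K)` (default `K = 100`; reduced-scale
  analyses and the test suite use smaller `K`);
* size factor `d_c ~ LogNormal(mu_d, sigma_d^2)`, prior moments matched to
  the observed log group totals of the kept cells (computed per batch when
  the fit is batch-aware).  This merges the library-size and band-size
  factors into one cell-by-band-group scale;
* mean fractions `mu = eta(z_c, s_c)` from a decoder network with a softmax
  output, so `sum_r mu_r = 1` — this makes `d_c` identifiable as the scale
  of the group total;
* per-pair rate `lambda_r ~ Gamma` with mean `mu_r` and shape `delta_v`, and
  count `N_r ~ Poisson(d_c * lambda_r)`; marginally `N_r` is negative
  binomial with mean `d_c * mu_r` and inverse-dispersion `delta_v`.
  `delta_v` is one free parameter per *band*, so each constituent band of a
  pooled group keeps its own dispersion;
* dropout indicator `T_r ~ Bernoulli(pi_r)` with `pi = omega(z_c, s_c)`;
  the observed value is zero when `T_r = 1` and `N_r` otherwise.

`s_c` is the one-hot batch label, concatenated onto both the encoder input
and the decoder inputs when batch awareness is enabled; this lets the
decoders explain away multiplicative batch distortions so that `z` does not
have to encode them.

With `pi = 0` and `delta -> inf` the observation model collapses to
Poisson; this reduction is verified numerically in the test suite against
the closed-form Poisson pmf.

### Inference

Amortized variational inference.  An encoder network maps `log1p(Y)` (plus
the batch one-hot) to Gaussian posteriors over `z` and `log d`; one Monte
Carlo sample per step reparametrizes both, and the evidence lower bound

    ELBO = E_q[ log ZINB(Y | d*mu, delta, pi) ]
           - KL(q(z) || N(0, I)) - KL(q(log d) || N(mu_d, sigma_d^2))

is maximized.  The implementation is NumPy with hand-derived gradients —
backpropagation through the ZINB log-likelihood, the softmax decoder, the
ReLU layers, and both reparametrizations — verified against central finite
differences at every parameter tensor in the test suite.

Numerical choices:

* encoder/decoder: one hidden ReLU layer of 128 units each; He
  initialization from the seeded generator.
* log-variance outputs are clipped to `[-15, 8]`; the gradient is zeroed
  where a clip is active.
* optimizer: full-batch Adam, 1000 epochs at learning rate `3e-3`.  Band
  groups here are small enough (hundreds of cells, at most a few thousand
  pairs) that full-batch training is fast and removes minibatch sampling as
  a source of nondeterminism; the epoch/rate pair was chosen on the
  parameter-recovery experiment, where shorter schedules left the decoder
  visibly underfitted while the latent space was already separated.
* a small constant (`1e-8`) guards `log(mean)` terms; a non-finite loss
  aborts with a diagnostic rather than continuing silently.
* one master seed drives initialization and sampling, so a fit is
  reproducible bit-for-bit on one machine.

Cells with no interaction across all locus pairs of a group are removed
before fitting; their rows of that group's latent block are imputed with
exact zeros when embeddings are concatenated (columns ordered by
(chromosome, group)).  A group with fewer than two remaining cells is
skipped and reported.

De-noised values are `d_c * mu_r` evaluated at the posterior means — the
expected dropout-free NB mean — so each cell's de-noised group total equals
its size factor.

### Band pooling

Distant bands are sparse and have few pairs, so bands are pooled into
groups fitted jointly.  Five schedules are provided; the default
(strategy 1) grows group sizes progressively 1, 2, 3, 4, ... —
`{1}, {2,3}, {4,5,6}, {7..10}, ...` — optionally truncated by a group-count
cap after which the last group absorbs every remaining band.  The cap
default is unlimited (triangular growth until bands are exhausted), which
keeps the schedule a pure function of `V`.  Strategy 2 fits bands 1–10
individually and then grows 2, 3, 4, ...; strategy 3 uses doubling sizes
5, 10, 20, ...; strategy 4 merges every ten bands; strategy 5 fits bands
1–10 individually and then merges every ten.  An optional pre-filter keeps
only the bands with the highest across-cell variance of band totals
(disabled by default — all bands are kept).

## scGAD scores

For a gene spanning bins `[a, b]` (width `w = b - a + 1` bins), the within
score sums normalized contacts over off-diagonal pairs
`a <= i < j <= b`; flank scores are computed identically on `[a-w, a-1]`
and `[b+1, b+w]`.  The raw score is within / mean(flank scores); raw scores
are then standardized per cell into z-scores across genes.  The input is
the BandNorm-normalized table, and the ratio plus standardization make the
score invariant to rescaling a cell's counts.

Conventions where the definition leaves room:

* sums (not per-pair means) are used in numerator and denominator — for
  equal-width windows the pair counts cancel, so the ratio is identical
  either way;
* a flank truncated by the chromosome edge is dropped and the remaining
  flank alone forms the denominator; a gene with no usable flank, a zero
  denominator, or spanning fewer than two bins is missing (masked out of
  every downstream test);
* only genes of at least 100 kb are scored — shorter genes cannot be
  resolved at typical contact-map resolutions.

**High-score threshold.**  Genes are ranked by cross-cell mean score; mean
scores and ranks are each min-max scaled to `[0, 1]`, producing a monotone
curve.  The curve is smoothed with a monotone cubic (PCHIP) spline and the
point where its derivative equals 1 is located by bracketing on a fine grid
plus root bisection.  With several slope-1 crossings the largest rank wins
(the most selective threshold); an exactly linear curve resolves to the
midpoint.  The threshold is reported in original score units.

**Statistics.**  High-score genes per cell type: one-sample Wilcoxon
signed-rank of cell-level scores against the threshold, one-sided
(greater), exact distribution for up to 25 non-zero differences and the
normal approximation with continuity correction above, Benjamini-Hochberg
adjusted across genes within each type.  Cell-type markers: raw scores are
total-normalized per cell, log1p-transformed, and z-scaled per gene; a gene
must be detected (positive log score) in at least 10% of in-group cells and
show an in-minus-out mean log difference of at least 0.25 before a
one-sided Wilcoxon rank-sum test; BH within type.  Differential scoring
between two groups uses the two-sided rank-sum test with the direction of
the mean difference.  Overlap of two marker lists over a gene universe is
tested with a one-sided Fisher's exact test.

## Evaluation metrics

* **ARI** — contingency-table adjusted Rand index (scikit-learn), verified
  against an all-pairs counting oracle.
* **Silhouette** — mean of `(b - a) / max(a, b)` under Euclidean distance.
* **K-means** — 300 restarts, 1000 iterations, seeded.
* **Louvain with a target cluster count** — SNN graph (Jaccard weights over
  20-nearest-neighbor sets), igraph's multilevel modularity with the
  resolution parameter binary-searched over `[1e-3, 10]` for up to 30
  steps; exact match returns immediately, otherwise the closest count wins
  with a warning.
* **iLISI** — per cell, a Gaussian kernel over all other cells is
  calibrated so the neighborhood entropy equals `log(perplexity)` (default
  30); the score is the inverse Simpson index of kernel-weighted batch
  frequencies, spanning 1 (single batch in the neighborhood) to the number
  of batches (perfect mixing).
* **SNN similarity** — Jaccard overlap of k-nearest-neighbor sets (self
  included, `k = 20`); diagonal reported as 0 by convention.
* **Cell-type dendrogram** — average-linkage clustering on
  `1 - similarity`, with per-type purity at the cut into as many clusters
  as types.
* The benchmark harness applies PCA to 50 components before clustering
  vectorized matrices, and consumes t-SNE/UMAP views as externally supplied
  coordinates — low-dimensional projection methods are not re-implemented.

## Synthetic data

The generator draws, for cell `c` of type `t` in batch `s`, pair `r` of
band `v`:

    rate = l_c * beta_s(v) * A_t * v^(-gamma_t) / m_v * fold(t, r)
    count ~ Poisson(rate), then zeroed with probability p0 (dropout)

with log-normal library sizes `l_c`, log-normal per-batch band multipliers
`beta_s(v)` (a distortion BandNorm cannot remove but the band model can),
and `fold` the planted type-specific structure.  Type differences enter
through two channels that mirror real data: the global decay exponent
`gamma_t`, and square self-interacting domains (8 per type, 6 bins wide,
3-fold enriched) standing in for type-specific TAD/compartment
organization.  Marker genes are planted as 3-fold enrichment of the pairs
inside a gene body in one target type; genes are tiled so that every flank
window lies inside the chromosome and outside every other gene body,
making the expected raw scGAD ratio of a marker exactly the fold in its
target type and exactly 1 elsewhere (verified on the generating rates).

Default study conditions: 3 types x 100 cells, one 60-bin chromosome at
1 Mb, library sigma 0.35, dropout 0.3, single batch.  Batch experiments use
2 types x 60 cells, 30 bins, 2 batches with band-multiplier sigma 0.6
(batches balanced within type so they are never confounded).  Marker
recovery uses 2 types x 100 cells on a 200-bin chromosome with 20 planted
genes.  These sizes keep every experiment deterministic and desk-scale
while leaving the planted structure clearly recoverable; dropout is
Bernoulli thinning to a hard zero, exactly the observation model the ZINB
fitter assumes.

What the generator does **not** emulate: spatial dependence between
adjacent locus pairs, realistic chromosome-scale compartment checkerboards,
translocations or copy-number effects, cell-cycle variation in decay, or
any real dataset's marginal statistics.  Passing tests therefore
demonstrate correctness of the implementations and recoverability of
planted structure under the model's own assumptions — not performance on
real tissue data.

## Sparse-cell filters

Two published-style filters are provided: at 1 Mb, a cell is removed if on
any chromosome its number of non-zero locus pairs is strictly below `x/6`
(`x` = chromosome length in Mb, not rounded); at higher resolutions, a cell
is removed if its fraction of zero entries exceeds 0.999 on any chromosome.
Both are idempotent.  Y and mitochondrial chromosomes are excluded at
load time by default; X is kept.  Inter-chromosomal records are dropped
(and counted) — all modeling is intra-chromosomal.

## Known limitations

* The variational fit is full-batch; for datasets with tens of thousands
  of cells a minibatch schedule would be preferable.
* The band model treats locus pairs as exchangeable within a band given
  `z`; no spatial smoothing across neighboring pairs is attempted.
* The scGAD per-cell z-standardization makes scores comparable within a
  cell but means a cell with few scoreable genes has noisy scores; genes
  missing in many cells are flagged rather than imputed.
* Louvain's community count is not perfectly monotone in the resolution
  parameter in general; the binary search therefore keeps the
  closest-count labeling seen rather than assuming convergence.
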