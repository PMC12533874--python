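# Methods

## Problem and model

Given a spots × genes count matrix `X` with per-spot 2-D coordinates, the goal
is an unsupervised partition of spots into spatially coherent domains. The
model couples three ingredients: (i) graph convolutions over a spatial KNN
graph `A_s` and an expression (cosine) KNN graph `A_f`, (ii) corruption-based
contrastive learning in the deep-graph-infomax style, and (iii) a
zero-inflated negative binomial (ZINB) autoencoder on the raw counts.

### Graphs

Directed k-nearest-neighbour edges (self excluded) are symmetrised by union:
an undirected edge survives if either endpoint selected the other. Union
symmetrisation keeps small-k graphs connected; ties in distance break
deterministically by (distance, node index). Convolutions use
`D̃^{-1/2}(A+I)D̃^{-1/2}` with `D̃` the degree matrix of `A+I`. Platform
defaults for the spatial graph are k=25 (10x Visium) and k=50 (Stereo-seq);
the feature graph reuses the spatial k unless configured. Note that row sums
of the normalised operator are *not* bounded by 1 for irregular graphs (a star
centre exceeds 1); the operator's spectrum, however, lies in (−1, 1], and row
sums are exactly 1 for regular graphs — these are the properties the tests
assert.

The feature graph is built over spots (cosine distance between spot
expression profiles): every propagation rule uses `A_f` as a spots × spots
operator, so a gene-level graph would be shape-inconsistent.

### Encoder, attention, discriminator

Five ReLU-GCN stacks (depth 2, widths [128, 64] by default) encode: spatial
(`W_s`), feature (`W_f`), co-convolution of X through both graphs with shared
`W_c` (averaged into `H_c`), and co-convolution of the corrupted `X_c` with
shared `W_cl`. Corruption shuffles whole spot rows with a fresh uniform
permutation each epoch (the permutation stream is seeded by the run seed);
graphs stay fixed, so each corrupted spot keeps a genuine profile at a wrong
location.

Attention scores each view per spot as `w2ᵀ·tanh(W1·h + b)` with parameters
shared across views (two distinct parameter sets — an inner matrix and an
outer vector — since a single matrix in both roles would be
shape-inconsistent), softmaxes the three scores onto the simplex and returns
the weighted sum.

The discriminator scores spot `i` against a graph summary `s` as
`sigmoid(z_iᵀ B s)` where `B` is a learned bilinear form and `s` is the
average readout `mean_rows(D̃^{-1/2}ÃD̃^{-1/2} H)`. By default the summaries
come from the co-convolution embeddings (`H_sc` with `A_s`, `H_fc` with
`A_f`), which is the pairing the contrastive construction compares against
`H_c`; a config switch (`readout_source="view"`) uses the view-specific
embeddings instead. The two discrimination directions (clean-vs-summary and
corrupted-vs-summary, swapped) are fused by a learned two-way softmax into the
per-view contrastive labels.

### Decoder and likelihood

A tanh layer maps the fused H to the bottleneck `Z` (default width 32; this is
what K-means clusters, with a `cluster_on="H"` switch); a second tanh layer on
Z feeds three heads: π by a logistic link, μ by an exponential link (clamped
pre-exp to ±30) scaled per spot by the size factor, and θ by softplus clamped
to [1e-4, 1e4]. θ is per-gene by default (standard ZINB-autoencoder practice,
far fewer parameters at this scale) with a per-entry option. Size factors are
spot total counts divided by the median total — the concrete meaning given to
the per-spot bias. The ZINB NLL uses log-gamma throughout; the zero branch
`log(π + (1−π)·exp(θ·log(θ/(θ+μ))))` is stable because the inner exponent is
nonpositive and π is clamped to [1e-6, 1−1e-6].

### Objective

`L = α·L_zinb + ((L_pos + L_neg)/2)·β + L_con·γ` with defaults
(α, β, γ) = (1, 1, 10). `L_con` row-normalises the two co-convolution
embeddings (zero rows map to zero and are logged), forms their Gram matrices
and takes the mean-square difference (division by N² keeps the scale
independent of spot count; a raw-Gram switch exists). The contrastive terms
are standard binary cross-entropy with clean spots targeted to 1 and
corrupted to 0, averaged over the two graph views; scores at exactly {0, 1}
are clamped to [1e-7, 1−1e-7]. Ablations: `no_zinb` sets α=0, `no_coconv`
sets β=γ=0.

Training is full-graph Adam (lr 1e-3, weight decay 5e-4, 200 epochs by
default) on CPU, fully deterministic given the seed; a non-finite loss aborts
with the last finite epoch reported.

## Preprocessing

Genes expressed in fewer than `min_cells` spots (default 100) are removed;
optional `min_genes` (per spot) and `min_counts` (per gene) filters serve
probe-panel platforms and are off by default — published descriptions of
such extra filters often conflate gene- and cell-level thresholds, so both
knobs are exposed explicitly rather than guessing an interpretation. Counts are library-size normalised to the median total
and log1p-transformed for the encoder; the post-filter raw counts are kept in
a `counts` layer because the ZINB likelihood lives on count scale. Filtering
always recomputes from the raw-count layer, making the operation idempotent.
HVG selection keeps the genes with highest Seurat-flavour normalised
dispersion (scanpy implementation), with raw dispersion as a deterministic
tie-break for degenerate bins.

## Synthetic data generator

The generator emulates an array-based section: spots on an `n_rows × n_cols`
lattice, `n_domains` contiguous domains, counts from NB(mean, θ) with an
independent Bernoulli zero-mask of probability `dropout_pi` (the ZINB mixture
form). Each domain multiplies its own disjoint block of
`n_marker_genes_per_domain` genes by `fold_change`.

Domains are grown around uniformly drawn seed spots by a best-first flood
fill on the 4-neighbour lattice ordered by Euclidean distance to the claiming
seed — a geodesically constrained Voronoi partition. Plain nearest-seed
assignment can leave disconnected slivers on a lattice; the flood fill keeps
the compact Voronoi geometry while guaranteeing 4-connected domains. One seed
sequence is split into independent streams for layout, marker assignment,
counts and dropout, so changing one knob leaves the other draws intact.

Defaults (30×30 lattice, 4 domains, 200 genes, fold change 4, dropout 0.1,
30 markers per domain, base mean 0.5, θ = 0.5) emulate a curated marker panel
in the sparse UMI regime: ~70% zeros, strong overdispersion, and a majority
of the panel domain-informative — the situation probe-panel platforms are
designed for. In this regime expression-only clustering is good but
imperfect, which is exactly where the spatial graph earns its keep. What the
generator does *not* model: histology, platform-specific noise, doublets,
ambient RNA, within-domain expression gradients, or irregular (non-lattice)
spot geometry — so passing recovery tests demonstrates correct mechanics and
a real spatial advantage on idealised tissue, not performance on any
particular real platform.

## Evaluation protocol

K-means (k-means++, 20 restarts, fixed seed) on Z, labels renumbered by
descending cluster size; the cluster count is user-supplied, as in annotated
real-data practice. ARI (pair-counting, chance-corrected) and NMI
(arithmetic-mean normalisation) against the annotation; unlabeled spots are
excluded from scoring only. The benchmark replicate
(`dmgcn.pipeline.synthetic_benchmark`) runs the fixture with spatial k = 10 —
a local neighbourhood appropriate for a 30×30 lattice, chosen as a per-dataset
setting the way the platform k values are — trains 200 epochs, and computes
the graph-free reference as K-means on a 30-component PCA of the same
normalised matrix. Fixture evaluations use the full 200-gene panel without an
HVG cut: on a narrow-mean panel the binned dispersion z-score demotes true
markers (a known artifact of the binning, also why probe-panel data is used
with mild or no HVG cuts).

## Numerical and design notes

* **Autodiff.** The network trains through a small reverse-mode engine on
  float64 numpy (sparse graph operators enter as constants); Adam is
  implemented alongside. Every op is checked against central finite
  differences in the tests. Full-graph training at desk scale takes ~0.2 s
  per epoch for 900 spots × 200 genes on one CPU.
* **Contrastive loss form.** A positive/negative loss that sums `log D` and
  `log(1−D)` of the *same* score is minimised at D = 0.5 and cannot separate
  positives from negatives; the standard DGI cross-entropy (clean→1,
  corrupted→0) is used.
* **Decoder parameters.** Each decoder layer has its own weights and bias;
  nothing is tied across layers.
* **Training dynamics.** Training the joint objective *degrades* the
  co-convolution embedding relative to its untrained state (the consistency
  term is easiest satisfied by near-degenerate embeddings both graphs agree
  on); the ZINB term is what anchors the latent space to expression content.
  This is why the ZINB-ablated variant collapses (ARI ≈ 0 on the fixture) —
  the strongest qualitative reproduction of the ablation ordering — and why
  clustering uses the decoder bottleneck rather than `H_c`.
* **Known limitations.** No mini-batching (full-graph only), no histology
  features, no multi-slice integration, no automatic cluster-count selection.
  At heavy noise levels (very sparse panels with few markers) the trained
  model can fall below its own untrained encoder; see the training-dynamics
  note above.
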