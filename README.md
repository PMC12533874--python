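# dmgcn — spatial-domain identification with a multi-view GCN

Spatial transcriptomics assays (10x Visium, Stereo-seq, MERFISH, …) measure a
counts matrix **X** over *spots* that carry 2-D tissue coordinates. A central
analysis task is **spatial-domain identification**: partitioning the spots
into contiguous regions with coherent expression — cortical layers, tumour
regions, embryonic organs. Expression-only clustering ignores where spots sit;
this package implements a multi-view graph convolutional model that uses both.

## The model

Two KNN graphs are built over the spots: a **spatial graph** `A_s` (Euclidean
distance on coordinates; default k = 25 for Visium, 50 for Stereo-seq) and a
**feature graph** `A_f` (cosine distance on expression profiles). Each graph
is used through its self-loop symmetric normalisation
`D̃^{-1/2}(A + I)D̃^{-1/2}`. The encoder runs five propagation stacks of the
form `H^{(l+1)} = ReLU(D̃^{-1/2}ÃD̃^{-1/2} H^{(l)} W^{(l)})`:

* a spatial branch (`W_s`) and a feature branch (`W_f`) on X;
* a **co-convolution** branch pushing X through *both* graphs with shared
  weights `W_c`, averaged into the joint embedding `H_c`;
* the same co-convolution applied with weights `W_cl` to **corrupted**
  features `X_c` (spot rows shuffled, graphs fixed) — the negatives for
  contrastive learning.

A per-spot attention softmax fuses the three views,
`H = φ_s·H_s + φ_f·H_f + φ_c·H_c`. A graph-smoothed average readout summarises
each graph; a bilinear discriminator scores spots against the summary, and
clean/corrupted scores are trained with binary cross-entropy. A fully
connected decoder maps H to a bottleneck **Z** (clustered by K-means) and to
the π / μ / θ heads of a **zero-inflated negative binomial** reconstruction of
the raw counts, with per-spot size factors as the bias.

The objective is

```
L = α·L_zinb + ( (L_pos + L_neg)/2 )·β + L_con·γ ,     (α, β, γ) = (1, 1, 10)
```

where `L_con` is the squared Frobenius distance between the row-normalised
Gram matrices of the two co-convolution embeddings and `L_zinb` the ZINB
negative log-likelihood. Ablation switches disable the ZINB term or the
contrastive/consistency block. Everything trains full-graph on CPU through a
small reverse-mode autodiff engine included in the package.

## Worked example

`examples/03_train_and_cluster.py` simulates a 15×15 synthetic tissue with 3
planted contiguous domains, trains for 60 epochs and clusters the bottleneck:

```
total loss: 1.805 (epoch 0) -> 1.635 (epoch 59)
model     ARI 0.985  NMI 0.977
PCA+KMeans ARI 0.957  NMI 0.932  (no spatial graph)
```

ARI/NMI score agreement with the planted domains (1 = perfect); the model
beats the graph-free PCA+K-means reference because the spatial graph smooths
noisy per-spot profiles toward their neighbourhood. The other examples cover
simulation (`01`), preprocessing and graph construction (`02`) and the
ablation comparison (`04` — removing the ZINB term collapses recovery to
ARI ≈ 0.02).

A thin CLI mirrors the stages:

```bash
dmgcn simulate --config sim.yaml --out fixture/
dmgcn preprocess --in fixture/ --format tsv --config pp.yaml --out processed.h5ad
dmgcn train --data processed.h5ad --config run.yaml --n-clusters 4 --out run/
dmgcn cluster --run run/ --n-clusters 7
dmgcn evaluate --run run/ --truth fixture/labels.tsv
```

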