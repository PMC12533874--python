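"""Filter, normalise and build the two KNN graphs the encoder convolves over.

The spatial graph connects Euclidean-nearest spots (platform defaults: k=25
for 10x Visium, k=50 for Stereo-seq); the feature graph connects spots with
cosine-similar expression profiles.
"""

import numpy as np

from dmgcn import (
    PreprocessConfig,
    SimConfig,
    build_graphs,
    default_k,
    filter_and_normalize,
    select_hvg,
    simulate_dataset,
)

adata = simulate_dataset(SimConfig(n_rows=15, n_cols=15, seed=1))
pp = filter_and_normalize(adata, PreprocessConfig(min_cells=1))
print(f"after filtering: {pp.shape}; X is log1p of median-library-size counts")
print(f"size factors: min {pp.obs['size_factors'].min():.2f}, "
      f"max {pp.obs['size_factors'].max():.2f}")

hvg = select_hvg(pp, 100)
print(f"top-100 HVG subset: {hvg.shape}")

g_s, g_f = build_graphs(pp, spatial_k=8)
for name, g in (("spatial", g_s), ("feature", g_f)):
    deg = np.ravel(g.adjacency.sum(axis=1))
    print(f"{name} graph: {g.adjacency.nnz // 2} edges, "
          f"mean degree {deg.mean():.1f} (k={g.k}, metric={g.metric})")
print(f"platform defaults: Visium k={default_k('visium')}, "
      f"Stereo-seq k={default_k('stereo-seq')}")

# Degrees exceed k because directed KNN edges are symmetrised by union; the
# normalised operator D^-1/2 (A+I) D^-1/2 is what the convolutions use.
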