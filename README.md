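# spagnn3d

Subcellular spatial-transcriptomics analysis in 3D: from single-transcript
detection to cell–cell-communication (CCC) motifs.

Imaging-based spatial transcriptomics (seqFISH/HCR-FISH, MERFISH) resolves
individual RNA molecules in three dimensions. Most analysis tools collapse
this to per-cell expression and discard where transcripts sit *inside* the
cell. `spagnn3d` keeps the subcellular geometry: each cell is partitioned
into spatially contiguous **patches** of transcripts, the local tendency of
gene pairs to be immediate neighbors is scored by permutation, and the
spatial arrangement of those scores across a cell is embedded with a graph
autoencoder whose explanations point at the patches and gene pairs that
drive cell–cell communication.

It is written for computational biologists working with decoded transcript
tables (gene, x, y, z, cell) or raw 3D image stacks plus a segmentation
mask. A synthetic-data module generates fully ground-truthed inputs for
every stage, so the whole pipeline is testable without microscopy data.

## The method

1. **Spot detection.** Diffraction-limited dots are located in a
   maximum-intensity projection across z (Laplacian-of-Gaussian detector);
   each dot's depth is the slice with the highest local intensity at its
   (x, y), with a default axial step of 0.3 μm. Cell identity comes from a
   segmentation label mask.
2. **Patches.** Within each cell, Leiden clustering of a k-nearest-neighbor
   graph over transcript 3D positions yields spatial patches; per-patch
   gene counts and the per-cell gene–gene Pearson correlation across
   patches follow.
3. **Gene proximity.** Within each patch, a kNN graph over transcripts
   defines immediate neighbors. For each unordered gene pair (g, h) the
   number of graph edges joining a g-transcript to an h-transcript is
   compared to a null obtained by shuffling all gene labels 500 times with
   positions fixed:

       z(g,h) = (observed − mean_perm) / sd_perm

   Positive z: the pair co-localizes more than chance. A per-patch **gene
   neighborhood network** connects pairs with |z| > 0.5.
4. **Graph autoencoder.** Patch centers connected to their 2 nearest
   patches form the patch graph; node features are the proximity-score
   vectors. A two-layer graph-convolutional encoder maps them to a latent
   space and an inner-product decoder p_ij = σ(⟨z_i, z_j⟩) reconstructs
   edges; the reconstruction loss
   L = −log(mean_pos p) − log(mean_neg (1−p)) is minimized on a 70/10/20
   edge split with link-prediction AUC on held-out edges as the metric.
5. **CCC structure.** A 2D Voronoi tessellation over patch centers marks
   patches whose ridge crosses a cell boundary as **border patches**
   (homotypic or heterotypic by the partner cell's expression cluster);
   explainability masks on the encoder (edge + feature masks optimized to
   preserve a border patch's embedding) extract the high-importance
   subgraph — the **CCC motif** — and rank the gene pairs that drive it.
   Microenvironment queries (30 μm balls), Delaunay cell graphs and
   shortest intercellular patch edges support tissue-scale analyses.
6. **Statistics & classification.** Mann–Whitney tests with
   Bonferroni-corrected α and the standard star legend; a harness compares
   logistic regression / SVM / random forest / kNN across four per-cell
   feature sets (RNA counts, patch gene correlation, proximity-network
   variation, pooled embeddings).

## Worked example

```python
import numpy as np
from spagnn3d import (SimConfig, simulate_point_cloud, cluster_patches,
                      cell_proximity_profiles, profiles_to_matrix,
                      patch_knn_graph, patches_to_frame, combine_graphs,
                      GraphAutoencoder)

cfg = SimConfig(n_cells=2, patches_per_cell=10, transcripts_per_patch=50, seed=3)
table, truth = simulate_point_cloud(cfg)

graphs = []
for cell_id, cell in table.groupby("cell_id"):
    patches, membership = cluster_patches(cell, cfg.panel, seed=0)
    profiles = cell_proximity_profiles(cell, membership, cfg.panel, seed=0)
    X, _ = profiles_to_matrix(profiles, cfg.panel)
    graphs.append(patch_knn_graph(patches_to_frame(patches), k=2, X=X,
                                  feature_names=cfg.panel.pair_labels()))

combined, _ = combine_graphs(graphs)
results = GraphAutoencoder(combined, hidden_dim=16, latent_dim=8, seed=0).fit()
print(results.summary())
```

prints (numbers from this exact run):

```
Graph autoencoder (2-layer GCN encoder, inner-product decoder)
==============================================================
nodes: 71   edges: 86   features: 45
hidden_dim: 16   latent_dim: 8   dropout: 0.5   loss: log_mean
split: 60/9/17 (train/val/test edges)
epochs run: 85   final train loss: 0.3719
best val AUC: 0.7531
test AUC: 0.7405   test AP: 0.7922
```

71 patches across the two simulated cells, each carrying its 45-dimensional
gene-pair proximity profile (the default 10-gene panel has 10·9/2 = 45
unordered pairs); the autoencoder reconstructs held-out patch
adjacencies with test AUC ≈ 0.74 on 17 test edges — well above chance for a
graph this small. `results.embeddings` and `results.pool()` feed the
downstream classification and motif steps.

A shell-level pipeline is available through the `spagnn3d` CLI
(`simulate`, `detect`, `patch`, `proximity`, `embed`).

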