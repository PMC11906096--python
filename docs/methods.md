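# Methods

This note documents the models and procedures implemented in `spagnn3d`,
the parameters that matter, the synthetic-data regime the tests run in, and
the design choices made where the design was genuinely open.

## Coordinate conventions

All coordinates are physical micrometers, origin at the field-of-view
corner, 0-based. Depth is quantized by the axial sampling:
`z_um = slice_index × z_step_um`, with a default z-step of 0.3 μm (fine
enough that diffraction-limited spots span several slices). Transcripts
outside every segmentation label carry the sentinel `cell_id = −1`; they
are excluded from per-cell analyses but participate in microenvironment
(radius-ball) queries, because extracellular signal is real signal in a
hydrogel.

## Spot detection and depth assignment

Detection operates on the maximum-intensity projection across z. The
detector is a Laplacian-of-Gaussian filter with σ matched to the lateral
PSF width (default 1.5 px), peak extraction with a minimum separation
(default 3 px), and an intensity floor (default: 99.5th percentile of the
projected image — a robust threshold when spots occupy a small fraction of
pixels; always overridable). Depth is the slice maximizing mean intensity
in a (2·w+1)² window (default w = 1 px) at the spot's (x, y); ties take the
lowest slice. Subpixel localization is deliberately omitted: the pipeline's
downstream statistics operate at patch scale (~μm), two orders of magnitude
above the pixel.

On the rendered benchmark (200 spots, anisotropic Gaussian PSF
σ_xy = 0.15 μm / σ_z = 0.4 μm, Gaussian read noise, amplitude/noise = 10)
the defaults give recall, precision and ±1-slice depth accuracy ≥ 0.95
(measured at 100% in the acceptance run).

## Patch clustering

Within one cell, a symmetrized kNN graph (default k = 15) over transcript
positions (x, y, z·z_weight; z_weight default 1.0, i.e. raw micrometers) is
partitioned with Leiden (RB-configuration modularity). The resolution
default (10.0) is set so a ~1,000-transcript cell of typical extent yields
roughly 40–50 patches — the granularity at which per-patch proximity
statistics have enough transcripts to be defined while still resolving
subcellular structure. Clusters under `min_patch_size` (default 5) merge
into the nearest surviving cluster by center distance, smallest first.
Patch numbering is canonicalized by lexicographic center sort, so row order
of the input cannot change patch identity.

## Proximity scores

Immediate-neighborhood structure inside a patch is a kNN graph over
transcripts (default k = 5), built from directed k-nearest relations
symmetrized by union — an edge exists if either endpoint lists the other.
Union (rather than mutual-kNN) makes counts refer to unordered transcript
pairs and sets the scale of the null; distance ties resolve to the lower
row index, making the graph fully deterministic.

For each unordered gene pair, the observed edge count is z-scored against
500 label permutations (positions and graph fixed, all gene labels
shuffled). A pair whose permutation SD is zero (e.g. single-gene patches)
is *undefined*: encoded as 0 with a parallel boolean mask so feature
matrices stay rectangular. Self-pairs (a gene with itself) are computed but
excluded from the node-feature vector; the feature length is always
C(panel, 2), derived from the active panel.

Calibration: with random labels the scores are approximately standard
normal — over 200 simulated 60-transcript patches the per-pair mean is
within ±0.2 of 0 and the SD within [0.95, 1.07]. On patches of ≤ 7
transcripts the sampled score agrees with exact enumeration of all
permutations within Monte-Carlo error. The per-patch gene neighborhood
network connects pairs with |z| > 0.5 (scores within half a null SD of
expectation are treated as unremarkable); detection power for a planted
fully-paired colocalization at 0.1 μm offset exceeds 95% for 100-transcript
patches (power grows roughly as the square root of patch size, since the
planted edge count scales with the source-gene count while the null SD
scales with its square root).

## Spatial graphs

* Patch graph: each patch connects to its k nearest patches by 3D center
  distance (default k = 2; configurable, as some analyses use 3).
* Border patches: Voronoi adjacency on (x, y) only — a 3D tessellation
  would connect patches across the tops of flattened cells. Computed via
  the Delaunay dual with convex-hull (infinite-ridge) edges dropped; a
  ridge joining patches of two different cells marks both as border patches
  and the cells as interacting. Degenerate collinear input is jittered by
  1e-9 μm with a warning.
* Homotypic/heterotypic: a border patch is homotypic with respect to a
  partner iff the partner cell's expression cluster equals its own; the
  labeling is invariant under renaming clusters.
* Microenvironment: closed 3D ball (default radius 30 μm) around a
  reference point, extracellular transcripts included; the n nearest
  patches (default 5) rank by center distance with patch-id tie-break.
* Cell graphs: 3D Delaunay adjacency over cell centroids (centroid of the
  cell's transcripts), with optional maximum-edge pruning; ≤ 4 points fall
  back to the complete graph. Neighborhoods are closed one-hop sets.
  Intercellular CCC edges are Delaunay edges over neighborhood patch
  centers with exactly one endpoint in the central cell, partner-filtered,
  with the 3 shortest kept by default.

Every geometric primitive is tested against an O(n²) brute-force oracle.

## Graph autoencoder

Encoder: `Z = Â · dropout(relu(Â X W₁)) · W₂` with
`Â = D̃^{-1/2}(A+I)D̃^{-1/2}`. Decoder: `p_ij = σ(⟨z_i, z_j⟩)`, clamped to
[1e-7, 1−1e-7]. Loss (default variant):

    L = −log(mean over positive pairs of p) − log(mean over negative pairs of (1−p))

with a standard mean-BCE variant available; both vanish exactly at perfect
reconstruction, and at mean p_pos = mean (1−p_neg) = 0.5 the default loss
equals 2·ln 2. The negative term is estimated by uniform sampling of
verified non-edges, one per positive, resampled each epoch for training and
fixed for validation/test; enumerating all non-edges is intractable and the
sampled estimator is the standard one. A complete graph has no non-edges
and is rejected — the reconstruction target requires sparsity.

Edges split 70/10/20 (train/validation/test). Message passing uses
**training edges only**: held-out edges must not leak into the encoder's
receptive field, otherwise link-prediction metrics are inflated.

Training: pure NumPy with manual backpropagation and Adam (lr 0.01), ReLU
after layer 1, inverted dropout (default rate 0.5) on the hidden layer,
Glorot-uniform init, ≤ 300 epochs with early stopping on validation AUC
(patience 30). Defaults: hidden 32, latent 100 for real panels (the
examples and fixtures use smaller latent dims matched to their feature
counts); a seeded exhaustive grid search over (hidden, latent) is provided,
ties resolved toward the smaller model. Everything is deterministic given
the seed.

### What link-prediction AUC can reach on the SBM fixture

The stress fixture is a 200-node stochastic block model (2 equal
communities, intra/inter edge probabilities 0.08/0.005, density ≈ 0.04)
with community-informative Gaussian node features. In a pure SBM,
conditional on community memberships all edges are independent, so a
held-out edge is independent of the training graph and features given
communities: the Bayes-optimal link predictor reduces to the
intra/inter-community indicator. Because ~48% of uniformly sampled
non-edges are intra-community, that oracle's AUC is ≈ 0.73–0.76 on this
fixture — an information-theoretic ceiling. The trained autoencoder
reaches ≈ 0.72, i.e. close to the ceiling, and reliably exceeds both the
untrained-encoder baseline and a degree-only baseline; those relative
comparisons, not an absolute AUC, are the meaningful test of training on
this fixture. (On geometric patch graphs from the worked example, where
adjacency is predictable from latent structure, held-out AUC is limited
only by sample size.)

## Explainability and motifs

The encoder is unsupervised, so the explanation objective preserves the
*embedding* rather than a class score: sigmoid-parameterized masks over the
edges of the target's 2-hop computation subgraph and over feature columns
minimize

    ‖z_masked(target) − z_full(target)‖² + λ_size·Σm + λ_ent·Σ entropy(m)

(λ_size = 0.005, λ_ent = 0.1, 200 Adam iterations, lr 0.1). Degree
normalization stays fixed at the unmasked graph so the forward pass is
differentiable in the masks alone. Mask logits start slightly below zero
(m ≈ 0.45): the fidelity term pulls influential masks toward 1 while both
regularizers push uninfluential ones toward 0 — with a trivial
(constant-output) encoder all masks shrink. Node importance is the max
(optionally mean) of incident edge masks, with the target fixed at 1; the
CCC motif is the set of nodes with importance ≥ 0.5 (plus the target) and
their induced edges, and per-gene-pair importance is the feature-mask mean
across targets. On fixtures where a single feature column determines the
embeddings, that column ranks first in ≥ 9/10 seeds.

## Statistics and classification

Group comparisons use the two-sided Mann–Whitney–Wilcoxon test. The
significance *level* is Bonferroni-corrected (α/n_comparisons) while star
annotations follow the raw-p legend exactly: ns > 5e-2 ≥ * > 1e-2 ≥ ** >
1e-3 ≥ *** > 1e-4 ≥ ****.

The four per-cell feature sets for the classifier harness are: raw RNA
counts; the upper triangle of the patch gene-correlation matrix (undefined
entries 0 + mask); "network variation" — per gene pair, the sample SD
(ddof = 1) of the proximity score across the cell's patches over defined
entries, an interpretation chosen because no formal definition exists for
this feature set; and mean-pooled autoencoder embeddings. Classifiers
(logistic regression, SVM, random forest, kNN) run with library defaults,
stratified 80/20 splits shared across the grid within a seed, and
standardization fit on the training fold only.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure the pipeline assumes:
disjoint ellipsoidal cells with axial extent one tenth of lateral (the
flattened geometry of gel-cultured cells), isotropic Gaussian patches,
planted colocalization by displaced partner points (a Neyman–Scott-style
pairing whose effect on immediate-neighbor counts is analytically
controllable), two-population negative-binomial expression, sparse SBM
patch graphs, and Gaussian-PSF image rendering with read noise. They do
not model optical aberrations, molecular crowding or quenching, segmentation
errors, cell-shape irregularity, or spatially varying expression within a
patch. Passing tests therefore demonstrate correctness of the algorithms
under their stated assumptions, not performance on real microscopy data.

Default study conditions: 2–4 cells of radius 15 μm, 8–25 patches/cell of
σ = 1 μm, 50–100 transcripts/patch, 5–10 gene panels; the SBM fixture is
200 nodes / 2 communities as above. Problem sizes throughout are chosen so
the full suite and the acceptance script each complete in well under a
minute while keeping every statistical check adequately powered.

## Numerical choices and degenerate inputs

* Probabilities clamped to [1e-7, 1−1e-7]; permutation SD of 0 ⇒ undefined
  score (masked, reported 0).
* kNN distance ties: lower index wins (exact O(n²) path below 2,000
  points; above, a tree query with a re-sorted candidate window).
* Leiden, splits, negative sampling, dropout, mask init: all seeded;
  per-patch seeds derive from a SeedSequence so patches are independent
  but reproducible.
* Degenerate inputs: single-slice TIFFs become one-slice stacks with a
  warning; collinear Voronoi input is jittered; < knn_k+1 transcripts form
  one patch; two cells' centers closer than twice the radius are rejected
  as over-packed; axially flat intensity profiles assign slice 0.

## Known limitations

* The spot detector and its thresholds are reasonable defaults for
  diffraction-limited dots, not a claim about any particular instrument.
* Patch granularity depends on the Leiden resolution; the 40–50
  patches/kilotranscript default is a calibration, not a biological claim.
* The proximity score's scale depends on the kNN k and the symmetrization
  convention; comparisons are only meaningful at fixed settings.
* Link-prediction AUC on block-model graphs has an information ceiling
  (see above); absolute AUC values are fixture-dependent.
* Multi-round registration and segmentation are assumed done upstream.
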