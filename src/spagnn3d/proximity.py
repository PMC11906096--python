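"""Permutation-based pairwise gene proximity within patches.

Within each patch, a nearest-neighbor graph among transcripts defines which
transcripts are immediate spatial neighbors.  The number of graph edges
connecting each gene pair is compared against a null built by shuffling the
gene label of every transcript (default 500 shuffles) while keeping
positions and the graph fixed.  The proximity score of a pair is the
z-score of the observed edge count under that null: positive z means the
two genes are immediate neighbors more often than random placement of
labels would produce.

A pair's score is undefined when the permutation SD is zero (e.g. a patch
containing a single gene); undefined scores are encoded as 0 with a parallel
boolean mask so node-feature matrices stay rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import networkx as nx
import numpy as np
import pandas as pd

from .io import GenePanel
from .spatial_graphs import symmetric_knn_edges

DEFAULT_N_PERM = 500
EDGE_Z_THRESHOLD = 0.5


@dataclass
class ProximityProfile:
    """Per-patch pairwise gene-proximity z-scores in fixed panel-pair order."""

    patch_id: int
    z: np.ndarray  # cross pairs, panel order; undefined entries are 0
    observed: np.ndarray  # observed pair-edge counts
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    defined: np.ndarray  # boolean; z meaningful where True
    self_z: np.ndarray | None = None  # per-gene self-pair scores (optional)


def transcript_knn_graph(points: np.ndarray, k: int = 5) -> np.ndarray:
    """Undirected kNN edge set over transcript 3D positions.

    Directed k-nearest-neighbor relations (Euclidean) are symmetrized by
    union: an edge is present if either endpoint lists the other among its
    k nearest.  Needs >= 2 points.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need >= 2 transcripts for a neighbor graph")
    return symmetric_knn_edges(points, k)


def _pair_key(gi: np.ndarray, gj: np.ndarray, n_genes: int) -> np.ndarray:
    """Collapse an (ordered) gene-index pair to an unordered bucket key."""
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    return lo * n_genes + hi


def count_pair_edges(edges: np.ndarray, gene_idx: np.ndarray, n_genes: int) -> np.ndarray:
    """Count neighbor-graph edges per unordered gene pair.

    Returns a dense (n_genes, n_genes) upper-triangular count matrix whose
    diagonal holds self-pairs; each undirected edge increments exactly one
    bucket, so the total equals the number of edges.
    """
    counts = np.zeros(n_genes * n_genes, dtype=np.int64)
    if len(edges):
        keys = _pair_key(gene_idx[edges[:, 0]], gene_idx[edges[:, 1]], n_genes)
        np.add.at(counts, keys, 1)
    return counts.reshape(n_genes, n_genes)


def _cross_pair_flat_keys(panel: GenePanel) -> np.ndarray:
    n = len(panel)
    keys = [i * n + j for i in range(n) for j in range(i + 1, n)]
    return np.array(keys, dtype=np.int64)


def permutation_proximity(points: np.ndarray, genes: np.ndarray, panel: GenePanel,
                          *, patch_id: int = 0, k: int = 5,
                          n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                          edges: np.ndarray | None = None) -> ProximityProfile:
    """Pairwise gene-proximity z-scores for one patch.

    Positions and the neighbor graph stay fixed; the gene labels are
    permuted uniformly ``n_perm`` times (default 500).  For each unordered
    pair, z = (observed - mean_perm) / sd_perm.  Deterministic given seed.
    """
    genes = np.asarray(genes)
    n = len(genes)
    gidx = np.array([panel.index(g) for g in genes], dtype=np.int64)
    if edges is None:
        edges = transcript_knn_graph(points, k)
    n_genes = len(panel)
    observed_full = count_pair_edges(edges, gidx, n_genes)

    rng = np.random.default_rng(seed)
    perm_counts = _permuted_counts(edges, gidx, n_genes, n_perm, rng)
    return _profile_from_counts(patch_id, panel, observed_full, perm_counts)


def _permuted_counts(edges: np.ndarray, gidx: np.ndarray, n_genes: int,
                     n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_genes*n_genes) pair-edge counts under label shuffling."""
    n = len(gidx)
    nkeys = n_genes * n_genes
    out = np.zeros((n_perm, nkeys), dtype=np.int64)
    if len(edges) == 0:
        return out
    perm_labels = np.empty((n_perm, n), dtype=np.int64)
    for p in range(n_perm):
        perm_labels[p] = gidx[rng.permutation(n)]
    gu = perm_labels[:, edges[:, 0]]
    gv = perm_labels[:, edges[:, 1]]
    keys = _pair_key(gu, gv, n_genes)  # (n_perm, n_edges)
    flat = keys + (np.arange(n_perm)[:, None] * nkeys)
    counts = np.bincount(flat.ravel(), minlength=n_perm * nkeys)
    return counts.reshape(n_perm, nkeys)


def _profile_from_counts(patch_id: int, panel: GenePanel, observed_full: np.ndarray,
                         perm_counts: np.ndarray) -> ProximityProfile:
    n_genes = len(panel)
    cross_keys = _cross_pair_flat_keys(panel)
    self_keys = np.arange(n_genes) * n_genes + np.arange(n_genes)

    mean = perm_counts.mean(axis=0)
    sd = perm_counts.std(axis=0, ddof=0)
    obs_flat = observed_full.reshape(-1).astype(float)

    def z_for(keys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        s = sd[keys]
        defined = s > 0
        z = np.zeros(len(keys))
        z[defined] = (obs_flat[keys][defined] - mean[keys][defined]) / s[defined]
        return z, obs_flat[keys], mean[keys], s, defined

    z, obs, m, s, defined = z_for(cross_keys)
    self_z, *_ = z_for(self_keys)
    return ProximityProfile(patch_id=patch_id, z=z, observed=obs.astype(np.int64),
                            perm_mean=m, perm_sd=s, defined=defined, self_z=self_z)


def exhaustive_proximity(points: np.ndarray, genes: np.ndarray, panel: GenePanel,
                         *, patch_id: int = 0, k: int = 5,
                         edges: np.ndarray | None = None,
                         max_n: int = 9) -> ProximityProfile:
    """Exact proximity scores by enumerating every label permutation.

    Tractable only for tiny patches (n! permutations); used as the exact
    reference the sampled null converges to.
    """
    genes = np.asarray(genes)
    n = len(genes)
    if n > max_n:
        raise ValueError(f"exhaustive enumeration limited to n <= {max_n}")
    gidx = np.array([panel.index(g) for g in genes], dtype=np.int64)
    if edges is None:
        edges = transcript_knn_graph(points, k)
    n_genes = len(panel)
    observed_full = count_pair_edges(edges, gidx, n_genes)
    all_perms = np.array(list(iter_permutations(range(n))), dtype=np.int64)
    perm_labels = gidx[all_perms]
    nkeys = n_genes * n_genes
    if len(edges):
        gu = perm_labels[:, edges[:, 0]]
        gv = perm_labels[:, edges[:, 1]]
        keys = _pair_key(gu, gv, n_genes) + np.arange(len(all_perms))[:, None] * nkeys
        perm_counts = np.bincount(keys.ravel(), minlength=len(all_perms) * nkeys).reshape(len(all_perms), nkeys)
    else:
        perm_counts = np.zeros((len(all_perms), nkeys), dtype=np.int64)
    return _profile_from_counts(patch_id, panel, observed_full, perm_counts)


def profiles_to_matrix(profiles: list[ProximityProfile], panel: GenePanel
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Stack profiles into a rectangular (n_patches, n_pairs) node-feature
    matrix (undefined entries 0) plus the boolean defined mask."""
    if not profiles:
        return np.empty((0, panel.n_pairs)), np.empty((0, panel.n_pairs), dtype=bool)
    X = np.stack([p.z for p in profiles])
    mask = np.stack([p.defined for p in profiles])
    return X, mask


def gene_network(profile: ProximityProfile, panel: GenePanel,
                 gene_counts: np.ndarray | None = None,
                 threshold: float = EDGE_Z_THRESHOLD) -> nx.Graph:
    """Per-patch gene neighborhood network.

    Nodes are panel genes present in the patch (node size attribute = patch
    gene count when provided); an edge joins a pair exactly when its score
    is defined and |z| > threshold (default 0.5: pairs within one SD of the
    random expectation are considered unremarkable).  Edge weight = signed z.
    """
    g = nx.Graph()
    counts = gene_counts if gene_counts is not None else np.ones(len(panel), dtype=np.int64)
    for gene, c in zip(panel.genes, counts):
        if c > 0:
            g.add_node(gene, size=int(c))
    for (a, b), z, ok in zip(panel.pairs, profile.z, profile.defined):
        if ok and abs(z) > threshold and a in g and b in g:
            g.add_edge(a, b, weight=float(z))
    return g


def cell_proximity_profiles(cell: pd.DataFrame, membership: np.ndarray, panel: GenePanel,
                            *, k: int = 5, n_perm: int = DEFAULT_N_PERM,
                            seed: int = 0) -> list[ProximityProfile]:
    """Proximity profiles for every patch of one cell.

    ``membership`` is the per-row patch assignment from patch clustering.
    Patches with fewer than 2 transcripts get an all-undefined profile.
    Each patch uses an independent child seed derived from ``seed``.
    """
    cell = cell.reset_index(drop=True)
    pts = cell[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    genes = cell["gene"].to_numpy()
    profiles = []
    ss = np.random.SeedSequence(seed)
    labels = np.unique(membership)
    child_seeds = ss.generate_state(len(labels))
    for label, child in zip(labels, child_seeds):
        sel = membership == label
        if sel.sum() < 2:
            npairs = panel.n_pairs
            profiles.append(ProximityProfile(
                patch_id=int(label), z=np.zeros(npairs),
                observed=np.zeros(npairs, dtype=np.int64),
                perm_mean=np.zeros(npairs), perm_sd=np.zeros(npairs),
                defined=np.zeros(npairs, dtype=bool)))
            continue
        profiles.append(permutation_proximity(
            pts[sel], genes[sel], panel, patch_id=int(label), k=k,
            n_perm=n_perm, seed=int(child % (2**31))))
    return profiles
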