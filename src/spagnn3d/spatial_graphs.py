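"""Spatial graph construction: patch nearest-neighbor graphs, Voronoi
border-patch detection, Delaunay cell graphs, microenvironments and
intercellular communication edges.

All distances are Euclidean in micrometers.  Cell-level Voronoi adjacency is
computed in 2D (x, y) only — a 3D tessellation would connect patches across
the tops of cells — via the Delaunay dual, discarding ridges that extend to
the unbounded region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, Voronoi, cKDTree


@dataclass
class PatchGraph:
    """A graph over subcellular patches.

    nodes
        ``nodes`` is a DataFrame with columns ``patch_id``, ``cell_id``,
        ``x_um``, ``y_um``, ``z_um`` (one row per node, row order = node
        order).
    edges
        ``edges`` is an (n_edges, 2) int array of node *positions* (row
        indices into ``nodes``), undirected, deduplicated, no self-loops,
        each pair stored once with u < v.
    X
        Optional (n_nodes, n_features) float node-feature matrix, row-aligned
        to ``nodes``; columns named by ``feature_names``.
    """

    nodes: pd.DataFrame
    edges: np.ndarray
    X: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    node_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if len(self.edges):
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            self.edges = canonical_edges(self.edges)
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.shape[0] != len(self.nodes):
                raise ValueError("feature matrix not row-aligned to nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def centers(self) -> np.ndarray:
        return self.nodes[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency (no self-loops)."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        if len(self.edges):
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, row in self.nodes.iterrows():
            attrs = dict(
                patch_id=int(row["patch_id"]),
                cell_id=int(row["cell_id"]),
                center=[float(row["x_um"]), float(row["y_um"]), float(row["z_um"])],
            )
            if self.X is not None:
                attrs["features"] = self.X[i].tolist()
            g.add_node(int(i), **attrs)
        g.add_edges_from((int(u), int(v)) for u, v in self.edges)
        g.graph["feature_names"] = list(self.feature_names)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "PatchGraph":
        order = sorted(g.nodes())
        rows, feats = [], []
        for n in order:
            a = g.nodes[n]
            cx, cy, cz = a["center"]
            rows.append(dict(patch_id=a["patch_id"], cell_id=a["cell_id"], x_um=cx, y_um=cy, z_um=cz))
            if "features" in a:
                feats.append(a["features"])
        pos = {n: i for i, n in enumerate(order)}
        edges = np.array([[pos[u], pos[v]] for u, v in g.edges()], dtype=np.int64).reshape(-1, 2)
        X = np.asarray(feats, dtype=float) if feats else None
        return cls(pd.DataFrame(rows), edges, X, list(g.graph.get("feature_names", [])))


def canonical_edges(edges: np.ndarray) -> np.ndarray:
    """Sort each edge (u < v), deduplicate, sort lexicographically."""
    e = np.sort(np.asarray(edges, dtype=np.int64).reshape(-1, 2), axis=1)
    e = np.unique(e, axis=0)
    return e


def symmetric_knn_edges(points: np.ndarray, k: int) -> np.ndarray:
    """Directed kNN on Euclidean distance, symmetrized by union.

    An undirected edge u–v is present if v is among u's k nearest
    neighbors or vice versa.  Distance ties are broken by lower index
    (cKDTree returns the lower index first for exact ties).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    k_eff = min(k, n - 1)
    edges = []
    if n <= 2000:
        # exact lexicographic (distance, index) ordering
        d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        for u in range(n):
            order = np.lexsort((np.arange(n), d2[u]))
            edges.extend((u, int(v)) for v in order[:k_eff])
    else:
        # tree query with a candidate window re-sorted for tie determinism
        tree = cKDTree(points)
        m = min(n, k_eff + 9)
        dist, idx = tree.query(points, k=m)
        for u in range(n):
            cand = [(round(float(d), 9), int(v)) for d, v in zip(dist[u], idx[u]) if v != u]
            cand.sort()
            edges.extend((u, v) for _, v in cand[:k_eff])
    return canonical_edges(np.array(edges))


def patch_knn_graph(patches: pd.DataFrame, k: int = 2, X: np.ndarray | None = None,
                    feature_names: Sequence[str] = ()) -> PatchGraph:
    """Patch nearest-neighbor graph for one cell: each patch is connected to
    its k nearest patches by 3D center distance (default k=2), symmetrized.
    """
    nodes = patches.reset_index(drop=True)
    pts = nodes[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if len(nodes) < 2:
        edges = np.empty((0, 2), dtype=np.int64)
    else:
        edges = symmetric_knn_edges(pts, k)
    return PatchGraph(nodes, edges, X, list(feature_names))


def combine_graphs(graphs: Sequence[PatchGraph]) -> tuple[PatchGraph, list[np.ndarray]]:
    """Disjoint union of per-cell patch graphs.

    Node features and edges are concatenated; no cross-cell edges are
    added.  Returns the combined graph and, per input graph, the array of
    global node positions its rows were mapped to.
    """
    if not graphs:
        empty = pd.DataFrame(columns=["patch_id", "cell_id", "x_um", "y_um", "z_um"])
        return PatchGraph(empty, np.empty((0, 2), dtype=np.int64)), []
    frames, edge_blocks, feats, index_maps = [], [], [], []
    offset = 0
    names = graphs[0].feature_names
    for g in graphs:
        frames.append(g.nodes)
        if len(g.edges):
            edge_blocks.append(g.edges + offset)
        if g.X is not None:
            feats.append(g.X)
        index_maps.append(np.arange(g.n_nodes) + offset)
        offset += g.n_nodes
    nodes = pd.concat(frames, ignore_index=True)
    edges = (np.concatenate(edge_blocks) if edge_blocks
             else np.empty((0, 2), dtype=np.int64))
    X = np.concatenate(feats) if feats else None
    return PatchGraph(nodes, edges, X, names), index_maps


# ---------------------------------------------------------------------------
# Voronoi border patches and homotypic/heterotypic labels
# ---------------------------------------------------------------------------

def _finite_voronoi_edges(xy: np.ndarray) -> np.ndarray:
    """Point-index pairs sharing a *finite* 2D Voronoi ridge.

    Computed from the Delaunay dual: every Delaunay edge is dual to a
    Voronoi ridge, and the ridges that extend to the unbounded region are
    exactly those dual to convex-hull edges, which are dropped.
    """
    tri = Delaunay(xy)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                u, v = int(simplex[a]), int(simplex[b])
                edges.add((min(u, v), max(u, v)))
    hull = set()
    for a, b in tri.convex_hull:
        u, v = int(a), int(b)
        hull.add((min(u, v), max(u, v)))
    finite = sorted(edges - hull)
    return np.array(finite, dtype=np.int64).reshape(-1, 2)


def voronoi_interactions(patches: pd.DataFrame) -> tuple[pd.DataFrame, set[tuple[int, int]]]:
    """Detect border patches and interacting cell pairs within one FOV.

    Only x and y positions are used to build the Voronoi tessellation.  A
    ridge connecting patches of two different cells marks both patches as
    border patches and the two cells as interacting (symmetric, irreflexive
    at the cell level).  Ridges to the unbounded region are ignored.

    Returns a DataFrame (patch_id, cell_id, partner_cell_id) with one row
    per border patch per partner cell, and the set of interacting cell
    pairs (a < b).
    """
    patches = patches.reset_index(drop=True)
    if len(patches) < 4:
        raise ValueError("need >= 4 patches for a 2D Voronoi tessellation")
    xy = patches[["x_um", "y_um"]].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(xy - xy.mean(0), tol=1e-9)
    if rank < 2:
        warnings.warn("degenerate (collinear) patch positions; jittering by 1e-9 um")
        rng = np.random.default_rng(0)
        xy = xy + rng.normal(scale=1e-9, size=xy.shape)
    edges = _finite_voronoi_edges(xy)
    cells = patches["cell_id"].to_numpy()
    records: list[dict] = []
    pairs: set[tuple[int, int]] = set()
    for u, v in edges:
        cu, cv = int(cells[u]), int(cells[v])
        if cu == cv:
            continue
        records.append(dict(patch_id=int(patches.loc[u, "patch_id"]), cell_id=cu, partner_cell_id=cv))
        records.append(dict(patch_id=int(patches.loc[v, "patch_id"]), cell_id=cv, partner_cell_id=cu))
        pairs.add((min(cu, cv), max(cu, cv)))
    borders = (pd.DataFrame(records, columns=["patch_id", "cell_id", "partner_cell_id"])
               .drop_duplicates().reset_index(drop=True))
    return borders, pairs


def label_homo_hetero(borders: pd.DataFrame, cluster_labels: dict[int, int]) -> pd.DataFrame:
    """Label each border-patch record homotypic or heterotypic.

    A border patch is homotypic with respect to a partner cell iff the
    partner's expression cluster equals its own cell's cluster.  A patch
    whose ridges touch cells of both kinds keeps one record per partner.
    """
    out = borders.copy()
    own = out["cell_id"].map(cluster_labels)
    partner = out["partner_cell_id"].map(cluster_labels)
    if own.isna().any() or partner.isna().any():
        raise ValueError("cluster label missing for some cell")
    out["interaction_type"] = np.where(own == partner, "homotypic", "heterotypic")
    return out


# ---------------------------------------------------------------------------
# microenvironments and nearest patches
# ---------------------------------------------------------------------------

def microenvironment(transcripts: pd.DataFrame, center_point: Sequence[float],
                     radius_um: float = 30.0) -> pd.DataFrame:
    """All transcripts within ``radius_um`` (closed 3D Euclidean ball) of a
    reference point — the transcriptional microenvironment.  Extracellular
    transcripts (cell_id = -1) are included."""
    pts = transcripts[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    d = np.linalg.norm(pts - np.asarray(center_point, dtype=float), axis=1)
    return transcripts.loc[d <= radius_um].reset_index(drop=True)


def nearest_patches(patches: pd.DataFrame, center_point: Sequence[float], n: int = 5) -> pd.DataFrame:
    """The n patches nearest to a reference point by ascending 3D center
    distance; ties broken by patch_id."""
    pts = patches[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    d = np.linalg.norm(pts - np.asarray(center_point, dtype=float), axis=1)
    order = np.lexsort((patches["patch_id"].to_numpy(), d))
    return patches.iloc[order[: min(n, len(patches))]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Delaunay cell graphs and intercellular CCC edges
# ---------------------------------------------------------------------------

def delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Undirected edges of the Delaunay triangulation of 3D points.

    Degenerate inputs (fewer than 5 points, or coplanar) fall back to the
    complete graph, which is the correct limit for <= 4 points in general
    position.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    complete = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=np.int64)
    if n <= 4:
        return complete
    try:
        tri = Delaunay(points)
    except Exception:
        return complete
    edges = set()
    for simplex in tri.simplices:
        m = len(simplex)
        for a in range(m):
            for b in range(a + 1, m):
                u, v = int(simplex[a]), int(simplex[b])
                edges.add((min(u, v), max(u, v)))
    return np.array(sorted(edges), dtype=np.int64).reshape(-1, 2)


def delaunay_cell_graph(cell_centers: pd.DataFrame, max_edge_um: float | None = None) -> nx.Graph:
    """Cell adjacency from the 3D Delaunay triangulation of cell centers.

    ``cell_centers``: DataFrame with cell_id, x_um, y_um, z_um (cell center
    = centroid of the cell's transcripts).  Optionally prune edges longer
    than ``max_edge_um``.
    """
    cc = cell_centers.reset_index(drop=True)
    pts = cc[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    edges = delaunay_edges(pts)
    g = nx.Graph()
    for _, row in cc.iterrows():
        g.add_node(int(row["cell_id"]), center=(float(row["x_um"]), float(row["y_um"]), float(row["z_um"])))
    ids = cc["cell_id"].to_numpy()
    for u, v in edges:
        length = float(np.linalg.norm(pts[u] - pts[v]))
        if max_edge_um is not None and length > max_edge_um:
            continue
        g.add_edge(int(ids[u]), int(ids[v]), length_um=length)
    return g


def astrocyte_neighborhood(cell_graph: nx.Graph, center_cell: int) -> set[int]:
    """Closed one-hop neighborhood of a central cell in the cell graph."""
    if center_cell not in cell_graph:
        raise KeyError(f"cell {center_cell} not in graph")
    return {center_cell} | set(cell_graph.neighbors(center_cell))


def intercellular_ccc_edges(patches: pd.DataFrame, central_cell: int, n_edges: int = 3,
                            partner_cells: Iterable[int] | None = None) -> pd.DataFrame:
    """Shortest intercellular patch edges out of a central cell.

    A Delaunay triangulation over all patch centers in the neighborhood
    yields candidate edges; those with exactly one endpoint in the central
    cell are intercellular.  Optionally only partners in ``partner_cells``
    (e.g. neurons) are kept; the ``n_edges`` shortest by 3D length survive.
    The central-cell endpoints are the interacting (CCC) patches.

    Returns a DataFrame sorted by length with columns central_patch_id,
    partner_patch_id, partner_cell_id, length_um.
    """
    p = patches.reset_index(drop=True)
    pts = p[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    cells = p["cell_id"].to_numpy()
    pids = p["patch_id"].to_numpy()
    edges = delaunay_edges(pts)
    rows = []
    for u, v in edges:
        cu, cv = int(cells[u]), int(cells[v])
        if (cu == central_cell) == (cv == central_cell):
            continue  # keep edges with exactly one endpoint in the central cell
        if cu != central_cell:
            u, v, cu, cv = v, u, cv, cu
        if partner_cells is not None and cv not in set(partner_cells):
            continue
        rows.append(dict(central_patch_id=int(pids[u]), partner_patch_id=int(pids[v]),
                         partner_cell_id=cv, length_um=float(np.linalg.norm(pts[u] - pts[v]))))
    rows.sort(key=lambda r: (r["length_um"], r["central_patch_id"], r["partner_patch_id"]))
    return pd.DataFrame(rows[:n_edges],
                        columns=["central_patch_id", "partner_patch_id", "partner_cell_id", "length_um"])
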