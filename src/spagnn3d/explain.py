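"""Post-hoc attribution on the trained graph encoder and CCC-motif
extraction.

For a target patch (typically a border patch), sigmoid-parameterized masks
over the edges of its 2-hop computation subgraph and over the gene-pair
feature columns are optimized by gradient descent so that the masked
encoder preserves the target's embedding while the masks stay small:

    minimize  ||z_masked(target) - z_full(target)||^2
              + lam_size * sum(mask) + lam_ent * entropy(mask)

Edges and patches that cannot be suppressed without moving the embedding
receive mask values near 1 — these high-importance patches and the induced
edges among them form the cell-interaction (CCC) motif.  The encoder here
is unsupervised, so the fidelity term is embedding preservation rather than
a class score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gae import Weights, _Adam
from .spatial_graphs import PatchGraph


@dataclass
class ExplanationMask:
    """Edge/feature importance masks for one target node.

    ``sub_edges`` are the edges (node-position pairs) of the target's
    computation subgraph; ``edge_mask`` aligns with them.  All mask values
    lie in [0, 1] by sigmoid parameterization.  ``node_importance`` maps a
    node position to the aggregate of its incident edge masks (the target
    itself is fixed at 1).
    """

    target: int
    sub_edges: np.ndarray
    edge_mask: np.ndarray
    feature_mask: np.ndarray
    node_importance: dict[int, float]
    final_loss: float


@dataclass
class Motif:
    """A high-importance subgraph around a target patch."""

    target: int
    nodes: np.ndarray  # node positions, ascending; always contains target
    edges: np.ndarray  # induced edges among nodes
    node_importance: dict[int, float]


def computation_subgraph(graph: PatchGraph, target: int, n_hops: int = 2
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Nodes reachable from the target in <= n_hops plus the edge index of
    edges among them (the receptive field of a 2-layer encoder)."""
    frontier = {int(target)}
    seen = set(frontier)
    adj: dict[int, set[int]] = {}
    for u, v in graph.edges:
        adj.setdefault(int(u), set()).add(int(v))
        adj.setdefault(int(v), set()).add(int(u))
    for _ in range(n_hops):
        frontier = {w for u in frontier for w in adj.get(u, ())} - seen
        seen |= frontier
    nodes = np.array(sorted(seen), dtype=np.int64)
    node_set = set(nodes.tolist())
    idx = [i for i, (u, v) in enumerate(graph.edges)
           if int(u) in node_set and int(v) in node_set]
    return nodes, np.array(idx, dtype=np.int64)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def explain_node(graph: PatchGraph, weights: Weights, target: int, *,
                 n_iters: int = 200, lam_size: float = 0.005, lam_ent: float = 0.1,
                 lr: float = 0.1, seed: int = 0, node_agg: str = "max") -> ExplanationMask:
    """Learn edge and feature importance masks for one node's embedding.

    The degree normalization of the graph convolution is held fixed at the
    unmasked graph's degrees so that the masked forward pass is
    differentiable in the mask alone.  Deterministic given ``seed``.  An
    isolated target yields an empty edge mask; the feature mask is still
    optimized.
    """
    if graph.X is None:
        raise ValueError("graph has no node features")
    X = graph.X
    n, f_dim = X.shape
    t = int(target)
    _, edge_idx = computation_subgraph(graph, t)
    sub_edges = graph.edges[edge_idx] if len(edge_idx) else np.empty((0, 2), dtype=np.int64)

    # fixed symmetric normalization from the unmasked graph
    deg = np.ones(n) + np.zeros(n)
    a_full = graph.adjacency()
    dinv = 1.0 / np.sqrt(a_full.sum(axis=1) + 1.0)
    nrm = dinv[:, None] * dinv[None, :]

    rng = np.random.default_rng(seed)
    # logits start just below 0 (mask slightly under 0.5): the fidelity term
    # pulls influential masks toward 1 while for uninfluential ones both the
    # size and the entropy regularizer point toward 0
    theta_e = rng.normal(-0.2, 0.05, size=len(sub_edges))
    theta_f = rng.normal(-0.2, 0.05, size=f_dim)

    # reference embedding of the target under the full graph
    z_full = _masked_forward(X, a_full, nrm, weights, sub_edges,
                             np.ones(len(sub_edges)), np.ones(f_dim))[0][t]

    opt = _Adam([theta_e.shape, theta_f.shape], lr)
    loss = np.nan
    for _ in range(n_iters):
        m_e = _sigmoid(theta_e)
        m_f = _sigmoid(theta_f)
        (Z, cache) = _masked_forward(X, a_full, nrm, weights, sub_edges, m_e, m_f)
        d = Z[t] - z_full
        data = float(d @ d)
        ent_e = _entropy(m_e).sum() if len(m_e) else 0.0
        loss = data + lam_size * (m_e.sum() + m_f.sum()) + lam_ent * (ent_e + _entropy(m_f).sum())
        g_me, g_mf = _masked_backward(d, cache, X, weights, sub_edges, t)
        g_me += lam_size + lam_ent * _entropy_grad(m_e)
        g_mf += lam_size + lam_ent * _entropy_grad(m_f)
        g_te = g_me * m_e * (1.0 - m_e)
        g_tf = g_mf * m_f * (1.0 - m_f)
        opt.step([theta_e, theta_f], [g_te, g_tf])

    m_e = _sigmoid(theta_e)
    m_f = _sigmoid(theta_f)
    importance: dict[int, float] = {}
    for (u, v), m in zip(sub_edges, m_e):
        for w in (int(u), int(v)):
            if node_agg == "max":
                importance[w] = max(importance.get(w, 0.0), float(m))
            else:
                importance.setdefault(w, 0.0)
    if node_agg == "mean":
        sums: dict[int, list[float]] = {}
        for (u, v), m in zip(sub_edges, m_e):
            for w in (int(u), int(v)):
                sums.setdefault(w, []).append(float(m))
        importance = {w: float(np.mean(v)) for w, v in sums.items()}
    importance[t] = 1.0
    return ExplanationMask(target=t, sub_edges=sub_edges, edge_mask=m_e,
                           feature_mask=m_f, node_importance=importance,
                           final_loss=float(loss))


def _entropy(m: np.ndarray) -> np.ndarray:
    m = np.clip(m, 1e-7, 1 - 1e-7)
    return -(m * np.log(m) + (1 - m) * np.log(1 - m))


def _entropy_grad(m: np.ndarray) -> np.ndarray:
    m = np.clip(m, 1e-7, 1 - 1e-7)
    return -np.log(m / (1 - m))


def _masked_forward(X, a_full, nrm, weights, sub_edges, m_e, m_f):
    n = len(X)
    W = a_full.copy()
    if len(sub_edges):
        W[sub_edges[:, 0], sub_edges[:, 1]] = m_e
        W[sub_edges[:, 1], sub_edges[:, 0]] = m_e
    W[np.arange(n), np.arange(n)] = 1.0  # self-loops
    a_hat = W * nrm
    Xm = X * m_f[None, :]
    P1 = a_hat @ Xm
    pre = P1 @ weights.W1
    H = np.maximum(pre, 0.0)
    P2 = a_hat @ H
    Z = P2 @ weights.W2
    cache = dict(a_hat=a_hat, nrm=nrm, Xm=Xm, P1=P1, pre=pre, H=H)
    return Z, cache


def _masked_backward(d, cache, X, weights, sub_edges, t):
    """Gradients of the data term w.r.t. edge masks and feature masks."""
    a_hat, nrm, Xm, pre, H = cache["a_hat"], cache["nrm"], cache["Xm"], cache["pre"], cache["H"]
    n = a_hat.shape[0]
    dZ = np.zeros((n, weights.W2.shape[1]))
    dZ[t] = 2.0 * d
    dP2 = dZ @ weights.W2.T
    dA = dP2 @ H.T
    dH = a_hat.T @ dP2
    dpre = dH * (pre > 0)
    dP1 = dpre @ weights.W1.T
    dA += dP1 @ Xm.T
    dXm = a_hat.T @ dP1
    g_mf = np.sum(dXm * X, axis=0)
    if len(sub_edges):
        u, v = sub_edges[:, 0], sub_edges[:, 1]
        g_me = dA[u, v] * nrm[u, v] + dA[v, u] * nrm[v, u]
    else:
        g_me = np.empty(0)
    return g_me, g_mf


def extract_motif(mask: ExplanationMask, graph: PatchGraph, node_threshold: float = 0.5) -> Motif:
    """Threshold node importance to obtain the CCC motif: nodes with
    importance >= threshold plus the target, and the induced edges."""
    keep = {w for w, imp in mask.node_importance.items() if imp >= node_threshold}
    keep.add(mask.target)
    nodes = np.array(sorted(keep), dtype=np.int64)
    edges = np.array([[u, v] for u, v in graph.edges
                      if int(u) in keep and int(v) in keep], dtype=np.int64).reshape(-1, 2)
    return Motif(target=mask.target, nodes=nodes, edges=edges,
                 node_importance={w: mask.node_importance.get(w, 0.0) for w in keep})


def rank_feature_importance(masks: list[ExplanationMask]) -> tuple[np.ndarray, np.ndarray]:
    """Mean feature-mask value per gene pair across targets, descending.

    Returns (feature indices by rank, mean importance per feature in
    original order).  Permuting the list of targets cannot change the
    ranking.
    """
    if not masks:
        raise ValueError("no masks to rank")
    mean = np.mean([m.feature_mask for m in masks], axis=0)
    order = np.argsort(-mean, kind="stable")
    return order, mean


def pool_motif(motif: Motif, embeddings: np.ndarray, profiles: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Average-pool embedded features and gene-proximity profiles over the
    motif's nodes (a single-node motif returns that node's own vectors)."""
    idx = motif.nodes
    return embeddings[idx].mean(axis=0), profiles[idx].mean(axis=0)
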