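"""Graph autoencoder for embedding patch proximity profiles.

A two-layer graph-convolutional encoder maps each patch's pairwise
gene-proximity vector into a latent space (default 100 dimensions); an
inner-product decoder predicts edge probabilities
p_ij = sigmoid(<z_i, z_j>), and the reconstruction error against the true
patch nearest-neighbor edges is backpropagated into the convolution
weights.  Edges are split 70/10/20 into train/validation/test; link
prediction on held-out edges (against sampled non-edges) measures the
embedding quality.

The graph must be sparse: if no non-edges exist the reconstruction target
is degenerate and fitting refuses to start.

Implementation is pure NumPy: the encoder is
``Z = Â · dropout(relu(Â X W1)) · W2`` with the symmetric degree-normalized
adjacency ``Â = D̃^{-1/2}(A+I)D̃^{-1/2}``, trained with Adam and manual
backpropagation.

Two reconstruction-loss variants are provided:

``log_mean``
    ``L = -log(mean_pos p) - log(mean_neg (1-p))`` — the log of mean
    predicted probability over positive pairs plus the log of mean
    complement over negative pairs.
``bce``
    standard mean binary cross-entropy over positive and negative pairs.

Both are zero exactly in the perfect-reconstruction limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .spatial_graphs import PatchGraph

EPS = 1e-7


@dataclass
class GAEConfig:
    hidden_dim: int = 32
    latent_dim: int = 100
    dropout_rate: float = 0.5
    loss_variant: str = "log_mean"  # or "bce"
    learning_rate: float = 0.01
    max_epochs: int = 300
    patience: int = 30
    train_frac: float = 0.7
    val_frac: float = 0.1
    test_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.hidden_dim < 1 or self.latent_dim < 1:
            raise ValueError("layer dims must be >= 1")
        if self.loss_variant not in ("log_mean", "bce"):
            raise ValueError("loss_variant must be 'log_mean' or 'bce'")


@dataclass
class EdgeSplit:
    """Disjoint train/val/test positive edges plus verified non-edge
    negatives for val/test (train negatives are resampled every epoch)."""

    train_pos: np.ndarray
    val_pos: np.ndarray
    test_pos: np.ndarray
    val_neg: np.ndarray
    test_neg: np.ndarray


@dataclass
class Weights:
    W1: np.ndarray
    W2: np.ndarray

    def copy(self) -> "Weights":
        return Weights(self.W1.copy(), self.W2.copy())


def normalized_adjacency(graph: PatchGraph, edges: np.ndarray | None = None) -> np.ndarray:
    """Symmetric degree-normalized adjacency with self-loops.

    ``edges`` restricts the adjacency to a subset (e.g. training edges
    only, so held-out edges never enter message passing).
    """
    n = graph.n_nodes
    if edges is None:
        a = graph.adjacency() + np.eye(n)
    else:
        a = np.eye(n)
        if len(edges):
            a[edges[:, 0], edges[:, 1]] = 1.0
            a[edges[:, 1], edges[:, 0]] = 1.0
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return a * dinv[:, None] * dinv[None, :]


def _sample_non_edges(n_nodes: int, edge_set: set[tuple[int, int]], n_samples: int,
                      rng: np.random.Generator) -> np.ndarray:
    max_pairs = n_nodes * (n_nodes - 1) // 2
    if len(edge_set) >= max_pairs:
        raise ValueError("graph not sparse; autoencoder undefined")
    out: list[tuple[int, int]] = []
    while len(out) < n_samples:
        u = rng.integers(0, n_nodes, size=2 * (n_samples - len(out)) + 8)
        v = rng.integers(0, n_nodes, size=len(u))
        for a, b in zip(u, v):
            if a == b:
                continue
            e = (min(int(a), int(b)), max(int(a), int(b)))
            if e in edge_set:
                continue
            out.append(e)
            if len(out) == n_samples:
                break
    return np.array(out, dtype=np.int64)


def split_edges(graph: PatchGraph, config: GAEConfig) -> EdgeSplit:
    """Uniform random 70/10/20 edge split with matched sampled negatives.

    Negatives are drawn uniformly from verified non-edges, one per positive
    in each held-out split.  Raises if the graph is complete (no non-edges).
    """
    rng = np.random.default_rng(config.seed)
    edges = graph.edges
    m = len(edges)
    if m == 0:
        raise ValueError("graph has no edges to split")
    edge_set = graph.edge_set()
    if len(edge_set) >= graph.n_nodes * (graph.n_nodes - 1) // 2:
        raise ValueError("graph not sparse; autoencoder undefined")
    perm = rng.permutation(m)
    n_test = int(round(config.test_frac * m))
    n_val = int(round(config.val_frac * m))
    test = edges[perm[:n_test]]
    val = edges[perm[n_test:n_test + n_val]]
    train = edges[perm[n_test + n_val:]]
    val_neg = _sample_non_edges(graph.n_nodes, edge_set, len(val), rng)
    test_neg = _sample_non_edges(graph.n_nodes, edge_set, len(test), rng)
    return EdgeSplit(train_pos=train, val_pos=val, test_pos=test,
                     val_neg=val_neg, test_neg=test_neg)


def init_weights(n_features: int, config: GAEConfig, rng: np.random.Generator) -> Weights:
    """Glorot-uniform initialization."""
    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    return Weights(glorot(n_features, config.hidden_dim),
                   glorot(config.hidden_dim, config.latent_dim))


def encode(graph: PatchGraph, weights: Weights, *, dropout_rate: float = 0.0,
           training: bool = False, rng: np.random.Generator | None = None,
           a_hat: np.ndarray | None = None):
    """Two-layer graph-convolution encoding of the node features.

    Evaluation mode (``training=False``) is deterministic; in training mode
    an inverted-dropout mask zeroes a ``dropout_rate`` fraction of hidden
    features.  Returns (Z, cache) where cache carries the intermediates
    needed for backpropagation.
    """
    if graph.X is None:
        raise ValueError("graph has no node features")
    if a_hat is None:
        a_hat = normalized_adjacency(graph)
    ax = a_hat @ graph.X
    pre = ax @ weights.W1
    h = np.maximum(pre, 0.0)
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.uniform(size=h.shape) >= dropout_rate) / (1.0 - dropout_rate)
        hd = h * mask
    else:
        mask = np.ones_like(h)
        hd = h
    ah = a_hat @ hd
    z = ah @ weights.W2
    cache = dict(a_hat=a_hat, ax=ax, pre=pre, mask=mask, ah=ah)
    return z, cache


def decode_edge_prob(z_i: np.ndarray, z_j: np.ndarray) -> np.ndarray:
    """p_ij = sigmoid(<z_i, z_j>), clamped away from {0, 1}; symmetric in
    its arguments."""
    s = np.sum(np.asarray(z_i) * np.asarray(z_j), axis=-1)
    p = 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
    return np.clip(p, EPS, 1.0 - EPS)


def _edge_probs(z: np.ndarray, edges: np.ndarray) -> np.ndarray:
    if len(edges) == 0:
        return np.empty(0)
    return decode_edge_prob(z[edges[:, 0]], z[edges[:, 1]])


def reconstruction_loss(p_pos: np.ndarray, p_neg: np.ndarray, variant: str = "log_mean"):
    """Reconstruction loss over predicted edge probabilities.

    Returns (L, positive term, negative term).  Both variants are >= 0 and
    approach 0 as p_pos -> 1 and p_neg -> 0.
    """
    p_pos = np.clip(p_pos, EPS, 1 - EPS)
    p_neg = np.clip(p_neg, EPS, 1 - EPS)
    if variant == "log_mean":
        pos_term = -np.log(np.mean(p_pos))
        neg_term = -np.log(np.mean(1.0 - p_neg))
    elif variant == "bce":
        pos_term = -np.mean(np.log(p_pos))
        neg_term = -np.mean(np.log(1.0 - p_neg))
    else:
        raise ValueError(f"unknown loss variant {variant!r}")
    return pos_term + neg_term, pos_term, neg_term


def _loss_grad_wrt_p(p_pos: np.ndarray, p_neg: np.ndarray, variant: str):
    if variant == "log_mean":
        gpos = -1.0 / (len(p_pos) * np.mean(p_pos))
        gneg = 1.0 / (len(p_neg) * np.mean(1.0 - p_neg))
        return np.full(len(p_pos), gpos), np.full(len(p_neg), gneg)
    gpos = -1.0 / (len(p_pos) * p_pos)
    gneg = 1.0 / (len(p_neg) * (1.0 - p_neg))
    return gpos, gneg


def link_prediction_metrics(z: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> dict:
    p = np.concatenate([_edge_probs(z, pos), _edge_probs(z, neg)])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return dict(auc=float(roc_auc_score(y, p)), ap=float(average_precision_score(y, p)))


def pool_embeddings(z: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-pool node embeddings per group (e.g. per cell).

    Returns (group ids sorted, pooled matrix); a single-node group pools to
    its own embedding.
    """
    groups = np.asarray(groups)
    ids = np.unique(groups)
    pooled = np.stack([z[groups == g].mean(axis=0) for g in ids])
    return ids, pooled


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class GraphAutoencoder:
    """Graph-autoencoder model over a :class:`PatchGraph`.

    Parameters are held in a :class:`GAEConfig`; ``fit()`` trains with Adam
    and early stopping on validation link-prediction AUC and returns a
    :class:`GAEResults`.
    """

    def __init__(self, graph: PatchGraph, config: GAEConfig | None = None, **kwargs):
        if config is None:
            config = GAEConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        if graph.X is None:
            raise ValueError("graph has no node features")
        self.graph = graph
        self.config = config
        self.split = split_edges(graph, config)
        # message passing sees training edges only: held-out edges must not
        # leak into the encoder's receptive field
        self.a_hat = normalized_adjacency(graph, self.split.train_pos)
        self._rng = np.random.default_rng(config.seed)
        self.initial_weights = init_weights(graph.X.shape[1], config, self._rng)

    # -- forward passes ----------------------------------------------------
    def embed(self, weights: Weights | None = None) -> np.ndarray:
        """Deterministic (evaluation-mode) node embeddings."""
        w = weights if weights is not None else self.initial_weights
        z, _ = encode(self.graph, w, a_hat=self.a_hat)
        return z

    def evaluate(self, weights: Weights, which: str = "test") -> dict:
        """Link-prediction AUC/AP on a held-out split (untrained weights
        give the null baseline)."""
        z = self.embed(weights)
        pos = getattr(self.split, f"{which}_pos")
        neg = getattr(self.split, f"{which}_neg")
        return link_prediction_metrics(z, pos, neg)

    # -- training ----------------------------------------------------------
    def fit(self) -> "GAEResults":
        cfg = self.config
        graph, a_hat = self.graph, self.a_hat
        edge_set = graph.edge_set()
        w = self.initial_weights.copy()
        opt = _Adam([w.W1.shape, w.W2.shape], cfg.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0])

        best_val, best_w, best_epoch = -np.inf, w.copy(), 0
        train_losses, val_aucs = [], []
        n_pos = len(self.split.train_pos)
        for epoch in range(cfg.max_epochs):
            neg = _sample_non_edges(graph.n_nodes, edge_set, n_pos, rng)
            z, cache = encode(graph, w, dropout_rate=cfg.dropout_rate,
                              training=True, rng=rng, a_hat=a_hat)
            pos = self.split.train_pos
            p_pos = _edge_probs(z, pos)
            p_neg = _edge_probs(z, neg)
            loss, _, _ = reconstruction_loss(p_pos, p_neg, cfg.loss_variant)
            train_losses.append(float(loss))

            gW1, gW2 = self._backward(z, cache, w, pos, neg, p_pos, p_neg)
            opt.step([w.W1, w.W2], [gW1, gW2])

            val = self.evaluate(w, "val")["auc"] if len(self.split.val_pos) else np.nan
            val_aucs.append(val)
            if np.isfinite(val) and val > best_val + 1e-6:
                best_val, best_w, best_epoch = val, w.copy(), epoch
            if np.isfinite(val) and epoch - best_epoch >= cfg.patience:
                break

        if not np.isfinite(best_val):  # no validation edges: keep final weights
            best_w, best_val = w.copy(), np.nan
        test = self.evaluate(best_w, "test") if len(self.split.test_pos) else dict(auc=np.nan, ap=np.nan)
        return GAEResults(model=self, weights=best_w, embeddings=self.embed(best_w),
                          train_losses=np.array(train_losses), val_aucs=np.array(val_aucs),
                          best_val_auc=float(best_val), test_auc=test["auc"], test_ap=test["ap"],
                          n_epochs=len(train_losses))

    def _backward(self, z, cache, w, pos, neg, p_pos, p_neg):
        cfg = self.config
        gpos, gneg = _loss_grad_wrt_p(p_pos, p_neg, cfg.loss_variant)
        dz = np.zeros_like(z)
        for edges, p, gp in ((pos, p_pos, gpos), (neg, p_neg, gneg)):
            if len(edges) == 0:
                continue
            ds = gp * p * (1.0 - p)  # d loss / d <z_i, z_j>
            np.add.at(dz, edges[:, 0], ds[:, None] * z[edges[:, 1]])
            np.add.at(dz, edges[:, 1], ds[:, None] * z[edges[:, 0]])
        a_hat = cache["a_hat"]
        gW2 = cache["ah"].T @ dz
        dhd = (a_hat @ dz) @ w.W2.T
        dh = dhd * cache["mask"]
        dpre = dh * (cache["pre"] > 0)
        gW1 = cache["ax"].T @ dpre
        return gW1, gW2


@dataclass
class GAEResults:
    """Fitted graph-autoencoder: embeddings, metrics and diagnostics."""

    model: GraphAutoencoder
    weights: Weights
    embeddings: np.ndarray
    train_losses: np.ndarray
    val_aucs: np.ndarray
    best_val_auc: float
    test_auc: float
    test_ap: float
    n_epochs: int

    def pool(self, groups: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-group mean-pooled embeddings (default grouping: cell_id)."""
        if groups is None:
            groups = self.model.graph.nodes["cell_id"].to_numpy()
        return pool_embeddings(self.embeddings, groups)

    def summary(self) -> str:
        cfg = self.model.config
        g = self.model.graph
        lines = [
            "Graph autoencoder (2-layer GCN encoder, inner-product decoder)",
            "=" * 62,
            f"nodes: {g.n_nodes}   edges: {g.n_edges}   features: {g.X.shape[1]}",
            f"hidden_dim: {cfg.hidden_dim}   latent_dim: {cfg.latent_dim}   "
            f"dropout: {cfg.dropout_rate}   loss: {cfg.loss_variant}",
            f"split: {len(self.model.split.train_pos)}/{len(self.model.split.val_pos)}"
            f"/{len(self.model.split.test_pos)} (train/val/test edges)",
            f"epochs run: {self.n_epochs}   final train loss: {self.train_losses[-1]:.4f}",
            f"best val AUC: {self.best_val_auc:.4f}",
            f"test AUC: {self.test_auc:.4f}   test AP: {self.test_ap:.4f}",
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.train_losses, label="train loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("reconstruction loss")
        ax.legend()
        return ax


def grid_search(graph: PatchGraph, hidden_dims, latent_dims,
                config: GAEConfig | None = None) -> tuple[GAEConfig, GAEResults]:
    """Exhaustive (hidden, latent) grid search by validation AUC.

    Ties favor the smaller model (fewer parameters).  The returned results
    object is the winning fitted model.
    """
    base = config or GAEConfig()
    best = None
    for h in hidden_dims:
        for l in latent_dims:
            cfg = replace(base, hidden_dim=int(h), latent_dim=int(l))
            res = GraphAutoencoder(graph, cfg).fit()
            size = h * graph.X.shape[1] + h * l
            key = (-res.best_val_auc, size)
            if best is None or key < best[0]:
                best = (key, cfg, res)
    return best[1], best[2]
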