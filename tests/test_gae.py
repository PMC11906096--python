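import numpy as np
import pandas as pd
import pytest

from spagnn3d.gae import (GAEConfig, GraphAutoencoder, Weights, decode_edge_prob,
                          encode, grid_search, init_weights, normalized_adjacency,
                          pool_embeddings, reconstruction_loss, split_edges)
from spagnn3d.simulate import simulate_patch_graph
from spagnn3d.spatial_graphs import PatchGraph


def small_graph(n=20, f=6, seed=0, **kw):
    g, _ = simulate_patch_graph(n, f, n_communities=2, seed=seed, **kw)
    return g


class TestSplitEdges:
    def test_fractions_and_determinism(self):
        g = small_graph(80, 4, seed=1, intra_p=0.25, inter_p=0.05)
        cfg = GAEConfig(seed=5)
        s1 = split_edges(g, cfg)
        s2 = split_edges(g, cfg)
        m = g.n_edges
        assert len(s1.test_pos) == round(0.2 * m)
        assert len(s1.val_pos) == round(0.1 * m)
        assert len(s1.train_pos) == m - len(s1.test_pos) - len(s1.val_pos)
        np.testing.assert_array_equal(s1.train_pos, s2.train_pos)
        # splits disjoint, union = all edges
        all_edges = {tuple(e) for e in g.edges.tolist()}
        parts = [set(map(tuple, s.tolist())) for s in (s1.train_pos, s1.val_pos, s1.test_pos)]
        assert parts[0] | parts[1] | parts[2] == all_edges
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2])

    def test_negatives_are_verified_non_edges(self):
        g = small_graph(40, 4, seed=2, intra_p=0.3, inter_p=0.1)
        s = split_edges(g, GAEConfig(seed=0))
        edge_set = g.edge_set()
        for neg in (s.val_neg, s.test_neg):
            for u, v in neg:
                assert (min(u, v), max(u, v)) not in edge_set

    def test_dense_graph_rejected(self):
        nodes = pd.DataFrame(dict(patch_id=range(4), cell_id=0,
                                  x_um=0.0, y_um=0.0, z_um=0.0))
        edges = np.array([(i, j) for i in range(4) for j in range(i + 1, 4)])
        g = PatchGraph(nodes, edges, np.eye(4), [f"f{i}" for i in range(4)])
        with pytest.raises(ValueError, match="sparse"):
            split_edges(g, GAEConfig())


class TestEncode:
    def test_edgeless_graph_embeds_own_features_only(self, rng):
        nodes = pd.DataFrame(dict(patch_id=range(3), cell_id=0,
                                  x_um=0.0, y_um=0.0, z_um=0.0))
        X = rng.normal(size=(3, 4))
        g = PatchGraph(nodes, np.empty((0, 2), dtype=int), X, list("abcd"))
        w = init_weights(4, GAEConfig(hidden_dim=5, latent_dim=3), rng)
        z, _ = encode(g, w)
        for i in range(3):
            zi = np.maximum(X[i] @ w.W1, 0) @ w.W2  # A-hat = I when no edges
            np.testing.assert_allclose(z[i], zi, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        g = small_graph(15, 5, seed=3, intra_p=0.4, inter_p=0.1)
        w = init_weights(5, GAEConfig(hidden_dim=4, latent_dim=3), rng)
        z, _ = encode(g, w)
        perm = rng.permutation(15)
        nodes_p = g.nodes.iloc[perm].reset_index(drop=True)
        inv = np.argsort(perm)
        edges_p = inv[g.edges]
        gp = PatchGraph(nodes_p, edges_p, g.X[perm], g.feature_names)
        zp, _ = encode(gp, w)
        np.testing.assert_allclose(zp, z[perm], atol=1e-10)

    def test_two_layer_output_matches_hand_unrolled_matrices(self):
        """4-node path graph: encoder equals the dense formula
        A2·relu(A2·X·W1)·W2 with A-hat built by hand."""
        nodes = pd.DataFrame(dict(patch_id=range(4), cell_id=0,
                                  x_um=0.0, y_um=0.0, z_um=0.0))
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, -1.0]])
        g = PatchGraph(nodes, edges, X, ["a", "b"])
        W1 = np.array([[1.0, -1.0, 0.5], [0.0, 2.0, -0.5]])
        W2 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        a = np.eye(4)
        for u, v in edges:
            a[u, v] = a[v, u] = 1.0
        dinv = 1 / np.sqrt(a.sum(1))
        ahat = a * dinv[:, None] * dinv[None, :]
        expect = ahat @ np.maximum(ahat @ X @ W1, 0) @ W2
        z, _ = encode(g, Weights(W1, W2))
        np.testing.assert_allclose(z, expect, atol=1e-12)


class TestDecodeAndLoss:
    def test_sigmoid_closed_forms_and_symmetry(self, rng):
        z0 = np.zeros(4)
        assert decode_edge_prob(z0, z0) == pytest.approx(0.5)
        zi, zj = np.array([1.0, 1.0]), np.array([1.0, 1.0])
        assert decode_edge_prob(zi, zj) == pytest.approx(1 / (1 + np.exp(-2.0)))
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert decode_edge_prob(a, b) == decode_edge_prob(b, a)

    def test_loss_at_half_equals_two_ln_two(self):
        p_pos = np.array([0.3, 0.7])  # mean 0.5
        p_neg = np.array([0.5, 0.5])  # mean(1-p) = 0.5
        for variant in ("log_mean",):
            L, _, _ = reconstruction_loss(p_pos, p_neg, variant)
            assert L == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_perfect_reconstruction_drives_both_variants_to_zero(self):
        p_pos = np.full(10, 1.0)
        p_neg = np.full(10, 0.0)
        for variant in ("log_mean", "bce"):
            L, _, _ = reconstruction_loss(p_pos, p_neg, variant)
            assert L < 1e-3

    def test_monotone_in_positive_probabilities(self):
        p_neg = np.full(5, 0.2)
        losses = [reconstruction_loss(np.full(5, p), p_neg, "log_mean")[0]
                  for p in (0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(losses, losses[1:]))


@pytest.fixture(scope="module")
def fitted():
    g, _ = simulate_patch_graph(200, 20, n_communities=2, intra_p=0.08,
                                inter_p=0.005, seed=3)
    model = GraphAutoencoder(g, GAEConfig(hidden_dim=32, latent_dim=16,
                                          patience=100, max_epochs=300, seed=3))
    return model, model.fit()


class TestTraining:
    def test_trained_beats_untrained_and_degree_baseline(self, fitted):
        model, res = fitted
        untrained = model.evaluate(model.initial_weights)["auc"]
        assert res.test_auc > untrained
        # degree-only baseline: score = deg(u) + deg(v) on train graph
        deg = np.zeros(model.graph.n_nodes)
        for u, v in model.split.train_pos:
            deg[u] += 1
            deg[v] += 1
        from sklearn.metrics import roc_auc_score

        pos, neg = model.split.test_pos, model.split.test_neg
        score = np.concatenate([deg[pos[:, 0]] + deg[pos[:, 1]],
                                deg[neg[:, 0]] + deg[neg[:, 1]]])
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        assert res.test_auc > roc_auc_score(y, score)

    def test_training_loss_trends_down(self, fitted):
        _, res = fitted
        k = min(10, len(res.train_losses) // 2)
        assert res.train_losses[-k:].mean() < res.train_losses[:k].mean() + 1e-3

    def test_summary_mentions_key_numbers(self, fitted):
        _, res = fitted
        s = res.summary()
        assert "test AUC" in s and "latent_dim: 16" in s

    def test_seed_reproducibility(self):
        g, _ = simulate_patch_graph(60, 8, seed=4, intra_p=0.2, inter_p=0.02)
        cfg = GAEConfig(hidden_dim=8, latent_dim=4, max_epochs=30, seed=11)
        r1 = GraphAutoencoder(g, cfg).fit()
        r2 = GraphAutoencoder(g, cfg).fit()
        np.testing.assert_allclose(r1.embeddings, r2.embeddings)
        assert r1.test_auc == r2.test_auc


class TestPooling:
    def test_single_node_group_identity_and_mean(self):
        z = np.array([[0.0, 2.0], [2.0, 0.0], [5.0, 5.0]])
        ids, pooled = pool_embeddings(z, np.array([0, 0, 1]))
        np.testing.assert_allclose(pooled[0], [1.0, 1.0])
        np.testing.assert_allclose(pooled[1], [5.0, 5.0])

    def test_order_invariance_within_group(self, rng):
        z = rng.normal(size=(6, 3))
        groups = np.array([0, 1, 0, 1, 0, 1])
        _, p1 = pool_embeddings(z, groups)
        perm = np.array([4, 2, 0, 5, 3, 1])
        _, p2 = pool_embeddings(z[perm], groups[perm])
        np.testing.assert_allclose(p1, p2)


class TestGridSearch:
    def test_single_cell_grid_returns_it(self):
        g = small_graph(40, 6, seed=5, intra_p=0.3, inter_p=0.05)
        cfg, res = grid_search(g, [8], [4], GAEConfig(max_epochs=20, seed=0))
        assert (cfg.hidden_dim, cfg.latent_dim) == (8, 4)

    def test_best_config_reproduces_standalone(self):
        g = small_graph(40, 6, seed=6, intra_p=0.3, inter_p=0.05)
        base = GAEConfig(max_epochs=20, seed=2)
        cfg, res = grid_search(g, [4, 8], [4], base)
        again = GraphAutoencoder(g, cfg).fit()
        assert again.best_val_auc == pytest.approx(res.best_val_auc)
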