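import numpy as np
import pandas as pd
import pytest

from spagnn3d import GenePanel, SimConfig, PlantedPair, default_panel, simulate_point_cloud


@pytest.fixture(scope="session")
def panel5() -> GenePanel:
    return default_panel(5)


@pytest.fixture(scope="session")
def two_cell_field():
    """Two adjacent synthetic cells with patch structure (table, truth, config)."""
    cfg = SimConfig(n_cells=2, patches_per_cell=10, transcripts_per_patch=50, seed=3)
    table, truth = simulate_point_cloud(cfg)
    return table, truth, cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_knn_edges(points: np.ndarray, k: int) -> set[tuple[int, int]]:
    """O(n^2) union-symmetrized kNN with (distance, index) tie-break."""
    n = len(points)
    k = min(k, n - 1)
    edges = set()
    for u in range(n):
        cand = sorted((float(np.sum((points[u] - points[v]) ** 2)), v)
                      for v in range(n) if v != u)
        for _, v in cand[:k]:
            edges.add((min(u, v), max(u, v)))
    return edges
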