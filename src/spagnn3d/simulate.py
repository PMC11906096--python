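"""Synthetic data with the statistical structure the pipeline assumes.

The generators emulate multi-cell fields of 3D labeled transcript point
clouds: disjoint ellipsoidal cells (axial extent ~1/10 of lateral, as in
hydrogel-cultured cells imaged with a fine z-step), isotropic Gaussian
subcellular patches, planted gene-pair colocalization via displaced partner
points, two expression-distinct populations with negative-binomial counts,
and PSF-rendered noisy image stacks.  All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import GenePanel, TRANSCRIPT_COLUMNS, ImageStack
from .spatial_graphs import PatchGraph


class PlantedPair(NamedTuple):
    """A planted colocalization: a fraction of gene_a transcripts receive a
    gene_b partner displaced by exactly offset_um in a random direction."""

    gene_a: str
    gene_b: str
    pairing_fraction: float
    offset_um: float


def default_panel(n_genes: int = 10) -> GenePanel:
    return GenePanel([f"G{i:02d}" for i in range(1, n_genes + 1)])


@dataclass
class SimConfig:
    """Conditions for the synthetic multi-cell field.

    Defaults emulate the data regime of hydrogel-cultured mesenchymal stem
    cells: ~15 μm lateral cell radius with a tenfold-flattened axial axis,
    tens of patches per cell and tens of transcripts per patch.
    """

    n_cells: int = 2
    cell_radius_um: float = 15.0
    cell_aspect_z: float = 0.1  # axial/lateral extent ratio
    patches_per_cell: int = 8
    transcripts_per_patch: int = 50
    patch_sigma_um: float = 1.0
    panel: GenePanel = field(default_factory=default_panel)
    colocalized_pairs: list[PlantedPair] = field(default_factory=list)
    background_rate: float = 0.0  # expected extracellular transcripts per cell
    population_profiles: dict[str, Sequence[float]] | None = None  # per-gene mean counts
    nb_dispersion: float = 2.0  # negative-binomial shape r (var = mu + mu^2/r)
    cell_centers_um: np.ndarray | None = None
    fov_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.colocalized_pairs:
            if not (0.0 <= p.pairing_fraction <= 1.0):
                raise ValueError("pairing_fraction must be in [0, 1]")
            if p.offset_um < 0:
                raise ValueError("offset_um must be >= 0")
            if p.gene_a not in self.panel or p.gene_b not in self.panel:
                raise ValueError("planted pair genes must be in the panel")
        if self.population_profiles is not None:
            for name, prof in self.population_profiles.items():
                prof = np.asarray(prof, dtype=float)
                if len(prof) != len(self.panel) or np.any(prof < 0):
                    raise ValueError(f"profile {name!r} must have {len(self.panel)} non-negative means")
        if self.cell_centers_um is not None:
            centers = np.asarray(self.cell_centers_um, dtype=float).reshape(-1, 3)
            if len(centers) != self.n_cells:
                raise ValueError("cell_centers_um must have n_cells rows")
            if len(centers) > 1:
                from scipy.spatial.distance import pdist

                if pdist(centers[:, :2]).min() < 2 * self.cell_radius_um:
                    raise ValueError("cell centers overlap beyond packing")
            self.cell_centers_um = centers


@dataclass
class GroundTruth:
    """Truth accompanying a simulated TranscriptTable."""

    patch_id: np.ndarray  # per transcript-table row; -1 = background
    positions_um: np.ndarray  # (n, 3) true spot positions
    cell_population: dict[int, str]  # cell_id -> population name
    planted_pairs: list[PlantedPair]


def _grid_cell_centers(config: SimConfig) -> np.ndarray:
    if config.cell_centers_um is not None:
        return config.cell_centers_um
    spacing = 2.4 * config.cell_radius_um
    ncol = int(np.ceil(np.sqrt(config.n_cells)))
    z0 = config.cell_radius_um * config.cell_aspect_z + 6 * config.patch_sigma_um
    centers = []
    for i in range(config.n_cells):
        r, c = divmod(i, ncol)
        centers.append([spacing * (c + 0.5), spacing * (r + 0.5), z0])
    return np.array(centers)


def _uniform_in_ellipsoid(rng: np.random.Generator, n: int, semi_axes: np.ndarray) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1 / 3)
    return v * r * semi_axes


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_point_cloud(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a multi-cell field of 3D transcripts with patch structure.

    Cells are disjoint ellipsoids on a grid (or at user-supplied centers);
    patches are isotropic Gaussian blobs centered at positions drawn inside
    the cell; genes are drawn i.i.d. from the cell's expression profile
    (uniform if none given).  For each planted pair, a fraction
    ``pairing_fraction`` of gene_a transcripts gains a gene_b partner at
    exactly ``offset_um``.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    genes = np.array(panel.genes)
    centers = _grid_cell_centers(config)
    semi = config.cell_radius_um * np.array([1.0, 1.0, config.cell_aspect_z])

    profiles = config.population_profiles or {"uniform": np.ones(len(panel))}
    pop_names = sorted(profiles)

    rows_xyz, rows_gene, rows_cell, rows_patch = [], [], [], []
    cell_population: dict[int, str] = {}
    patch_counter = 0
    for cell_id, center in enumerate(centers):
        pop = pop_names[cell_id % len(pop_names)]
        cell_population[cell_id] = pop
        probs = np.asarray(profiles[pop], dtype=float)
        probs = probs / probs.sum() if probs.sum() > 0 else np.full(len(panel), 1 / len(panel))
        # patch centers inside a shrunken ellipsoid so blobs stay inside the cell
        pcenters = center + _uniform_in_ellipsoid(rng, config.patches_per_cell, semi * 0.8)
        for pc in pcenters:
            pts = pc + rng.normal(scale=config.patch_sigma_um, size=(config.transcripts_per_patch, 3))
            g = rng.choice(genes, size=len(pts), p=probs)
            rows_xyz.append(pts)
            rows_gene.append(g)
            rows_cell.append(np.full(len(pts), cell_id))
            rows_patch.append(np.full(len(pts), patch_counter))
            # planted colocalization: displaced partner points
            for pair in config.colocalized_pairs:
                src = np.flatnonzero(g == pair.gene_a)
                take = src[rng.uniform(size=len(src)) < pair.pairing_fraction]
                if len(take) == 0:
                    continue
                partners = pts[take] + pair.offset_um * _random_directions(rng, len(take))
                rows_xyz.append(partners)
                rows_gene.append(np.full(len(take), pair.gene_b, dtype=object))
                rows_cell.append(np.full(len(take), cell_id))
                rows_patch.append(np.full(len(take), patch_counter))
            patch_counter += 1
        n_bg = rng.poisson(config.background_rate)
        if n_bg:
            bg = center + _uniform_in_ellipsoid(rng, n_bg, semi * 1.5)
            rows_xyz.append(bg)
            rows_gene.append(rng.choice(genes, size=n_bg))
            rows_cell.append(np.full(n_bg, -1))
            rows_patch.append(np.full(n_bg, -1))

    xyz = np.concatenate(rows_xyz)
    xyz[:, 2] = np.maximum(xyz[:, 2], 0.0)  # axial coordinate is physical depth
    gene = np.concatenate(rows_gene)
    cell = np.concatenate(rows_cell).astype(np.int64)
    patch = np.concatenate(rows_patch).astype(np.int64)
    table = pd.DataFrame({
        "transcript_id": np.arange(len(xyz), dtype=np.int64),
        "gene": gene,
        "x_um": xyz[:, 0],
        "y_um": xyz[:, 1],
        "z_um": xyz[:, 2],
        "cell_id": cell,
        "fov_id": np.full(len(xyz), config.fov_id, dtype=np.int64),
    })[TRANSCRIPT_COLUMNS]
    truth = GroundTruth(patch_id=patch, positions_um=xyz.copy(),
                        cell_population=cell_population,
                        planted_pairs=list(config.colocalized_pairs))
    return table, truth


def simulate_image_stack(positions_um: np.ndarray, amplitudes: Sequence[float] | float,
                         shape_px: tuple[int, int, int], *,
                         lateral_um_per_px: float = 0.108, z_step_um: float = 0.3,
                         psf_sigma_xy_um: float = 0.15, psf_sigma_z_um: float = 0.4,
                         noise_sd: float = 0.0, baseline: float = 0.0,
                         seed: int = 0) -> ImageStack:
    """Render spots as anisotropic 3D Gaussians plus Gaussian read noise.

    ``positions_um`` are true spot positions (x, y, z) in μm; the stack is
    (z, y, x) with the given pixel sizes.  Negative intensities after noise
    are clipped at zero (a photon count cannot be negative).
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape_px
    vox = np.zeros((nz, ny, nx))
    positions_um = np.asarray(positions_um, dtype=float).reshape(-1, 3)
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(positions_um),))
    sx = psf_sigma_xy_um / lateral_um_per_px
    sz = psf_sigma_z_um / z_step_um
    rad_xy, rad_z = int(np.ceil(4 * sx)), int(np.ceil(4 * sz))
    for (x_um, y_um, z_um), a in zip(positions_um, amps):
        cx, cy, cz = x_um / lateral_um_per_px, y_um / lateral_um_per_px, z_um / z_step_um
        x0, x1 = max(0, int(cx) - rad_xy), min(nx, int(cx) + rad_xy + 1)
        y0, y1 = max(0, int(cy) - rad_xy), min(ny, int(cy) + rad_xy + 1)
        z0, z1 = max(0, int(cz) - rad_z), min(nz, int(cz) + rad_z + 1)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
        blob = a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sx**2) - (zz - cz) ** 2 / (2 * sz**2))
        vox[z0:z1, y0:y1, x0:x1] += blob
    vox += baseline
    if noise_sd > 0:
        vox += rng.normal(scale=noise_sd, size=vox.shape)
    np.clip(vox, 0.0, None, out=vox)
    return ImageStack(vox, lateral_um_per_px=lateral_um_per_px, z_step_um=z_step_um)


def simulate_patch_graph(n_nodes: int, feature_dim: int, n_communities: int = 2,
                         intra_p: float = 0.08, inter_p: float = 0.005,
                         feature_scale: float = 1.0, seed: int = 0) -> tuple[PatchGraph, np.ndarray]:
    """Stochastic-block-model patch graph with community-informative features.

    Edges appear independently with probability ``intra_p`` within and
    ``inter_p`` between equal-sized communities; node features are the
    community mean (a random vector of norm ``feature_scale``·√dim) plus
    unit Gaussian noise.  Densities are kept sparse so non-edges exist for
    link-prediction negatives.  Returns the graph and the community labels.
    """
    rng = np.random.default_rng(seed)
    comm = np.arange(n_nodes) % n_communities
    means = rng.normal(size=(n_communities, feature_dim))
    means *= feature_scale * np.sqrt(feature_dim) / np.linalg.norm(means, axis=1, keepdims=True)
    X = means[comm] + rng.normal(size=(n_nodes, feature_dim))
    iu, ju = np.triu_indices(n_nodes, k=1)
    p = np.where(comm[iu] == comm[ju], intra_p, inter_p)
    keep = rng.uniform(size=len(p)) < p
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    centers = rng.uniform(0, 100, size=(n_nodes, 3))
    nodes = pd.DataFrame({
        "patch_id": np.arange(n_nodes, dtype=np.int64),
        "cell_id": comm.astype(np.int64),
        "x_um": centers[:, 0], "y_um": centers[:, 1], "z_um": centers[:, 2],
    })
    names = [f"f{i}" for i in range(feature_dim)]
    return PatchGraph(nodes, edges, X, names), comm


def simulate_two_populations(config: SimConfig, seed: int | None = None
                             ) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Per-cell transcript tables from two expression-distinct populations.

    Per-cell gene counts are negative-binomial around population-specific
    means (``config.population_profiles`` must name exactly two profiles);
    transcripts are placed into Gaussian patches as in
    :func:`simulate_point_cloud`.  Returns one table per cell and the 0/1
    population label array.
    """
    if config.population_profiles is None or len(config.population_profiles) != 2:
        raise ValueError("config.population_profiles must define exactly two populations")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pop_names = sorted(config.population_profiles)
    panel = config.panel
    genes = np.array(panel.genes)
    semi = config.cell_radius_um * np.array([1.0, 1.0, config.cell_aspect_z])
    r = config.nb_dispersion

    tables, labels = [], []
    tid0 = 0
    for cell_id in range(config.n_cells):
        label = cell_id % 2
        mu = np.asarray(config.population_profiles[pop_names[label]], dtype=float)
        # NB(mu, r): gamma-poisson mixture
        lam = rng.gamma(shape=r, scale=np.maximum(mu, 1e-12) / r)
        counts = rng.poisson(lam)
        counts[mu == 0] = 0
        n_tx = int(counts.sum())
        center = np.array([0.0, 0.0, config.cell_radius_um * config.cell_aspect_z + 6 * config.patch_sigma_um])
        pcenters = center + _uniform_in_ellipsoid(rng, config.patches_per_cell, semi * 0.8)
        which_patch = rng.integers(0, config.patches_per_cell, size=n_tx)
        pts = pcenters[which_patch] + rng.normal(scale=config.patch_sigma_um, size=(n_tx, 3))
        pts[:, 2] = np.maximum(pts[:, 2], 0.0)
        gene = np.repeat(genes, counts)
        table = pd.DataFrame({
            "transcript_id": np.arange(tid0, tid0 + n_tx, dtype=np.int64),
            "gene": gene,
            "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2],
            "cell_id": np.full(n_tx, cell_id, dtype=np.int64),
            "fov_id": np.full(n_tx, config.fov_id, dtype=np.int64),
        })[TRANSCRIPT_COLUMNS]
        tid0 += n_tx
        tables.append(table)
        labels.append(label)
    return tables, np.array(labels, dtype=np.int64)
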