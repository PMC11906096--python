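"""Readers, writers and canonical tabular schemas.

All coordinates in the pipeline are physical micrometers with the origin at
the field-of-view corner, 0-based; the axial coordinate is
``z_um = slice_index * z_step_um``.  Transcripts outside any segmented cell
carry the sentinel ``cell_id = -1``: they are excluded from per-cell
analyses but retained in microenvironment queries.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("spagnn3d")

#: canonical transcript-table columns, in file order
TRANSCRIPT_COLUMNS = ["transcript_id", "gene", "x_um", "y_um", "z_um", "cell_id", "fov_id"]

#: sentinel cell id for extracellular transcripts
UNASSIGNED = -1


class PanelError(ValueError):
    """A gene symbol or pair request is inconsistent with the declared panel."""


@dataclass(frozen=True)
class GenePanel:
    """An ordered gene panel and its derived ordered list of unordered pairs.

    The pair ordering is a pure function of the panel: pairs are enumerated
    lexicographically by panel index with i < j, so node-feature vectors
    built from the same panel are always aligned, across sessions.
    """

    genes: tuple[str, ...]

    def __init__(self, genes: Sequence[str]):
        genes = tuple(str(g) for g in genes)
        if len(set(genes)) != len(genes):
            raise PanelError("gene panel contains duplicate symbols")
        if not genes:
            raise PanelError("gene panel is empty")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise PanelError(f"gene {gene!r} not in panel") from None

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """Unordered cross-gene pairs (i < j by panel index)."""
        return list(itertools.combinations(self.genes, 2))

    @property
    def n_pairs(self) -> int:
        n = len(self.genes)
        return n * (n - 1) // 2

    def pair_index(self, gene_a: str, gene_b: str) -> int:
        """Position of the unordered pair {gene_a, gene_b} in ``pairs``."""
        i, j = sorted((self.index(gene_a), self.index(gene_b)))
        if i == j:
            raise PanelError("self-pairs have no cross-pair index")
        n = len(self.genes)
        # pairs (0,1)..(0,n-1),(1,2)..: offset formula for i<j
        return i * (2 * n - i - 1) // 2 + (j - i - 1)

    def pair_labels(self) -> list[str]:
        return [f"{a}--{b}" for a, b in self.pairs]


@dataclass
class ImageStack:
    """A 3D intensity stack (z, y, x) with physical pixel sizes in μm.

    ``z_step_um`` defaults to 0.3 μm, the axial sampling used for
    diffraction-limited transcript detection.
    """

    voxels: np.ndarray
    lateral_um_per_px: float = 0.108
    z_step_um: float = 0.3

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            warnings.warn("2D image treated as single-slice stack", stacklevel=2)
            self.voxels = self.voxels[None, :, :]
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D (z,y,x) stack, got ndim={self.voxels.ndim}")
        if np.any(self.voxels < 0):
            raise ValueError("stack intensities must be non-negative")
        if self.lateral_um_per_px <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def validate_transcripts(df: pd.DataFrame, panel: GenePanel | None = None) -> pd.DataFrame:
    """Validate a transcript table against the canonical schema.

    Raises on missing columns, non-finite coordinates, negative z or
    duplicate transcript ids; rows whose gene is absent from ``panel`` are
    dropped with a logged warning (the return value is the filtered frame).
    """
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transcript table missing columns: {missing}")
    df = df[TRANSCRIPT_COLUMNS].copy()
    coords = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("transcript coordinates must be finite (missing coordinate?)")
    if np.any(df["z_um"].to_numpy(dtype=float) < 0):
        raise ValueError("z_um must be >= 0")
    if df["transcript_id"].duplicated().any():
        raise ValueError("transcript_id values must be unique")
    if panel is not None:
        ok = df["gene"].isin(panel.genes)
        n_bad = int((~ok).sum())
        if n_bad:
            bad = sorted(df.loc[~ok, "gene"].unique())
            logger.warning("dropping %d transcripts with genes outside panel: %s", n_bad, bad)
            df = df.loc[ok].reset_index(drop=True)
    for col in ("transcript_id", "cell_id", "fov_id"):
        df[col] = df[col].astype(np.int64)
    return df


def read_transcripts(path: str | Path, panel: GenePanel | None = None) -> pd.DataFrame:
    """Read a decoded-transcript CSV (comma, '.', UTF-8, mandatory header)."""
    df = pd.read_csv(path)
    return validate_transcripts(df, panel)


def write_transcripts(table: pd.DataFrame, path: str | Path) -> None:
    """Write a transcript table in the canonical CSV dialect."""
    table[TRANSCRIPT_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_stack(path: str | Path, lateral_um_per_px: float = 0.108, z_step_um: float = 0.3) -> ImageStack:
    """Read a 3D TIFF stack; axis order is normalized to (z, y, x).

    A single-page file is treated as a one-slice stack (with a warning via
    :class:`ImageStack`).  4D (channel, z, y, x) input is rejected here:
    read channels individually.
    """
    voxels = tifffile.imread(str(path))
    if voxels.ndim == 4:
        raise ValueError("multi-channel TIFF: read one channel per call")
    return ImageStack(voxels, lateral_um_per_px=lateral_um_per_px, z_step_um=z_step_um)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.voxels)


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read an integer segmentation label mask (0 = background), 2D or 3D."""
    mask = tifffile.imread(str(path))
    if mask.ndim not in (2, 3):
        raise ValueError("label mask must be 2D or 3D")
    return mask.astype(np.int64)


# ---------------------------------------------------------------------------
# graph serialization (JSON node-link; attribute-preserving round trip)
# ---------------------------------------------------------------------------

def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as JSON node-link; re-reading yields an isomorphic
    graph with equal node/edge attributes (arrays become lists)."""
    g = nx.Graph()
    for n, attrs in graph.nodes(data=True):
        g.add_node(_jsonable(n), **{k: _jsonable(v) for k, v in attrs.items()})
    for u, v, attrs in graph.edges(data=True):
        g.add_edge(_jsonable(u), _jsonable(v), **{k: _jsonable(a) for k, a in attrs.items()})
    data = nx.node_link_data(g, edges="links")
    Path(path).write_text(json.dumps(data))


def read_graph(path: str | Path) -> nx.Graph:
    data = json.loads(Path(path).read_text())
    return nx.node_link_graph(data, edges="links")
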