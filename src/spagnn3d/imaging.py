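"""Spot detection in 3D stacks and cell assignment.

Diffraction-limited dots are located in a maximum-intensity projection
across z; the depth of each dot is then the slice with the highest local
intensity at the dot's 2D position.  With a z-step of 0.3 μm this yields
full 3D transcript coordinates.  Cell assignment is a label-mask lookup
(segmentation, e.g. Cellpose, is consumed as an input mask, never produced
here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace
from skimage.feature import peak_local_max

from .io import ImageStack, TRANSCRIPT_COLUMNS


@dataclass(frozen=True)
class Spot2D:
    x_px: float
    y_px: float
    intensity: float


@dataclass(frozen=True)
class Spot3D:
    x_um: float
    y_um: float
    z_um: float
    slice_index: int
    gene: str = ""


def max_project(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity projection across the z axis: out[y,x] = max_z in[z,y,x]."""
    return stack.voxels.max(axis=0)


def detect_spots_2d(image: np.ndarray, log_sigma_px: float = 1.5,
                    min_intensity: float | None = None,
                    min_separation_px: int = 3) -> list[Spot2D]:
    """Detect diffraction-limited dots in a 2D image.

    A Laplacian-of-Gaussian filter (sigma matched to the PSF) enhances
    blobs; peaks are local maxima of the LoG response separated by at least
    ``min_separation_px`` whose raw intensity exceeds ``min_intensity``
    (default: 99.5th percentile of the image, a robust floor when most
    pixels are background).  Deterministic; an all-zero image yields no
    spots.
    """
    image = np.asarray(image, dtype=float)
    if image.max() <= 0:
        return []
    if min_intensity is None:
        min_intensity = float(np.percentile(image, 99.5))
    # negative LoG: bright blobs become positive peaks
    response = -gaussian_laplace(image, sigma=log_sigma_px)
    coords = peak_local_max(response, min_distance=min_separation_px,
                            threshold_abs=0.0, exclude_border=False)
    spots = []
    for y, x in coords:
        if image[y, x] > min_intensity:
            spots.append(Spot2D(x_px=float(x), y_px=float(y), intensity=float(image[y, x])))
    return spots


def assign_z(stack: ImageStack, spots: list[Spot2D], window_px: int = 1) -> list[Spot3D]:
    """Assign each 2D spot a depth: the slice with the highest mean
    intensity in a (2·window+1)² window at (y, x); ties go to the lowest
    slice index.  z_um = slice × z_step_um.  (x, y) are never changed."""
    vox = stack.voxels
    nz, ny, nx = vox.shape
    out = []
    for s in spots:
        x, y = int(round(s.x_px)), int(round(s.y_px))
        if not (0 <= x < nx and 0 <= y < ny):
            raise ValueError(f"spot ({s.x_px},{s.y_px}) outside image bounds")
        y0, y1 = max(0, y - window_px), min(ny, y + window_px + 1)
        x0, x1 = max(0, x - window_px), min(nx, x + window_px + 1)
        profile = vox[:, y0:y1, x0:x1].mean(axis=(1, 2))
        z = int(np.argmax(profile))  # argmax returns the first (lowest) index on ties
        out.append(Spot3D(
            x_um=s.x_px * stack.lateral_um_per_px,
            y_um=s.y_px * stack.lateral_um_per_px,
            z_um=z * stack.z_step_um,
            slice_index=z,
        ))
    return out


def detect_spots_3d(stack: ImageStack, gene: str = "", **kwargs) -> list[Spot3D]:
    """Max-project, detect in 2D, then localize depth (convenience wrapper)."""
    window_px = kwargs.pop("window_px", 1)
    spots2d = detect_spots_2d(max_project(stack), **kwargs)
    spots = assign_z(stack, spots2d, window_px=window_px)
    if gene:
        spots = [Spot3D(s.x_um, s.y_um, s.z_um, s.slice_index, gene) for s in spots]
    return spots


def assign_cells(spots: list[Spot3D], mask: np.ndarray, lateral_um_per_px: float,
                 z_step_um: float = 0.3, fov_id: int = 0) -> pd.DataFrame:
    """Assign each 3D spot to a cell by looking up the segmentation label at
    its pixel position (2D mask: (y, x); 3D mask: (z, y, x)).  Background
    label 0 maps to the extracellular sentinel cell_id = -1.  Returns a
    canonical transcript table."""
    mask = np.asarray(mask)
    rows = []
    for i, s in enumerate(spots):
        x = int(round(s.x_um / lateral_um_per_px))
        y = int(round(s.y_um / lateral_um_per_px))
        if mask.ndim == 2:
            label = int(mask[y, x]) if 0 <= y < mask.shape[0] and 0 <= x < mask.shape[1] else 0
        else:
            z = min(s.slice_index, mask.shape[0] - 1)
            label = (int(mask[z, y, x])
                     if 0 <= y < mask.shape[1] and 0 <= x < mask.shape[2] else 0)
        rows.append(dict(transcript_id=i, gene=s.gene, x_um=s.x_um, y_um=s.y_um, z_um=s.z_um,
                         cell_id=label if label > 0 else -1, fov_id=fov_id))
    return pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)
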