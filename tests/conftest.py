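"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid scipy.ndimage / skimage so they can serve as
independent references for the labelling- and counting-based operations:
connected components by breadth-first search, hole enclosure by explicit
distance checks, fractions by plain voxel counting.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from islet3d import ChannelMap, PipelineConfig, VoxelGrid
from islet3d.imageio import MarkerParams


# ---------------------------------------------------------------------------
# independent oracles


def bfs_label_26(mask: np.ndarray) -> np.ndarray:
    """26-connected component labelling by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if (
                    0 <= n[0] < mask.shape[0]
                    and 0 <= n[1] < mask.shape[1]
                    and 0 <= n[2] < mask.shape[2]
                    and mask[n]
                    and not labels[n]
                ):
                    labels[n] = current
                    queue.append(n)
    return labels


def oracle_holes_pct(
    islet: np.ndarray,
    stain: np.ndarray,
    voxel_size,
    min_hole_volume_um3: float,
    boundary_margin_um: float,
) -> float:
    """Hole percentage by BFS components plus brute-force surface distances."""
    vs = np.asarray(voxel_size, dtype=float)
    unstained = islet & ~stain
    comp = bfs_label_26(unstained)
    bg = np.argwhere(~islet).astype(float) * vs
    vol = float(np.prod(vs))
    total = 0
    for c in range(1, comp.max() + 1):
        vox = np.argwhere(comp == c)
        if len(vox) * vol < min_hole_volume_um3:
            continue
        pts = vox.astype(float) * vs
        # min distance from any component voxel to any background voxel
        dmin = np.inf
        for chunk in np.array_split(pts, max(len(pts) // 512, 1)):
            d = np.sqrt(((chunk[:, None, :] - bg[None, :, :]) ** 2).sum(-1)).min()
            dmin = min(dmin, d)
        if dmin <= boundary_margin_um:
            continue  # reaches the boundary shell: an indentation, not a hole
        total += len(vox)
    return 100.0 * total / islet.sum()


# ---------------------------------------------------------------------------
# fixtures


def make_grid(channels: dict[str, np.ndarray], voxel_size=(1.0, 1.0, 1.0)) -> VoxelGrid:
    """Build a VoxelGrid from named channel arrays (uint16)."""
    names = list(channels)
    data = np.stack([np.asarray(channels[n], dtype=np.uint16) for n in names])
    cmap = ChannelMap([(i, n, "absolute") for i, n in enumerate(names)])
    return VoxelGrid(data=data, voxel_size=voxel_size, channel_map=cmap)


def ball(shape, center, radius) -> np.ndarray:
    """Voxel-centre ball mask on an integer grid (unit voxels)."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def sphere_grid():
    """Noise-free 1000 AU sphere, r = 75 µm, 1 µm isotropic voxels."""
    shape = (160, 160, 160)
    mask = ball(shape, (80, 80, 80), 75.0)
    chan = np.where(mask, 1000, 0).astype(np.uint16)
    return make_grid({"nuclei": chan}), mask


@pytest.fixture()
def half_config():
    """Explicit-threshold config: islet at 500 AU, sigma 2 µm."""
    return PipelineConfig(sigma_islet_um=2.0, islet_threshold=500.0, split_touching=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def marker_params_half():
    def _make(intensity: float, sigma: float = 1.0) -> MarkerParams:
        return MarkerParams(sigma_um=sigma, threshold=intensity / 2.0)

    return _make
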