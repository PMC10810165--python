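"""Per-islet morphometric quantities.

All measures operate on one islet of an :class:`~islet3d.segmentation.IsletLabeling`
together with binary stain masks:

* islet volume (voxel count x voxel volume, µm³);
* stained volume fraction (% of islet volume), the primary abundance
  readout for every target protein, including CA9;
* laminin node count and node volumes (26-connected components above a
  minimum volume);
* E-cadherin hole fraction: interior unstained cavities — connected
  components of the unstained islet volume that do not reach the islet
  boundary shell — as % of islet volume;
* mean raw channel intensity over the islet (arbitrary units);
* 2D viability: green (viable) area over the union of green and red areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imageio import VoxelGrid
from .segmentation import IsletLabeling, StainMask, _STRUCT_26

__all__ = [
    "MorphometryRecord",
    "NoStainedAreaError",
    "islet_volume",
    "volume_fraction",
    "count_nodes",
    "quantify_holes",
    "mean_intensity",
    "viability_ratio",
    "ca9_fraction",
    "measure_islet",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "islet_id",
    "condition",
    "marker",
    "islet_volume_um3",
    "volume_fraction_pct",
    "node_count",
    "hole_fraction_pct",
    "mean_intensity_au",
    "viability",
]


class NoStainedAreaError(ValueError):
    """Viability is undefined: neither channel has any stained area."""


@dataclass
class MorphometryRecord:
    """One islet x one target: the tidy-table row the pipeline reports."""

    islet_id: int
    condition: str
    marker: str
    islet_volume_um3: float
    volume_fraction_pct: float
    mean_intensity_au: float
    node_count: int | None = None  # laminin only
    node_volumes_um3: list[float] = field(default_factory=list)
    hole_fraction_pct: float | None = None  # E-cadherin only
    viability: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.volume_fraction_pct <= 100.0:
            raise ValueError(f"volume fraction out of [0, 100]: {self.volume_fraction_pct}")
        if self.hole_fraction_pct is not None and not 0.0 <= self.hole_fraction_pct <= 100.0:
            raise ValueError(f"hole fraction out of [0, 100]: {self.hole_fraction_pct}")
        if self.islet_volume_um3 <= 0:
            raise ValueError("islet volume must be positive")
        if self.node_count is not None and self.node_count != len(self.node_volumes_um3):
            raise ValueError("node_count must equal the number of node volumes")

    def as_row(self) -> dict:
        return {
            "islet_id": self.islet_id,
            "condition": self.condition,
            "marker": self.marker,
            "islet_volume_um3": self.islet_volume_um3,
            "volume_fraction_pct": self.volume_fraction_pct,
            "node_count": self.node_count,
            "hole_fraction_pct": self.hole_fraction_pct,
            "mean_intensity_au": self.mean_intensity_au,
            "viability": self.viability,
        }


def islet_volume(labeling: IsletLabeling, islet_id: int) -> float:
    """Volume of one islet in µm³ (voxel count times physical voxel volume)."""
    return labeling.voxel_count(islet_id) * labeling.voxel_volume


def _islet_mask(labeling: IsletLabeling, islet_id: int) -> np.ndarray:
    m = labeling.mask(islet_id)
    if not m.any():
        raise ValueError(f"islet {islet_id} is empty")
    return m


def volume_fraction(stain: StainMask, labeling: IsletLabeling, islet_id: int) -> float:
    """Stained volume as % of islet volume; stain outside the islet is ignored."""
    if stain.mask.shape != labeling.labels.shape:
        raise ValueError(
            f"shape mismatch: stain {stain.mask.shape} vs labels {labeling.labels.shape}"
        )
    islet = _islet_mask(labeling, islet_id)
    return 100.0 * np.count_nonzero(stain.mask & islet) / np.count_nonzero(islet)


def count_nodes(
    stain: StainMask,
    labeling: IsletLabeling,
    islet_id: int,
    min_node_volume_um3: float = 4.0 / 3.0 * np.pi * 3.0**3,
) -> tuple[int, list[float]]:
    """Count discrete stained blobs ("nodes") of one islet.

    26-connected components of ``stain ∩ islet``; components below
    ``min_node_volume_um3`` are discarded.  Returns the count and the sorted
    component volumes in µm³ (an islet with zero nodes is valid).
    """
    islet = _islet_mask(labeling, islet_id)
    inside = stain.mask & islet
    lab, n = ndimage.label(inside, structure=_STRUCT_26)
    if n == 0:
        return 0, []
    counts = np.bincount(lab.ravel())[1:]
    vols = counts * labeling.voxel_volume
    vols = np.sort(vols[vols >= min_node_volume_um3])
    return int(len(vols)), [float(v) for v in vols]


def quantify_holes(
    ecad: StainMask,
    labeling: IsletLabeling,
    islet_id: int,
    min_hole_volume_um3: float = 4.0 / 3.0 * np.pi * 3.0**3,
    boundary_margin_um: float = 3.0,
) -> float:
    """Interior unstained cavities as % of islet volume.

    Within the islet, unstained voxels are grouped into 26-connected
    components.  Components that reach the islet's boundary shell (voxels
    within ``boundary_margin_um`` of the islet surface) are surface
    indentations, not holes, and are discarded, as are components below
    ``min_hole_volume_um3``.  A fully stained islet scores 0.
    """
    islet = _islet_mask(labeling, islet_id)
    unstained = islet & ~ecad.mask
    if not unstained.any():
        return 0.0
    depth = ndimage.distance_transform_edt(islet, sampling=labeling.voxel_size)
    shell = islet & (depth <= boundary_margin_um)
    lab, n = ndimage.label(unstained, structure=_STRUCT_26)
    if n == 0:
        return 0.0
    touching = np.unique(lab[shell & (lab > 0)])
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    min_vox = min_hole_volume_um3 / labeling.voxel_volume
    hole_vox = 0
    for comp in range(1, n + 1):
        if comp in touching or counts[comp] < min_vox:
            continue
        hole_vox += int(counts[comp])
    return 100.0 * hole_vox / np.count_nonzero(islet)


def mean_intensity(
    grid: VoxelGrid, marker: str, labeling: IsletLabeling, islet_id: int
) -> float:
    """Arithmetic mean of the raw (unfiltered) channel over the islet, in AU."""
    islet = _islet_mask(labeling, islet_id)
    chan = grid.channel(marker)
    return float(chan[islet].mean())


def viability_ratio(
    image: np.ndarray,
    green_threshold: float | None = None,
    red_threshold: float | None = None,
    pixel_size_um: float | None = None,
) -> dict:
    """Live/dead ratio of a 2-channel 2D image (channel 0 green, 1 red).

    Each channel is thresholded (per-channel Otsu when no threshold is
    given); viability is green area over the union of green and red areas.
    When neither channel stains anything the ratio is undefined and a
    :class:`NoStainedAreaError` is raised rather than returning a number.

    Returns a dict with ``viability`` in [0, 1], pixel areas, and physical
    areas in µm² when ``pixel_size_um`` is known.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) image, got shape {image.shape}")
    masks = []
    for chan, thr in zip(image.astype(np.float64), (green_threshold, red_threshold)):
        if thr is None:
            thr = float(threshold_otsu(chan)) if np.ptp(chan) > 0 else np.inf
        masks.append(chan >= thr)
    green, red = masks
    union = int(np.count_nonzero(green | red))
    if union == 0:
        raise NoStainedAreaError("no stained area in either channel; viability undefined")
    n_green = int(np.count_nonzero(green))
    out = {
        "viability": n_green / union,
        "green_area_px": n_green,
        "red_area_px": int(np.count_nonzero(red)),
        "stained_area_px": union,
    }
    if pixel_size_um is not None:
        out["green_area_um2"] = n_green * pixel_size_um**2
        out["stained_area_um2"] = union * pixel_size_um**2
    return out


def ca9_fraction(stain: StainMask, labeling: IsletLabeling, islet_id: int) -> float:
    """CA9-positive volume as % of islet volume (hypoxia readout)."""
    return volume_fraction(stain, labeling, islet_id)


def measure_islet(
    grid: VoxelGrid,
    labeling: IsletLabeling,
    islet_id: int,
    stains: dict[str, StainMask],
    condition: str = "",
    min_node_volume_um3: float = 4.0 / 3.0 * np.pi * 3.0**3,
    min_hole_volume_um3: float = 4.0 / 3.0 * np.pi * 3.0**3,
    boundary_margin_um: float = 3.0,
) -> list[MorphometryRecord]:
    """All records for one islet: one row per non-nuclear marker.

    Laminin rows carry node counts, E-cadherin rows carry hole fractions;
    every row carries the volume fraction and raw mean intensity.
    """
    vol = islet_volume(labeling, islet_id)
    records = []
    for marker, stain in stains.items():
        if marker == "nuclei":
            continue
        rec = MorphometryRecord(
            islet_id=islet_id,
            condition=condition,
            marker=marker,
            islet_volume_um3=vol,
            volume_fraction_pct=volume_fraction(stain, labeling, islet_id),
            mean_intensity_au=mean_intensity(grid, marker, labeling, islet_id),
        )
        if marker == "laminin":
            n, vols = count_nodes(stain, labeling, islet_id, min_node_volume_um3)
            rec.node_count = n
            rec.node_volumes_um3 = vols
        if marker == "ecadherin":
            rec.hole_fraction_pct = quantify_holes(
                stain, labeling, islet_id, min_hole_volume_um3, boundary_margin_um
            )
        records.append(rec)
    return records
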