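"""Reading and writing multi-channel 3D stacks and run configuration.

The pipeline's raw input is a 4D intensity array ordered ``(channel, z, y, x)``
with physical voxel sizes in micrometres and a channel map naming each
fluorescence channel.  Stacks are exchanged as multi-page TIFF / OME-TIFF;
voxel sizes are embedded in (and recovered from) OME metadata, with an
explicit override for plain TIFFs that carry none.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "MARKER_NAMES",
    "DETECTION_MODES",
    "ChannelMap",
    "VoxelGrid",
    "MarkerParams",
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "load_config",
    "ConfigError",
    "StackFormatError",
]

#: Recognised fluorescence targets.  ``viability_green`` / ``viability_red``
#: are only meaningful for 2D live/dead images.
MARKER_NAMES = frozenset(
    {
        "nuclei",
        "insulin",
        "glucagon",
        "ca9",
        "collagen4",
        "fibronectin",
        "laminin",
        "ecadherin",
        "viability_green",
        "viability_red",
    }
)

DETECTION_MODES = ("absolute", "background_subtracted")


class StackFormatError(ValueError):
    """Raised when a TIFF stack cannot be interpreted as a VoxelGrid."""


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration values."""


@dataclass(frozen=True)
class ChannelMap:
    """Ordered assignment of channel indices to marker names.

    Each entry is ``(channel_index, marker_name, detection_mode)``.  Indices
    must be unique and contiguous from 0, and a 3D stack carries exactly one
    nuclei channel.
    """

    entries: tuple[tuple[int, str, str], ...]

    def __init__(self, entries: Sequence[tuple[int, str, str]]):
        entries = tuple((int(i), str(m), str(d)) for i, m, d in entries)
        indices = [e[0] for e in entries]
        if sorted(indices) != list(range(len(entries))):
            raise ConfigError(
                f"channel indices must be unique and contiguous from 0, got {indices}"
            )
        for _, marker, mode in entries:
            if marker not in MARKER_NAMES:
                raise ConfigError(f"unknown marker name: {marker!r}")
            if mode not in DETECTION_MODES:
                raise ConfigError(f"unknown detection mode: {mode!r}")
        object.__setattr__(self, "entries", tuple(sorted(entries)))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(e[1] for e in self.entries)

    def index_of(self, marker: str) -> int:
        for idx, name, _ in self.entries:
            if name == marker:
                return idx
        raise KeyError(f"marker {marker!r} not in channel map {self.markers}")

    def mode_of(self, marker: str) -> str:
        for _, name, mode in self.entries:
            if name == marker:
                return mode
        raise KeyError(f"marker {marker!r} not in channel map {self.markers}")

    def validate_3d(self) -> None:
        if self.markers.count("nuclei") != 1:
            raise ConfigError(
                f"a 3D stack needs exactly one nuclei channel, got {self.markers}"
            )


@dataclass
class VoxelGrid:
    """A multi-channel 3D intensity image with physical voxel sizes.

    Parameters
    ----------
    data
        Nonnegative integer array, axis order ``(channel, z, y, x)``.
    voxel_size
        ``(dz, dy, dx)`` in µm, each strictly positive.  Anisotropy is
        permitted (light-sheet z-spacing usually exceeds the lateral pixel
        size).
    channel_map
        Marker assignment for the channel axis.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_map: ChannelMap

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (c, z, y, x), got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.unsignedinteger):
            if np.issubdtype(self.data.dtype, np.signedinteger) and self.data.min() >= 0:
                self.data = self.data.astype(np.uint16)
            else:
                raise ValueError(f"intensities must be nonnegative integers, dtype {self.data.dtype}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive values (dz, dy, dx), got {self.voxel_size}")
        if len(self.channel_map) != self.data.shape[0]:
            raise ValueError(
                f"channel map has {len(self.channel_map)} entries for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial (z, y, x) shape shared by all channels."""
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, marker: str) -> np.ndarray:
        """The 3D intensity array of one named marker (a view)."""
        return self.data[self.channel_map.index_of(marker)]


def write_stack(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a VoxelGrid as an OME-TIFF with voxel size in the metadata.

    The round trip through :func:`read_stack` is lossless: intensities,
    voxel sizes and channel count are preserved exactly.
    """
    path = Path(path)
    dz, dy, dx = grid.voxel_size
    tifffile.imwrite(
        path,
        grid.data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
        },
    )
    return path


def _ome_voxel_size(ome_xml: str) -> tuple[float, float, float] | None:
    sizes = {}
    for axis in "XYZ":
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome_xml)
        if m:
            sizes[axis] = float(m.group(1))
    if set(sizes) == {"X", "Y", "Z"}:
        return (sizes["Z"], sizes["Y"], sizes["X"])
    return None


def read_stack(
    path: str | Path,
    channel_map: ChannelMap,
    voxel_size: tuple[float, float, float] | None = None,
    interleave: str | None = None,
) -> VoxelGrid:
    """Read a multi-page TIFF / OME-TIFF into a VoxelGrid.

    Parameters
    ----------
    path
        Existing TIFF file.  The page count must be divisible by the number
        of channels in ``channel_map``.
    channel_map
        Expected channel assignment; channel order follows it.
    voxel_size
        ``(dz, dy, dx)`` µm override.  Required when the file metadata does
        not state voxel sizes; when both are present the override wins.
    interleave
        Page interleaving dialect for plain multi-page TIFFs: ``"channel"``
        (all z-planes of channel 0, then channel 1, ...) or ``"plane"``
        (channels cycle fastest).  Auto-detected from OME/ImageJ metadata
        when possible; defaults to ``"channel"`` for bare TIFFs.

    Intensities are never rescaled on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    n_ch = len(channel_map)
    with tifffile.TiffFile(path) as tif:
        meta_vs = None
        data = None
        if tif.is_ome and tif.ome_metadata:
            meta_vs = _ome_voxel_size(tif.ome_metadata)
            series = tif.series[0]
            arr = series.asarray()
            axes = series.axes  # e.g. 'CZYX' or 'ZYX' or 'QZYX'
            arr = _to_czyx(arr, axes, n_ch)
            data = arr
        else:
            pages = tif.asarray()
            if pages.ndim == 2:
                pages = pages[None]
            if pages.ndim != 3:
                raise StackFormatError(f"cannot interpret TIFF of shape {pages.shape}")
            n_pages = pages.shape[0]
            if n_pages % n_ch != 0:
                raise StackFormatError(
                    f"page/channel mismatch: {n_pages} pages not divisible by {n_ch} channels"
                )
            nz = n_pages // n_ch
            if interleave is None:
                ij = tif.imagej_metadata or {}
                # ImageJ hyperstacks store CZT with channels cycling fastest.
                interleave = "plane" if ij.get("channels") == n_ch else "channel"
            if interleave == "channel":
                data = pages.reshape(n_ch, nz, *pages.shape[1:])
            elif interleave == "plane":
                data = pages.reshape(nz, n_ch, *pages.shape[1:]).transpose(1, 0, 2, 3)
            else:
                raise ValueError(f"interleave must be 'channel' or 'plane', got {interleave!r}")
            if tif.imagej_metadata and "spacing" in tif.imagej_metadata:
                dz = float(tif.imagej_metadata["spacing"])
                res = tif.pages[0].tags.get("XResolution")
                if res is not None:
                    num, den = res.value
                    dx = den / num if num else None
                    if dx:
                        meta_vs = (dz, dx, dx)
    vs = voxel_size if voxel_size is not None else meta_vs
    if vs is None:
        raise StackFormatError(
            f"{path}: no voxel size in metadata and no override given"
        )
    return VoxelGrid(data=data, voxel_size=vs, channel_map=channel_map)


def _to_czyx(arr: np.ndarray, axes: str, n_ch: int) -> np.ndarray:
    axes = axes.upper().replace("S", "C").replace("Q", "C")
    if arr.ndim == 3:
        if n_ch == 1:
            return arr[None]
        if arr.shape[0] % n_ch == 0:
            return arr.reshape(n_ch, -1, *arr.shape[1:])
        raise StackFormatError(
            f"page/channel mismatch: {arr.shape[0]} planes, {n_ch} channels"
        )
    if arr.ndim != 4:
        raise StackFormatError(f"cannot interpret series with axes {axes}, shape {arr.shape}")
    if len(axes) != 4:
        raise StackFormatError(f"unsupported axes {axes!r}")
    order = [axes.index(a) for a in "CZYX"]
    out = arr.transpose(order)
    if out.shape[0] != n_ch:
        raise StackFormatError(
            f"page/channel mismatch: file has {out.shape[0]} channels, map has {n_ch}"
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class MarkerParams:
    """Detection parameters for one marker channel.

    All lengths are physical (µm) and are converted to voxel units per axis
    using the stack's voxel size.  ``threshold=None`` requests an automatic
    Otsu threshold on the filtered channel.
    """

    sigma_um: float = 1.0
    threshold: float | None = None
    mode: str = "absolute"
    background_sigma_um: float = 20.0

    def validate(self, name: str = "marker") -> None:
        if self.sigma_um < 0:
            raise ConfigError(f"{name}.sigma_um must be >= 0, got {self.sigma_um}")
        if self.threshold is not None and not np.isfinite(self.threshold):
            raise ConfigError(f"{name}.threshold must be finite")
        if self.mode not in DETECTION_MODES:
            raise ConfigError(f"{name}.mode must be one of {DETECTION_MODES}, got {self.mode!r}")
        if self.mode == "background_subtracted" and self.background_sigma_um <= self.sigma_um:
            raise ConfigError(
                f"{name}: background_sigma_um ({self.background_sigma_um}) must exceed "
                f"sigma_um ({self.sigma_um}) in background_subtracted mode"
            )


@dataclass
class PipelineConfig:
    """All tunable parameters of an analysis run.

    Lengths are in µm, volumes in µm³, intensities in the acquisition's
    arbitrary units (AU).  Defaults are documented in the methods note; every
    run echoes its resolved configuration for provenance.
    """

    # islet delineation
    sigma_islet_um: float = 3.0
    islet_threshold: float | None = None  # None -> Otsu on the smoothed sum
    min_islet_volume_um3: float = 5000.0
    split_touching: bool = True
    split_min_separation_um: float = 15.0

    # per-marker detection
    markers: dict[str, MarkerParams] = field(default_factory=dict)

    # morphometry
    min_node_volume_um3: float = 4.0 / 3.0 * np.pi * 3.0**3  # 3 µm-radius sphere
    min_hole_volume_um3: float = 4.0 / 3.0 * np.pi * 3.0**3
    boundary_margin_um: float = 3.0

    # statistics
    alpha: float = 0.05
    transform: str = "log"  # the only transform-to-normality policy offered
    pooled_variance: bool = False
    holm_correction: bool = False

    # provenance / curation
    exclude_islets: list[int] = field(default_factory=list)
    seed: int = 0
    voxel_size_override: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("sigma_islet_um", "min_islet_volume_um3", "min_node_volume_um3",
                     "min_hole_volume_um3", "boundary_margin_um", "split_min_separation_um"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.islet_threshold is not None and (
            not np.isfinite(self.islet_threshold) or self.islet_threshold < 0
        ):
            raise ConfigError(f"islet_threshold must be finite and >= 0, got {self.islet_threshold}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.transform not in ("none", "log"):
            raise ConfigError(f"transform must be 'none' or 'log', got {self.transform!r}")
        for name, mp in self.markers.items():
            if name not in MARKER_NAMES:
                raise ConfigError(f"unknown marker name in config: {name!r}")
            mp.validate(name)

    def marker_params(self, marker: str) -> MarkerParams:
        """Parameters for ``marker``, falling back to defaults."""
        return self.markers.get(marker, MarkerParams())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["markers"] = {k: asdict(v) for k, v in self.markers.items()}
        if d["voxel_size_override"] is not None:
            d["voxel_size_override"] = list(d["voxel_size_override"])
        return d

    def dump(self, path: str | Path) -> Path:
        """Serialize the resolved configuration (YAML) beside run outputs."""
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML run configuration; unspecified fields take the defaults.

    ``path=None`` (or an empty file) yields the all-default configuration.
    Unknown marker names and nonpositive length parameters are rejected with
    errors naming the offending field.
    """
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such config file: {path}")
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    markers_raw = raw.pop("markers", {}) or {}
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    markers = {}
    for name, params in markers_raw.items():
        if not isinstance(params, dict):
            raise ConfigError(f"marker entry {name!r} must be a mapping")
        bad = set(params) - {f.name for f in MarkerParams.__dataclass_fields__.values()}
        if bad:
            raise ConfigError(f"unknown keys for marker {name!r}: {sorted(bad)}")
        markers[name] = MarkerParams(**params)
    if "voxel_size_override" in raw and raw["voxel_size_override"] is not None:
        raw["voxel_size_override"] = tuple(raw["voxel_size_override"])
    return PipelineConfig(markers=markers, **raw)
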