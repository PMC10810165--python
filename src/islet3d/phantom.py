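"""Synthetic islet phantoms with exact ground truth.

Cleared-islet light-sheet stacks are emulated at desk scale so every
downstream stage — delineation, stain detection, morphometry, statistics —
can be verified without microscopy data.  An islet is rendered as a
(possibly slightly ellipsoidal) ball of radius 25–125 µm containing
geometric primitives for each target:

* nuclei — small non-overlapping spheres, excluded from the necrotic core;
* laminin — scattered spherical "nodes" (normoxia) or one/two large central
  scar-like blobs (hypoxia);
* E-cadherin — the islet volume minus a central spherical cavity (the
  "hole" whose relative volume the pipeline measures);
* CA9 — a rim of hypoxic cells around the central scar, or sporadic small
  blobs under normoxia;
* collagen 4 — vessel-like tubes along random chords;
* fibronectin — the boundary mesh of a seeded Voronoi partition of the
  islet interior, plus a condensed central blob when a scar is present;
* insulin / glucagon — cytoplasmic stain (interior minus nuclei).

Rendering order: rasterize structures at stated intensities over a low
background, apply an anisotropic Gaussian PSF (sigma_z > sigma_xy), add
signal-dependent Poisson noise plus Gaussian read noise, clip to the bit
depth.  The pre-blur, pre-noise masks are the ground truth.

Seeding is hierarchical: one spec seed; per-structure substreams are derived
from fixed labels so adding one structure never reshuffles the others, and
per-islet cohort seeds are derived from (cohort seed, islet index) only, so
cohorts with different condition profiles but the same seed are "seed-paired"
(islet i shares its radius draw across profiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .imageio import ChannelMap, VoxelGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ConditionProfile",
    "PROFILE_NAMES",
    "get_profile",
    "generate_islet_phantom",
    "generate_cohort",
    "generate_viability_image",
    "analysis_config",
    "PlacementError",
]

PROFILE_NAMES = ("ND1", "ND5", "HD5")

_DEFAULT_INTENSITIES = {
    "background": 100.0,
    "nuclei": 8000.0,
    "laminin": 5000.0,
    "ecadherin": 6500.0,
    "ca9": 5000.0,
    "collagen4": 5000.0,
    "fibronectin": 4000.0,
    "insulin": 6000.0,
    "glucagon": 6000.0,
}


class PlacementError(RuntimeError):
    """A structure could not be placed under its separation constraints."""


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic islet acquisition.

    Lengths in µm, intensities in arbitrary units (AU) on a 16-bit range.
    ``markers`` selects the three non-nuclear channels rendered (one
    acquisition round images nuclei plus three targets).
    """

    islet_radius_um: float = 60.0
    shape_irregularity: float = 0.06  # per-axis ellipsoid jitter, volume-preserving
    markers: tuple[str, ...] = ("laminin", "ecadherin", "ca9")

    n_nuclei: int = 60
    nucleus_radius_um: float = 3.0

    # laminin nodes
    n_nodes: int = 7
    node_radius_um: float = 5.0
    node_placement_radius_frac: float = 0.85  # of (islet radius - node radius)
    well_separated: bool = True

    # central scar / hypoxia
    scar_radius_um: float = 0.0  # 0 = no scar
    ca9_rim_um: float = 0.0
    n_ca9_blobs: int = 0
    ca9_blob_radius_um: float = 2.5

    # E-cadherin cavity
    hole_radius_um: float = 0.0  # 0 = no central hole

    # collagen 4 tubes / fibronectin mesh
    n_tubes: int = 3
    tube_radius_um: float = 3.0
    mesh_n_seeds: int = 24
    mesh_thickness_um: float = 2.0

    intensity: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_INTENSITIES))

    blur_sigma_xy_um: float = 1.0
    blur_sigma_z_um: float = 2.0
    noise_gaussian_au: float = 50.0
    poisson_gain_au_per_photon: float = 10.0  # 0 disables shot noise

    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    canvas_shape: tuple[int, int, int] | None = None  # None -> fitted to the islet
    bit_depth: int = 16
    seed: int = 0

    def validate(self) -> None:
        r = self.islet_radius_um
        if r <= 0:
            raise ValueError("islet_radius_um must be positive")
        if self.scar_radius_um + self.ca9_rim_um >= r:
            raise ValueError(
                "scar radius plus CA9 rim thickness must stay below the islet radius"
            )
        if self.hole_radius_um >= r:
            raise ValueError("hole radius must stay below the islet radius")
        if not 0 <= self.shape_irregularity < 0.5:
            raise ValueError("shape_irregularity must lie in [0, 0.5)")
        for m in self.markers:
            if m not in _DEFAULT_INTENSITIES:
                raise ValueError(f"no rendering rule for marker {m!r}")


@dataclass
class PhantomTruth:
    """Pre-blur, pre-noise ground truth of one phantom.

    ``hole_fraction_pct`` is exactly ``100 * hole voxels / islet voxels``.
    All planted marker masks are subsets of the islet mask; nuclei lie
    strictly inside it.
    """

    islet_mask: np.ndarray
    marker_masks: dict[str, np.ndarray]
    node_count: int
    node_centers_um: np.ndarray  # (n, 3) z, y, x relative to canvas origin
    hole_fraction_pct: float
    viable_fraction: float | None
    intensities: dict[str, float]
    spec: PhantomSpec

    @property
    def islet_volume_um3(self) -> float:
        dz, dy, dx = self.spec.voxel_size
        return float(self.islet_mask.sum()) * dz * dy * dx

    def marker_fraction_pct(self, marker: str) -> float:
        """Planted stained-volume percentage of ``marker`` inside the islet."""
        m = self.marker_masks[marker] & self.islet_mask
        return 100.0 * m.sum() / self.islet_mask.sum()


# ---------------------------------------------------------------------------
# geometry helpers


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-structure RNG; independent of other structures."""
    h = np.frombuffer(label.encode(), dtype=np.uint8)
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *h.tolist()]))


def _sample_in_ball(rng: np.random.Generator, radius: float, n: int = 1) -> np.ndarray:
    """Uniform points in a ball of ``radius`` centred at the origin."""
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - got) + 8, 3))
        ok = cand[np.sum(cand**2, axis=1) <= radius**2]
        take = min(len(ok), n - got)
        pts[got:got + take] = ok[:take]
        got += take
    return pts


def _place_separated(
    rng: np.random.Generator,
    n: int,
    region_radius: float,
    min_separation: float,
    max_attempts: int = 5000,
    what: str = "structure",
) -> np.ndarray:
    """Rejection-sample ``n`` centers in a ball with pairwise separation."""
    centers: list[np.ndarray] = []
    attempts = 0
    stuck = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n} {what}s with pairwise separation "
                f">= {min_separation:.1f} µm inside radius {region_radius:.1f} µm "
                f"after {max_attempts} attempts"
            )
        cand = _sample_in_ball(rng, region_radius)[0]
        attempts += 1
        if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
            centers.append(cand)
            stuck = 0
        else:
            stuck += 1
            if stuck >= 200:
                # earlier placements may have painted us into a corner
                # (e.g. a first centre too central to admit a far partner);
                # restart the whole configuration
                centers.clear()
                stuck = 0
    return np.asarray(centers).reshape(n, 3)


# ---------------------------------------------------------------------------
# phantom generation


def _canvas_and_coords(spec: PhantomSpec):
    vs = np.asarray(spec.voxel_size, dtype=float)
    if spec.canvas_shape is not None:
        shape = tuple(int(s) for s in spec.canvas_shape)
    else:
        margin = 4 * spec.blur_sigma_z_um + 6.0
        extent = 2 * spec.islet_radius_um * (1 + spec.shape_irregularity) + 2 * margin
        shape = tuple(int(np.ceil(extent / v)) for v in vs)
    center = (np.asarray(shape) * vs) / 2.0
    # voxel-centre coordinates relative to the islet centre, one 1D array per axis
    coords = [
        (np.arange(shape[d]) + 0.5) * vs[d] - center[d]
        for d in range(3)
    ]
    return shape, center, coords


def _ellipsoid_scales(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.shape_irregularity == 0:
        return np.ones(3)
    s = rng.uniform(1 - spec.shape_irregularity, 1 + spec.shape_irregularity, size=3)
    return s / np.cbrt(np.prod(s))  # volume-preserving


def generate_islet_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    """Render one 4-channel phantom stack and its ground truth.

    The same spec (including seed) always yields bit-identical output.
    Structures are placed in the islet's unit-sphere frame and mapped through
    the ellipsoidal shape perturbation, so containment invariants hold
    exactly on the rasterized masks.
    """
    spec.validate()
    shape, center, coords = _canvas_and_coords(spec)
    vs = np.asarray(spec.voxel_size, dtype=float)
    r = spec.islet_radius_um
    inten = dict(_DEFAULT_INTENSITIES, **spec.intensity)

    scales = _ellipsoid_scales(spec, _substream(spec.seed, "shape"))
    # u-frame: coordinates divided by the per-axis scale; islet = |u| <= r
    u_ax = [coords[d] / scales[d] for d in range(3)]
    u2 = (
        u_ax[0][:, None, None] ** 2
        + u_ax[1][None, :, None] ** 2
        + u_ax[2][None, None, :] ** 2
    )
    islet = u2 <= r**2

    def to_canvas(u_pts: np.ndarray) -> np.ndarray:
        """Map u-frame points to canvas coordinates (µm from origin)."""
        return u_pts * scales + center

    def ball_in_u(mask: np.ndarray, u_center, radius_um) -> None:
        # Spheres are rasterized in the u-frame metric so containment in the
        # islet (a u-frame ball) is exact; with small shape_irregularity they
        # remain near-spherical in real space.
        c = np.asarray(u_center, dtype=float)
        lo = np.maximum(np.floor((to_canvas(c) - radius_um * scales.max() - vs) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((to_canvas(c) + radius_um * scales.max() + vs) / vs).astype(int) + 1, shape)
        if np.any(lo >= hi):
            return
        ax = [
            ((np.arange(lo[d], hi[d]) + 0.5) * vs[d] - center[d]) / scales[d] - c[d]
            for d in range(3)
        ]
        d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= radius_um**2

    # --- nuclei: non-overlapping, strictly inside, excluded from the scar core
    rng_nuc = _substream(spec.seed, "nuclei")
    nuc_mask = np.zeros(shape, dtype=bool)
    nuc_r = spec.nucleus_radius_um
    placed: list[np.ndarray] = []
    attempts, max_attempts = 0, 200 * max(spec.n_nuclei, 1)
    inner = r - nuc_r - 2 * max(vs)  # strictly inside, clear of the surface voxel layer
    while len(placed) < spec.n_nuclei and attempts < max_attempts:
        cand = _sample_in_ball(rng_nuc, inner)[0]
        attempts += 1
        if np.linalg.norm(cand) <= spec.scar_radius_um + nuc_r:
            continue  # scarce nuclei in the necrotic core
        if all(np.linalg.norm(cand - p) >= 2 * nuc_r for p in placed):
            placed.append(cand)
    for c in placed:
        ball_in_u(nuc_mask, c, nuc_r)

    marker_masks: dict[str, np.ndarray] = {}
    node_centers = np.zeros((0, 3))
    n_nodes_planted = 0

    for marker in spec.markers:
        m = np.zeros(shape, dtype=bool)
        if marker == "laminin":
            rng_lam = _substream(spec.seed, "laminin")
            if spec.n_nodes > 0:
                reach = max(spec.node_placement_radius_frac * (r - spec.node_radius_um), 1.0)
                # the axial PSF is the widest; the gap between node surfaces
                # must exceed two of its sigmas or half-max detection bridges
                # neighbouring nodes along z
                sep = (
                    2 * (spec.node_radius_um + max(spec.blur_sigma_xy_um, spec.blur_sigma_z_um))
                    if spec.well_separated
                    else 0.0
                )
                # the separation contract must survive rasterization: on
                # coarse grids two balls with a sub-voxel gap can fuse into
                # one 26-connected component, so resample until the planted
                # mask has exactly n components
                for _ in range(20):
                    centers = _place_separated(
                        rng_lam, spec.n_nodes, reach, sep, what="laminin node"
                    )
                    m[:] = False
                    for c in centers:
                        ball_in_u(m, c, spec.node_radius_um)
                    if not spec.well_separated:
                        break
                    _, k = ndimage.label(m, structure=np.ones((3, 3, 3), bool))
                    if k == spec.n_nodes:
                        break
                else:
                    raise PlacementError(
                        f"{spec.n_nodes} laminin nodes kept fusing after rasterization "
                        f"at voxel size {tuple(vs)}"
                    )
                node_centers = to_canvas(centers)
                n_nodes_planted = spec.n_nodes
        elif marker == "ecadherin":
            m = islet.copy()
            if spec.hole_radius_um > 0:
                hole = np.zeros(shape, dtype=bool)
                ball_in_u(hole, (0.0, 0.0, 0.0), spec.hole_radius_um)
                m &= ~hole
        elif marker == "ca9":
            rng_ca9 = _substream(spec.seed, "ca9")
            if spec.scar_radius_um > 0 and spec.ca9_rim_um > 0:
                outer = np.zeros(shape, dtype=bool)
                ball_in_u(outer, (0.0, 0.0, 0.0), spec.scar_radius_um + spec.ca9_rim_um)
                core = np.zeros(shape, dtype=bool)
                ball_in_u(core, (0.0, 0.0, 0.0), spec.scar_radius_um)
                m = outer & ~core & islet
            for c in _sample_in_ball(rng_ca9, max(r - spec.ca9_blob_radius_um - 1, 1.0), max(spec.n_ca9_blobs, 1))[: spec.n_ca9_blobs]:
                ball_in_u(m, c, spec.ca9_blob_radius_um)
        elif marker == "collagen4":
            rng_col = _substream(spec.seed, "collagen4")
            for _ in range(spec.n_tubes):
                a, b = _sample_in_ball(rng_col, 0.9 * r, 2)
                n_steps = max(int(np.linalg.norm(b - a) / (spec.tube_radius_um / 2)), 2)
                for t in np.linspace(0, 1, n_steps):
                    ball_in_u(m, a + t * (b - a), spec.tube_radius_um)
            if spec.scar_radius_um > 0:
                ball_in_u(m, (0.0, 0.0, 0.0), spec.scar_radius_um)
        elif marker == "fibronectin":
            rng_fib = _substream(spec.seed, "fibronectin")
            m = _voronoi_mesh(
                islet, coords, scales, rng_fib, r, spec.mesh_n_seeds,
                spec.mesh_thickness_um, vs,
            )
            if spec.scar_radius_um > 0:
                ball_in_u(m, (0.0, 0.0, 0.0), spec.scar_radius_um)
        elif marker in ("insulin", "glucagon"):
            m = islet & ~nuc_mask
        m &= islet
        marker_masks[marker] = m

    marker_masks["nuclei"] = nuc_mask

    if "ecadherin" in marker_masks:
        hole_vox = int((islet & ~marker_masks["ecadherin"]).sum())
    else:
        hole_vox = 0
    hole_fraction = 100.0 * hole_vox / islet.sum()

    # --- render: intensities -> anisotropic PSF -> Poisson-Gaussian noise
    channel_names = ("nuclei",) + tuple(spec.markers)
    rng_noise = _substream(spec.seed, "noise")
    sigma_vox = np.array([spec.blur_sigma_z_um, spec.blur_sigma_xy_um, spec.blur_sigma_xy_um]) / vs
    max_val = 2**spec.bit_depth - 1
    data = np.empty((len(channel_names), *shape), dtype=np.uint16)
    for ci, name in enumerate(channel_names):
        img = np.full(shape, inten["background"], dtype=np.float64)
        img[marker_masks[name]] = inten[name]
        if np.any(sigma_vox > 0):
            img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        if spec.poisson_gain_au_per_photon > 0:
            g = spec.poisson_gain_au_per_photon
            img = rng_noise.poisson(img / g).astype(np.float64) * g
        if spec.noise_gaussian_au > 0:
            img = img + rng_noise.normal(0.0, spec.noise_gaussian_au, size=shape)
        data[ci] = np.clip(np.rint(img), 0, max_val).astype(np.uint16)

    cmap = ChannelMap([(i, n, "absolute") for i, n in enumerate(channel_names)])
    grid = VoxelGrid(data=data, voxel_size=tuple(vs), channel_map=cmap)
    truth = PhantomTruth(
        islet_mask=islet,
        marker_masks=marker_masks,
        node_count=n_nodes_planted,
        node_centers_um=node_centers,
        hole_fraction_pct=float(hole_fraction),
        viable_fraction=None,
        intensities={n: inten[n] for n in channel_names},
        spec=spec,
    )
    return grid, truth


def _voronoi_mesh(islet, coords, scales, rng, r, n_seeds, thickness_um, vs) -> np.ndarray:
    """Intercellular mesh: boundaries of a seeded Voronoi partition of the islet."""
    seeds_u = _sample_in_ball(rng, 0.95 * r, n_seeds)
    idx = np.argwhere(islet)
    if len(idx) == 0 or n_seeds < 2:
        return np.zeros_like(islet)
    pts_u = np.column_stack([
        ((idx[:, d] + 0.5) * vs[d] - (np.asarray(islet.shape[d]) * vs[d]) / 2.0) / scales[d]
        for d in range(3)
    ])
    _, owner = cKDTree(seeds_u).query(pts_u)
    lab = np.zeros(islet.shape, dtype=np.int32)
    lab[tuple(idx.T)] = owner + 1
    mx = ndimage.maximum_filter(lab, size=3)
    mn = np.where(islet, lab, np.iinfo(np.int32).max)
    mn = ndimage.minimum_filter(mn, size=3)
    mesh = islet & (mx != np.where(mn == np.iinfo(np.int32).max, mx, mn))
    n_iter = max(int(round(thickness_um / (2 * min(vs)))), 0)
    if n_iter:
        mesh = ndimage.binary_dilation(mesh, iterations=n_iter) & islet
    return mesh


# ---------------------------------------------------------------------------
# condition profiles


@dataclass
class ConditionProfile:
    """Distributions over phantom parameters for one experimental group.

    ``ND1`` / ``ND5`` are normoxia day 1 / day 5; ``HD5`` is hypoxia (1% O2)
    day 5.  Hypoxic islets get one or two large central laminin scars, a
    bigger E-cadherin cavity, a CA9-positive rim around the necrotic core,
    scarce nuclei, and a brighter E-cadherin signal; normoxic islets get
    5–9 small scattered nodes (more in bigger islets) and sporadic CA9.
    """

    name: str
    radius_range_um: tuple[float, float] = (35.0, 80.0)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    markers: tuple[str, ...] = ("laminin", "ecadherin", "ca9")

    def sample_spec(self, rng: np.random.Generator, seed: int) -> PhantomSpec:
        # The radius draw comes first and depends only on the rng state, so
        # seed-paired cohorts share islet sizes across profiles.
        r = rng.uniform(*self.radius_range_um)
        inten = dict(_DEFAULT_INTENSITIES)
        common = dict(
            islet_radius_um=r,
            voxel_size=self.voxel_size,
            markers=self.markers,
            seed=seed,
        )
        lo, hi = self.radius_range_um
        if self.name == "HD5":
            n_nodes = int(rng.integers(1, 3))
            node_r = rng.uniform(0.15, 0.20) * r
            scar_r = rng.uniform(0.38, 0.46) * r
            hole_r = rng.uniform(0.40, 0.48) * r
            inten["ecadherin"] = float(np.clip(rng.normal(14800.0, 1760.0), 4000, 40000))
            return PhantomSpec(
                **common,
                n_nuclei=int(rng.integers(18, 32)),
                n_nodes=n_nodes,
                node_radius_um=node_r,
                node_placement_radius_frac=min(0.55 * r - node_r, r - node_r - 2.0)
                / max(r - node_r, 1.0),
                scar_radius_um=scar_r,
                ca9_rim_um=min(6.0, r - scar_r - 2.0),
                n_ca9_blobs=0,
                hole_radius_um=hole_r,
                intensity=inten,
            )
        # normoxia: node count grows with islet size plus unit jitter
        base = 5 + 4 * (r - lo) / max(hi - lo, 1e-9)
        n_nodes = int(np.clip(round(base + rng.normal(0.0, 0.7)), 5, 9))
        if self.name == "ND5":
            hole_r = rng.uniform(0.27, 0.35) * r
            n_ca9 = int(rng.integers(1, 4))
            inten["ecadherin"] = float(np.clip(rng.normal(6460.0, 660.0), 2000, 40000))
        elif self.name == "ND1":
            hole_r = rng.uniform(0.25, 0.33) * r
            n_ca9 = int(rng.integers(0, 2))
            inten["ecadherin"] = float(np.clip(rng.normal(8600.0, 1320.0), 2000, 40000))
        else:
            raise ValueError(f"unknown condition profile: {self.name!r}")
        return PhantomSpec(
            **common,
            n_nuclei=int(rng.integers(45, 70)),
            n_nodes=n_nodes,
            node_radius_um=rng.uniform(4.0, 6.0),
            scar_radius_um=0.0,
            ca9_rim_um=0.0,
            n_ca9_blobs=n_ca9,
            hole_radius_um=hole_r,
            intensity=inten,
        )


def get_profile(
    name: str,
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5),
    radius_range_um: tuple[float, float] = (35.0, 80.0),
    markers: tuple[str, ...] = ("laminin", "ecadherin", "ca9"),
) -> ConditionProfile:
    """Look up a named condition profile (``ND1``, ``ND5`` or ``HD5``)."""
    if name not in PROFILE_NAMES:
        raise ValueError(f"unknown condition profile {name!r}; expected one of {PROFILE_NAMES}")
    return ConditionProfile(
        name=name, voxel_size=voxel_size, radius_range_um=radius_range_um, markers=markers
    )


def generate_cohort(
    profile: ConditionProfile | str,
    n: int,
    seed: int,
) -> list[tuple[VoxelGrid, PhantomTruth]]:
    """Generate ``n`` independent phantoms for one condition.

    Per-islet seeds derive deterministically from ``(seed, islet index)``;
    the profile name never enters the derivation, so cohorts generated for
    different profiles from the same seed are paired islet-by-islet (same
    radius draws — islet volume is identically distributed across groups).
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    out = []
    for i in range(n):
        ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, i])
        islet_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        rng = np.random.default_rng(ss)
        spec = profile.sample_spec(rng, seed=islet_seed)
        out.append(generate_islet_phantom(spec))
    return out


# ---------------------------------------------------------------------------
# 2D viability phantoms


def generate_viability_image(
    viable_fraction: float,
    n_islets_2d: int = 6,
    seed: int = 0,
    canvas_shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 2.0,
    stain_au: float = 3000.0,
    background_au: float = 60.0,
    noise_gaussian_au: float = 30.0,
) -> tuple[np.ndarray, PhantomTruth]:
    """Emulate a fluorescein / propidium-iodide live-dead image.

    Disk-shaped islet silhouettes are partitioned into a green-labelled
    (viable) and a red-labelled (dead) region; the planted green area over
    total stained area equals ``viable_fraction`` up to one pixel's
    quantization.  Dead regions grow from a random "pole" per islet, so they
    look like contiguous necrotic sectors rather than salt-and-pepper labels.

    Returns a ``(2, H, W)`` uint16 array (channel 0 = green, 1 = red) and a
    truth record whose ``viable_fraction`` is the exact planted ratio.
    """
    if not 0.0 <= viable_fraction <= 1.0:
        raise ValueError(f"viable_fraction must lie in [0, 1], got {viable_fraction}")
    if n_islets_2d < 1:
        raise ValueError("need at least one islet silhouette")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 2]))
    H, W = canvas_shape
    yy, xx = np.mgrid[0:H, 0:W]
    occupied = np.zeros((H, W), dtype=bool)
    disks = []  # (mask, center, pole angle)
    attempts = 0
    while len(disks) < n_islets_2d and attempts < 200 * n_islets_2d:
        attempts += 1
        rad = rng.uniform(25.0, 90.0) / pixel_size_um  # ø 50-180 µm silhouettes
        cy = rng.uniform(rad + 2, H - rad - 2)
        cx = rng.uniform(rad + 2, W - rad - 2)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = d2 <= rad**2
        if (disk & occupied).any():
            continue
        occupied |= disk
        disks.append((disk, (cy, cx), rng.uniform(0, 2 * math.pi)))
    if not disks:
        raise PlacementError("could not place any islet silhouette on the canvas")

    # order all stained pixels: islet by islet, by distance from that islet's
    # necrosis pole; the global red quota fills from the end of this ordering.
    order_rows = []
    for k, (disk, (cy, cx), ang) in enumerate(disks):
        ys, xs = np.nonzero(disk)
        pole = (cy + math.cos(ang) * 1e3, cx + math.sin(ang) * 1e3)
        d = (ys - pole[0]) ** 2 + (xs - pole[1]) ** 2
        sub = np.argsort(d, kind="stable")[::-1]  # farthest from pole first
        order_rows.append(np.column_stack([np.full(len(ys), k), ys[sub], xs[sub]]))
    order = np.concatenate(order_rows)
    n_total = len(order)
    n_green = int(round(viable_fraction * n_total))
    green = np.zeros((H, W), dtype=bool)
    red = np.zeros((H, W), dtype=bool)
    green[order[:n_green, 1], order[:n_green, 2]] = True
    red[order[n_green:, 1], order[n_green:, 2]] = True

    img = np.full((2, H, W), background_au, dtype=np.float64)
    img[0][green] = stain_au
    img[1][red] = stain_au
    if noise_gaussian_au > 0:
        img += rng.normal(0.0, noise_gaussian_au, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth = PhantomTruth(
        islet_mask=occupied[None],
        marker_masks={"viability_green": green[None], "viability_red": red[None]},
        node_count=0,
        node_centers_um=np.zeros((0, 3)),
        hole_fraction_pct=0.0,
        viable_fraction=n_green / n_total,
        intensities={"viability_green": stain_au, "viability_red": stain_au},
        spec=PhantomSpec(voxel_size=(1.0, pixel_size_um, pixel_size_um), seed=seed),
    )
    return img, truth


def analysis_config(**overrides) -> "PipelineConfig":
    """A pipeline configuration matched to the phantom rendering defaults.

    Markers rendered at a fixed nominal intensity (laminin, CA9, collagen 4,
    fibronectin, nuclei, hormones) get an absolute threshold at half that
    intensity; E-cadherin, whose brightness varies across conditions, uses
    the per-stack Otsu default.  The islet threshold is likewise left to
    Otsu on the smoothed channel sum, which tracks the condition-dependent
    plateau automatically.
    """
    from .imageio import MarkerParams, PipelineConfig

    markers = {
        name: MarkerParams(sigma_um=1.0, threshold=_DEFAULT_INTENSITIES[name] / 2.0)
        for name in ("laminin", "ca9", "collagen4", "fibronectin", "insulin", "glucagon")
    }
    markers["ecadherin"] = MarkerParams(sigma_um=1.0, threshold=None)
    defaults = dict(islet_threshold=None, min_islet_volume_um3=5000.0, markers=markers)
    defaults.update(overrides)
    return PipelineConfig(**defaults)
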