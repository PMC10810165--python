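# Methods

## Scope and data model

`islet3d` quantifies multi-channel 3D fluorescence stacks of cleared,
light-sheet-imaged pancreatic islets, plus 2-channel 2D live/dead images.
A stack is a `VoxelGrid`: a `(channel, z, y, x)` array of nonnegative
integers (8- or 16-bit, never rescaled on I/O), physical voxel sizes
`(dz, dy, dx)` in µm (anisotropy allowed — LSFM z-spacing typically exceeds
the lateral pixel size), and a channel map naming each marker. All length
parameters are specified in µm and converted to voxel units per axis, so
results are invariant to resampling conventions. Intensities are carried in
the acquisition's arbitrary units (AU); no calibration is assumed.

## Islet delineation

The islet surface is defined on the sum of all channels: Gaussian smoothing
(`sigma_islet_um`, default 3 µm), a global threshold, filling of internal
cavities (an unstained necrotic core still belongs to the islet), 26-connected
component labelling, a minimum-volume filter (default 5000 µm³ ≈ a 10.6 µm
sphere, well below any real islet) and relabelling by decreasing volume.
The default threshold is Otsu's method on the smoothed sum: a fixed AU
threshold cannot track condition-dependent staining brightness and was
measured to inflate islet volume by >20 % on dim stacks, while Otsu lands
near half the interior plateau and recovers planted phantom volumes to <1 %.
An explicit `islet_threshold` overrides it.

Touching islets are separated by a watershed on the smoothed Euclidean
distance transform. Markers are the h-maxima of the distance map with
`h = 0.25 · max(dt)` — only maxima rising well above their connecting neck
seed a split, which suppresses spurious splits of single, slightly
irregular islets — merged when closer than `split_min_separation_um`
(default 15 µm). A split is accepted only if every part clears the minimum
islet volume; labelled voxels are conserved. Manual artifact curation is
replaced by a config exclusion list of islet ids (`"stackname:id"`).

## Stain detection

Per marker: Gaussian filter (default sigma 1 µm) then a threshold, either
on absolute intensity or after subtracting a copy blurred at
`background_sigma_um` (default 20 µm, must exceed the filter sigma;
negatives clamped to zero). No morphological post-processing is applied, so
raising a threshold can only shrink a mask (a tested monotonicity
invariant). Which mode suits which protein is configuration, not fact.
Default thresholds are per-channel Otsu; note that Otsu is only meaningful
when the channel actually contains signal — on a signal-free channel it
splits the noise floor. For phantom analysis,
`islet3d.phantom.analysis_config()` therefore pins absolute half-intensity
thresholds for the markers the generator renders at fixed brightness and
keeps Otsu only for E-cadherin, whose level varies across conditions.

## Morphometry

* **Islet volume**: voxel count × voxel volume (µm³).
* **Volume fraction**: `100 · |stain ∩ islet| / |islet|`; stain outside the
  islet is ignored. CA9 abundance is this fraction on the CA9 channel.
* **Nodes** (laminin): 26-connected components of the stain within the
  islet, discarding components below `min_node_volume_um3` (default the
  volume of a 3 µm-radius sphere, 113 µm³ — above single-voxel noise
  speckle, below any genuine node). Component volumes are reported
  alongside the count to make "fewer but larger" scarring quantifiable.
* **Holes** (E-cadherin): within the islet, unstained 26-connected
  components that do **not** reach the boundary shell (voxels within
  `boundary_margin_um`, default 3 µm, of the islet surface) and exceed
  `min_hole_volume_um3`; reported as % of islet volume. The enclosure rule
  is this package's definition of a "central hole": open surface
  indentations never count. Distances use the anisotropic physical metric.
* **Mean intensity**: arithmetic mean of the raw, unfiltered channel over
  the islet (AU).
* **Viability** (2D): threshold each channel (per-channel Otsu by default);
  viability = green area / (green ∪ red) area. An image with no stained
  area raises a distinct error instead of returning a number.

## Statistics

Samples are screened with Shapiro–Wilk (n between 3 and 5000, nonconstant).
A sample failing at `alpha` and strictly positive is natural-log
transformed; nonpositive data are never silently shifted. Two-group
comparisons use Welch's unequal-variance *t* on the working values (pooled
variance optional, giving the exact F = t² duality with one-way ANOVA,
verified to 1e-9); k-group comparisons use one-way fixed-effects ANOVA;
associations use Pearson's r. Reported means and SDs always describe the
untransformed data, with the transform recorded per comparison. No
multiple-testing correction is applied by default (two-by-two reporting);
Holm-adjusted p-values are available and their use is recorded. All kernels
delegate to scipy.stats and are pinned against an independent R reference
(shapiro.test, t.test, anova(lm), cor.test) to 1e-6 on fixed fixtures.

## Synthetic phantoms

The generator renders geometric primitives into an islet — a
volume-preserving, slightly ellipsoidal ball (shape jitter ±6 % per axis by
default) of radius 25–125 µm:

| structure | primitive | intensity default (AU) |
|---|---|---|
| nuclei | non-overlapping 3 µm spheres, strictly interior, excluded from the scar core | 8000 |
| laminin | n spherical nodes; pairwise centre separation ≥ 2·(node radius + max PSF sigma) in well-separated mode | 5000 |
| E-cadherin | islet minus a central spherical cavity (the planted hole) | 6500 (condition-dependent) |
| CA9 | shell of thickness `ca9_rim_um` around the central scar, plus optional sporadic blobs | 5000 |
| collagen 4 | tubes of radius 3 µm along random chords; condensed central blob when a scar is present | 5000 |
| fibronectin | boundary mesh of a seeded 3D Voronoi partition of the interior | 4000 |
| insulin / glucagon | cytoplasm (interior minus nuclei) | 6000 |

Rendering: masks at stated intensities over a 100 AU background →
anisotropic Gaussian PSF (defaults σ_xy = 1 µm, σ_z = 2 µm) →
signal-dependent Poisson noise (gain 10 AU/photon) plus Gaussian read noise
(σ = 50 AU) → clip to 16 bits. The pre-blur, pre-noise masks are the ground
truth; the planted hole fraction is exactly the voxel ratio. Because a
sub-voxel gap can fuse two rasterized balls into one 26-connected
component, node placement is resampled until the planted mask has exactly
n components — the separation contract holds on the actual grid, not just
in continuous space. Seeding is hierarchical (per-structure substreams from
fixed labels; per-islet cohort seeds from (cohort seed, islet index)), so
identical specs are bit-reproducible, adding a structure does not reshuffle
the others, and cohorts of different conditions built from one seed are
paired islet-by-islet — in particular islet radii, and hence volumes, are
identically distributed across groups by construction.

Condition profiles encode the contrast between normoxia and hypoxia as
parameter distributions: islet radius uniform on 35–80 µm for every group;
normoxic islets get 5–9 laminin nodes of radius 4–6 µm (count increasing
with islet radius plus unit jitter, which induces the node-count /
islet-volume correlation), a modest central cavity (hole radius 0.25–0.35
of islet radius), sporadic or absent CA9, and E-cadherin intensity drawn
near 8600 (day 1) or 6460 (day 5) AU; hypoxic islets get 1–2 central nodes
of radius 0.15–0.20 R, a scar of 0.38–0.46 R with a 6 µm CA9 rim, a large
cavity (0.40–0.48 R), scarce nuclei and E-cadherin near 14800 AU. The 2D
viability generator partitions disk silhouettes into a viable (green) and a
dead (red) region growing from a random pole per islet, with the planted
green share exact to one pixel.

What the phantoms do **not** emulate: light-sheet stripe artifacts,
depth-dependent attenuation or refractive-index mismatch, real vascular
topology, nuclear texture, or any empirical intensity statistics of real
acquisitions (the AU levels are free parameters). Passing recovery tests
therefore demonstrates correctness of the measurement chain under the
stated image-formation model, not performance on real microscopy data.

## Numerical choices and degenerate inputs

Thresholding uses `>=`; component labelling uses 26-connectivity for both
islets and stains (the most inclusive voxel analogue of surface-based
delineation); relabelling sorts by decreasing volume with ties broken by
prior label for determinism. Empty delineations are valid (K = 0), an empty
stain gives 0 nodes and 0 %, a fully stained islet gives 0 % holes, and a
constant sample or n < 3 is rejected by the normality check with a distinct
error. Identical constant groups compare as t = 0, p = 1. Otsu falls back
to an empty mask on a constant channel. Per-stack and per-islet failures in
a pipeline run are recorded and skipped; a run with zero measured islets
exits nonzero. Reports embed the resolved configuration, package version,
seed and SHA-256 digests of file inputs; figures are rendered without
timestamps so reruns are byte-identical.

## Problem sizes

Defaults target desk-scale runtimes: phantoms are rendered at 1.5 µm
isotropic voxels on a canvas fitted to the islet (≈100–130³ voxels), with a
2× z-anisotropy preset available. The recovery test cohorts use 20 islets
per condition at 2 µm voxels (radii 35–60 µm); the replicate
phenotype-detection study uses 50 seed-paired cohorts of 8 islets per group
at 3 µm voxels (radii 30–55 µm); the acceptance script runs 8 islets per
group at the default 1.5 µm scale. These sizes are the package's chosen
trade-off between voxel-quantization error and runtime; all scale knobs
(voxel size, radius range, cohort size) are ordinary parameters.

## Known limitations

Node volumes are biased low (~30 % for 5 µm nodes) by half-maximum
thresholding of small blurred spheres; counts are unbiased under the
separation constraint. Hole fractions inherit a few-percent bias from the
adaptive E-cadherin threshold interacting with the PSF (well within the
±15 % recovery tolerance at the tested scales). The watershed splitter
handles moderately overlapping near-convex islets; heavily fused clusters
may stay merged (the conservative failure mode). The statistics module
implements only the workflow above — no mixed models, repeated measures or
Bayesian alternatives.
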