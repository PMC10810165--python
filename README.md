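# islet3d

3D morphometry of cleared, light-sheet-imaged pancreatic islets.

Pancreatic islets (ø 50–250 µm) lose extracellular matrix (ECM) during
isolation and suffer hypoxia after transplantation. Tissue clearing plus
light-sheet fluorescence microscopy (LSFM) makes whole-islet 3D imaging
routine, but turning those multi-channel stacks into numbers — how much of
an islet is stained for collagen 4, fibronectin, laminin, E-cadherin,
insulin, glucagon or the hypoxia marker CA9, and how the staining is
*arranged* — requires a reproducible digital image analysis. `islet3d`
implements that analysis as an open, tested library:

* **segmentation** — islets are delineated on the Gaussian-smoothed sum of
  all channels by global thresholding, cavity filling and 26-connected
  component labelling; touching islets are separated by a
  distance-transform watershed. Stained volume per marker is detected by a
  Gaussian filter followed by an absolute-intensity or
  background-subtracted threshold, with no morphological post-processing.
* **morphometry** — per islet *i* and marker *m*: islet volume
  `V_i = N_i · dz·dy·dx` (µm³), stained volume fraction
  `f_im = 100 · |S_m ∩ I_i| / |I_i|` (%), laminin **node** count (discrete
  26-connected blobs above a minimum volume), E-cadherin **hole** fraction
  (interior unstained cavities that do not reach the islet boundary shell,
  as % of islet volume), raw mean intensity (AU), and 2D live/dead
  viability `green / (green ∪ red)`.
* **stats** — Shapiro–Wilk normality screening with an optional natural-log
  transform, two-by-two independent-means comparisons (Welch's *t* by
  default), one-way ANOVA, Pearson correlations; group summaries are always
  mean ± SD of untransformed data.
* **phantom** — a seeded synthetic generator that emulates normoxic (ND1,
  ND5) and hypoxic (HD5) islet morphologies — scattered laminin nodes vs.
  one or two central scars, central E-cadherin voids, CA9 rims around the
  necrotic core, scarce nuclei, anisotropic PSF blur and Poisson–Gaussian
  noise — with exact voxel-level ground truth, so every pipeline stage is
  verifiable without microscopy data.

Audience: groups doing islet transplantation research or 3D
immunofluorescence quantification who want the measurement chain to be
scriptable, seedable and testable end to end.

## Worked example

```bash
python examples/02_segment_and_measure.py
```

```text
islets found: 1
islet volume: measured 697,231 µm³ vs planted 697,049 µm³
laminin    stained volume:   0.31 % (planted   0.45 %)
           nodes: 6 (planted 6); volumes [354, 358, 358, 361, 368, 375] µm³
ecadherin  stained volume:  97.10 % (planted  97.05 %)
           hole fraction: 2.86 % (planted 2.95 %)
           mean intensity: 6,124 AU
ca9        stained volume:   0.00 % (planted   0.00 %)
```

One normoxic phantom islet: the delineated volume matches the planted
sphere to 0.03 %, all six planted laminin nodes are recovered, the central
E-cadherin hole (2.95 % of islet volume planted) is measured at 2.86 %, and
CA9 is absent, as expected under normoxia. Node *volumes* run ~30 % below
the planted spheres — half-maximum thresholding of small blurred spheres
shrinks them — which is why node *count*, not node volume, is the primary
endpoint. `examples/04_cohort_statistics.py` runs three seed-paired
cohorts end to end and prints the group table and tests (hypoxia: fewer
nodes, bigger holes, brighter E-cadherin, CA9-positive core; islet volume
not different).

Other entry points: `examples/01_phantom_and_truth.py` (generator ground
truth), `examples/03_viability.py` (live/dead ratio), and a thin CLI —
`islet3d phantom|run|stats|viability --help` — for batch runs over TIFF
stacks listed in a manifest.

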