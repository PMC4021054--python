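# Methods

This note records the models behind `trabmorph`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic phantoms do
and do not establish about real data.

## Coordinate and grid conventions

All grids use one axis order: axis 0 anterior-posterior (the MR slice
direction), axis 1 vertical with superior at row 0 (image-row convention),
axis 2 medial-lateral.  Every extent, spacing and origin triple follows the
same order, in millimetres.  A voxel with index `(i, j, k)` occupies the
half-open box `[origin + idx·spacing, origin + (idx+1)·spacing)`; its
centre sits at `origin + (idx + ½)·spacing`.

Two region rules are used, both defined in physical units:

- **2D ROIs** (MR morphometry): a pixel belongs to a rectangle iff its
  centre falls in the half-open rectangle.  On grids where the ROI size is
  an exact multiple of the spacing (the standard 0.69 mm ROI on a 0.23 mm
  grid, or 0.25 mm phantom grids) this gives the exact expected count.
- **3D VOIs** (microCT morphometry): a voxel is kept iff it lies entirely
  inside the half-open box, i.e. `floor(extent / spacing)` voxels per axis
  for a grid-aligned box.  This makes the realized extent never exceed the
  requested VOI, which is the conservative choice when the VOI is meant to
  delimit total volume.

## The phantom

### Microstructure

Cadaveric trabecular bone is emulated by a thresholded Gaussian random
field: white noise smoothed with a Gaussian kernel of width
`trabecular_scale` (default 0.3 mm, conventional trabecular spacing), then
cut at the empirical quantile `1 − target_bvtv` of its own values.
Quantile thresholding is the point of the construction: the realized bone
fraction equals the target up to one voxel of rank granularity (ties have
probability zero in a continuous field), so the phantom is an exact oracle
for every downstream estimator.  Rod/plate lattice models would look more
like bone but forfeit that exactness; they are out of scope.

A slab of pure bone of thickness `cortical_plate_thickness` (default
0.4 mm) is prepended on the superior face to mimic the subchondral cortical
plate.  It is excluded from the trabecular-fraction accounting and from the
microCT VOI, but the MR measurement ROI deliberately includes it, as the
clinical protocol does.

### Geometry

The real acquisition (9 μm isotropic over a ~17 × 14 × 4 mm VOI) is ~10⁹
voxels; the default phantom instead uses a 0.05 mm isotropic fine grid over
a 10 × 4 × 10 mm VOI (3.5 M voxels), preserving the qualitative MR : CT
resolution ratio (20 : 1 through-plane, 5 : 1 in-plane) at desk scale.
`fine_spacing` is a plain knob for anyone wanting finer grids.

### Renderings

*MicroCT-like*: bone voxels drawn at gray 180, marrow at 40, independent
Gaussian noise (σ = 5), clipped to [0, 255].  With the standard [80, 255]
binarization window both classes sit ≥ 8σ from the threshold, so
misclassification is negligible by the Gaussian tail bound — the rendering
exists to exercise the chain, not to model scanner physics.

*MR-like*: each MR voxel's bone fraction `f` is the block average of the
truth (the partial-volume mechanism); the noiseless signal is
`f·bone_signal + (1−f)·marrow_signal` (defaults 20 and 200, bone dark);
Rician noise is the magnitude `|(s + σg₁) + i·σg₂|` with independent
standard Gaussians and σ = 10 — the standard magnitude-image model.
`mr_spacing` must be an integer multiple of the fine spacing per axis; the
default (1.0, 0.25, 0.25) mm is the clinical geometry snapped to the
0.05 mm grid (0.25 rather than 0.23 mm in-plane).  Trailing fine voxels
that do not fill a block are cropped (the superior face, carrying the
plate, is always preserved).  Optional lesion boxes multiply the marrow
signal locally before mixing, emulating hyperintense bone-marrow lesions.

### Cohorts

`generate_cohort` draws `n` specimens with true BV/TV evenly spaced over
`bvtv_range` (default 0.10–0.45, bracketing the 12–45% range seen in the
reference table).  Specimens are labelled like a paired-knee cohort
(consecutive specimens share a donor id, sides alternate right/left) purely
to exercise the per-side subgroup analysis; no anatomical asymmetry is
modelled.  All randomness descends from one seed through spawned
`SeedSequence` children, so identical spec + seed reproduces every volume
bit for bit.

## MR morphometry

The threshold is the pooled mean of all pixels in twenty 0.69 × 0.69 mm
cortical ROIs.  How twenty ROI readings become one threshold is genuinely
underdetermined in the field; the pooled mean is the simplest defensible
statistic, and `pooled_mean_plus_sd` / `percentile` variants are exposed
for sensitivity analyses.  On phantoms, calibration runs on a separately
rendered pure-cortical block (a stand-in for the thick femoral-condyle
cortex used clinically) because the default 0.4 mm subchondral plate is
thinner than the 0.69 mm ROI.

Measurement places one rectangle (default 3.75 mm high × 15.00 mm wide)
identically on the central consecutive slices (default 20; ties in the
centring broken toward the lower index).  The in-slice anchor must be
supplied — placing it anatomically is an operator decision the package does
not automate.  Apparent BV/TV per slice is the fraction of ROI pixels *at
or below* the threshold (inclusive), and the specimen value is the mean of
per-slice fractions (with a constant ROI footprint this coincides with
pooling, but the per-slice definition is the contract).

Two exact properties pin the implementation: at truth resolution with zero
noise and any threshold strictly between the bone and marrow signals, the
measure equals the true voxel fraction; at coarse resolution with zero
noise and a plate-calibrated threshold, only pure-bone voxels can pass, so
the measure is a guaranteed underestimate — the mechanism behind the
systematic negative bias the validation quantifies.

For the desk-scale phantom the pipeline defaults shrink the protocol to the
geometry available: 10 slices of 1 mm (the phantom's full
anterior-posterior extent) and an 8 mm ROI width inside the 10 mm
medial-lateral extent, anchored at the superior face so the plate is
included.  These are the package's own scaled protocol choices, recorded
here; the function-level defaults keep the full-size clinical values.

## microCT morphometry

Binarization is a global two-sided window, both bounds inclusive (a voxel
exactly at 80 is bone).  BV/TV defaults to the marching-cubes estimate: the
mask is padded with one background voxel per face, the 0.5 iso-surface is
extracted with linear interpolation, and the enclosed volume is the
divergence-theorem sum of signed tetrahedra (origin-anchored, one per mesh
triangle).  TV is voxel count × voxel volume of the extracted VOI, not the
mesh bounding box.  Orientation consistency is checked by requiring the
|signed volume| to exceed a quarter of the bone-voxel volume — a mixed
orientation cancels volume and fails that bound.

One geometric fact worth stating: the iso-surface runs half a voxel outside
the outermost bone centres on flat faces but *chamfers* edges and corners
diagonally, so a full cuboid reads ≈ 0.986, not 1.0, and small isolated
structures are shaved slightly.  This is inherent to marching cubes with
linear interpolation; the voxel-count estimator has no such bias, the two
agree within 0.02 on smooth structures at the default grids, and the gap
shrinks under grid refinement.  Tests assert exactly this behaviour rather
than an idealised closed form.

## Agreement statistics

- Spearman ρ is the Pearson correlation of mid-ranks (average ranks on
  ties); constant vectors are an explicit error, not a NaN.
- The CI uses the Fisher z-transform with SE `1/√(n−3)`; the heavier-tailed
  Bonett-Wright SE `√((1+ρ²/2)/(n−3))` is available behind a flag.  With
  the bundled table's ρ = 0.830 and n = 10 the Fisher form reproduces the
  reference interval (0.42, 0.96) at two decimals, which is why it is the
  default.
- Bland-Altman differences are **MR − microCT** everywhere, stated in every
  output, so conservative-threshold underestimation appears as negative
  bias; limits are bias ± 1.96·SD with the n−1 SD.
- ICC(3,1) comes from the two-way ANOVA decomposition,
  `(BMS − EMS)/(BMS + (k−1)·EMS)` — consistency form, insensitive to fixed
  rater offsets.
- RMS %CV uses the two-replicate SD `|d|/√2` (n−1 divisor; the n-divisor
  `|d|/2` variant is a flag) over the pair mean, root-mean-squared across
  pairs.
- The Fisher-z sample size is `⌈((z_{1−α/2}+z_{power})/(atanh ρ₁ − atanh
  ρ₀))² + 3⌉`; at ρ₁ = 0.80, α = 0.05, power 0.80 it gives 10.
- Comparisons against printed values round half-up to two decimals.
- Each knee is treated as an independent observation, matching the
  reference analysis; donor-level clustering is a known limitation, not
  modelled.

In the bundled table the per-side coefficients computed from the raw pairs
are 0.90 (right) and 0.80 (left); published prose swaps the two labels, so
programmatic checks compare the unordered pair.

## What the phantom does and does not show

Passing the synthetic end-to-end tests demonstrates: exact BV/TV control;
correct geometry handling across anisotropic grids; the partial-volume +
conservative-threshold mechanism producing systematic MR underestimation
with preserved ranking; and marching-cubes/voxel-count consistency.  It
does **not** demonstrate fidelity to real tissue: the Gaussian-field
microstructure has no rod/plate anisotropy, the renderings ignore
steady-state MR signal equations, coil profiles, chemical shift, beam
hardening and reconstruction artifacts, and the phantom's near-perfect
cross-modality correlation (ρ ≈ 1 at n = 10) is cleaner than cadaveric
reality (ρ ≈ 0.8 with wide CI).  The synthetic cohort validates the
*pipeline*, while the bundled cadaveric table validates the *statistics*.

## Problem sizes

Defaults used by the test suite and the acceptance script: fine grid 0.05 mm
over 10 × 4 × 10 mm (3.5 M voxels per specimen), cohorts of 10, twenty
replicate cohorts for the Monte-Carlo direction-of-bias checks, 50 seeds
for the threshold-calibration band, and 64³–128³ grids for estimator
agreement and refinement ladders.  One full synthetic experiment runs in
~10 s on a single core.
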