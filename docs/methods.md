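# Methods

`perivasc` quantifies phospho-tau, neurons and neurofibrillary tangles (NFTs)
relative to individual blood vessels in 3D cleared-tissue image volumes. This
note records the models and conventions the package implements, the choices
made where the design was genuinely open, and what the synthetic phantoms do
and do not establish.

## Coordinate and unit conventions

Volumes are 3D scalar grids in (x, y, z) axis order (z = TIFF page index)
with per-axis voxel spacing in micrometres; spacing is a required input and
may be anisotropic everywhere. The world position of voxel (i, j, k) is
(i·sx, j·sy, k·sz) µm — one fixed corner convention, so there is no
half-voxel ambiguity anywhere in the pipeline. Distances are reported in µm
and volumes in mm³ (µm³ × 10⁻⁹).

## Vessel geometry

**Surface distance field.** For each vessel mask, every voxel gets the
Euclidean distance (anisotropy-aware, via the sampled distance transform) to
the nearest mask voxel; voxels inside the mask are 0. Distance inside the
vessel is *defined* as 0 — the analysis measures tau away from the abluminal
surface and never uses negative/inside distances — so the 3 µm "surface"
window contains the mask itself plus the first 3 µm of surrounding tissue.

**Centerline.** The mask is thinned to a 3D skeleton; the skeleton voxels
form a graph (26-connectivity, world-distance edge weights) and the
centerline is the longest geodesic path between skeleton endpoints, which
discards spur branches automatically. The path is smoothed with a 5-point
moving average, resampled at ≤1 µm steps, and *extended along the end
tangents* while still inside the mask: topological thinning retracts the
skeleton by roughly one radius from each tube end, and without the extension
cylinder arc lengths would be biased short by 2r. Orientation is made
deterministic by putting s = 0 at the endpoint with the lexicographically
smaller world coordinate.

Validation on analytic tubes: cylinder, quarter-arc and helix arc lengths
recover to within 5% (typically <1%), the extracted polyline stays within
one voxel of the true axis for tube radii ≥ 3 voxels, and arc length is
rotation-invariant to within 2%.

**Arc-length coordinate.** A point's distance-along-vessel is the cumulative
arc length of its *nearest centerline vertex* (ties broken toward the
smaller s). With ≤1 µm resampling this matches orthogonal projection to
within the resampling step, and is exactly reproducible.

**Diameter.** At three centerline sites (25/50/75% of arc length —
deterministic, rather than operator-chosen "separate locations") the maximal
chord of the mask across the plane perpendicular to the local tangent is
measured by ray-marching at quarter-voxel steps over 24 in-plane directions;
the diameter is the mean over sites. On voxelized cylinders this is accurate
to ~2 voxel edges.

## Intensity normalization

Raw fluorescence is not comparable across samples. Per sample, raw
intensities of three reference regimes — background, tissue
autofluorescence, unambiguous tau positivity — are recorded at 3 z-depths
with 10 measurements per category per depth, averaged into three anchor
means (grand means over all 30 values; a per-depth variant would be
possible but the grand-mean reading is used). A two-segment piecewise-linear
map sends the anchors to fixed canonical targets (0, 1, 2); beyond the end
anchors the adjacent segment's slope extrapolates linearly, so extreme NFT
intensities keep their ordering rather than saturating. The map is strictly
monotone, and two samples that differ by an affine intensity distortion
(gain/offset) with correspondingly shifted anchors normalize to identical
volumes — the harmonization property the cross-sample comparisons rely on.

Note one consequence of the canonical scale: normalized background sits near
0, so background-level measurements can be slightly negative under noise,
and log-ratio heatmap cells with non-positive ratios are reported as
missing.

## Vessel-relative quantification

**Voxel records.** Every tissue voxel within 100 µm of a vessel surface is
exported with position, raw and normalized intensity, cortical layer,
distance-from-surface and distance-along-vessel. A voxel in range of several
vessels is attributed only to the nearest one (ties to the lower vessel id),
so no voxel is double-counted; other vessels' lumina are excluded.

**Segment bins.** Each vessel is tiled into 10 µm arc-length intervals
([k·10, (k+1)·10)); the terminal bin may be shorter and is kept but flagged.
Each bin's *surface tau* is the mean normalized intensity of its voxels
within 3 µm of the surface; bins with no surface voxels are excluded from
ranking. Each bin also gets the majority cortical layer of its surface
voxels (ties to the smaller label).

**Deciles.** Rankable bins are sorted by surface tau (ties broken by donor,
vessel, bin index for determinism) and split into 10 rank groups; group g
holds rank fractions ((g−1)/10, g/10], so group sizes differ by at most one.
Pooling is cohort-wide by default (all vessels and donors ranked together,
matching cross-donor segment comparisons); per-donor scope is available via
the `scope` argument.

**Radial profiles.** Voxel records inherit their bin's decile; for each 1 µm
distance step the percent change relative to the donor's whole-normalized-
image mean is reported, per donor and decile, plus the across-donor
mean ± SEM. 0% means vessel-adjacent tau is indistinguishable from the image
average.

**Heatmaps and layer summaries.** Per-vessel rows of
log₁₀(surface tau / whole-image mean) over bins, padded with missing values
to the longest vessel; and per-donor per-layer means of surface tau over
bins (layer 0 = unassigned tissue is excluded).

## Object densities

Segmented neurons and NFTs (ingested from object tables, or from the
built-in threshold + 26-connected-components stand-in segmenter) get the
trilinearly interpolated distance to the nearest vessel surface; objects
within the 30 µm shell get that vessel's arc-length coordinate and bin.
Shell volumes are voxel-counted per bin (≤30 µm, excluding the lumen and
tissue nearer to another vessel) and converted to mm³; densities are
count/volume. A neuron counts as NFT-bearing when an NFT centroid lies
within a 5 µm colocalization radius — the cross-channel matching rule is not
otherwise specified, so the radius is an explicit, configurable stand-in
(an NFT is an intrasomatic aggregate, so centroid separation is small).
The NFT fraction per donor and decile pools counts over the donor's bins:
100 · Σ(NFT-bearing neurons) / Σ(neurons).

## Statistics

**Repeated-measures ANOVA.** The NFT fraction table (donors × deciles) is
analyzed as a one-way within-subject ANOVA with donor as the subject factor:
SS_total = SS_subject + SS_effect + SS_error, F = MS_effect/MS_error with
df = (k−1, (n−1)(k−1)). The reported R² is partial eta-squared,
SS_effect/(SS_effect+SS_error), chosen because the subject variance is
absorbed by the design; the definition is recorded here explicitly since
several conventions exist. Donor × decile cells missing in any donor drop
that decile level (complete-case on levels, logged in the result); no
imputation. No sphericity correction is applied by default;
Greenhouse–Geisser is available as an option. The implementation is
validated against an explicit sums-of-squares oracle and against an
independent reference implementation, its type-I error is nominal over 500
simulated null cohorts, and it is exactly invariant to adding per-donor
constants.

**Two-group tests.** Shapiro–Wilk at α = 0.05 on both groups gates the
comparison: both normal → equal-variance two-tailed t test, otherwise
two-sided Mann–Whitney U. Constant samples are treated as failing normality;
two identical constant groups are a degenerate case reported with p = 1.

**Lane intensities.** Capillary-Western lane totals are divided by the mean
of the control lanes per antibody (normalized control mean = 1 by
construction) and compared with a one-tailed equal-variance t test in the
stated direction, flagged at p < 0.05 and p < 0.01.

## Synthetic scenes

The generator builds volumetric phantoms with the statistical structure the
analysis assumes, so every stage is testable without donor data:

* **Vessels**: straight, arc or helix paths swept by a circular
  cross-section (radii 5–8 µm → diameters 10–16 µm, near the arteriole
  calibre the analysis targets), spanning the stacked cortical layers.
  Tubes are truncated flat at the path ends by default, the way traced
  masks end where tracing stops; this also keeps the generator's arc-length
  frame aligned with the extracted centerline to well under a bin length.
* **Tau channel**: Gaussian background (mean 100, SD 10), autofluorescence
  as fine-grained lipofuscin-like speckle (smoothed-noise blotches,
  σ = 1.5 µm, 20% volume fraction, mean 160), and vessel-anchored
  enrichment: amplitude · exp(−d_surface/decay) over chosen arc-length
  segments (default one 20 µm segment, amplitude 300 = 30× noise SD,
  decay 10 µm — the decay length is a scene choice, not an estimate of
  tissue behaviour). Enrichment segment edges sit mid-bin by default so
  edge bins are half-enriched rather than ambiguous. A per-donor affine
  gain/offset distortion emulates staining differences; anchor
  "measurements" are sampled from the true regime masks (a scene with no
  positivity, e.g. a control donor, uses operator-style calibration values
  for the positive anchor).
* **Objects**: neurons are a uniform Poisson process over tissue
  (100,000/mm³ — upper human-cortex range, chosen so the scaled-down scene
  volume still populates donor × decile cells); each neuron bears an NFT
  with probability clamp(base + slope · score, 0, 1) where score is the
  true normalized surface tau of its nearest segment (defaults base 0.05,
  slope 0.25). The link is linear-in-probability rather than logistic so
  recovery tests have closed-form expectations. NFT objects are emitted at
  the soma position with sub-µm scatter.
* **Layers**: planes along the vessel axis partition the volume into labels
  1–6 (a scaled-down cortex; real layers are an order of magnitude
  thicker).

Scenes are deterministic given their seed; a bundle (TIFF/HDF5 volumes,
object CSV, ground-truth JSON with true centerlines, enrichment segments,
anchors and the NFT link) is written for file-based runs.

**Problem sizes.** The test suite uses 64×64×96 voxel scenes with two
vessels (20 seeded scenes for the recovery and density-null properties);
the acceptance script uses 96×96×96 scenes with four vessels and 6 donors.
These sizes were chosen so full-cohort runs complete in minutes on one CPU
while every bin retains thousands of surface voxels.

**What the phantoms do not show.** No optical PSF, depth attenuation,
light-sheet striping, vessel branching, or morphologically realistic somata/
tangles; autofluorescence is stationary speckle rather than structured
tissue; enrichment is exactly exponential. Passing recovery tests therefore
demonstrates the correctness of the measurement pipeline under its own
model assumptions, not the biological findings themselves.

## Known limitations

* Centerlines are single unbranched paths; branching vessels must be traced
  as separate masks.
* The nearest-vertex arc-length rule quantizes s at the resampling step
  (≤1 µm), which smears segment-boundary assignment by about a voxel.
* Trilinear interpolation of the distance field underestimates distances in
  strongly concave corners of the shell; object distances on grid positions
  are exact.
* The RM-ANOVA drops incomplete decile levels; cohorts with very sparse
  donor × decile cells lose levels (and power) rather than being imputed.
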