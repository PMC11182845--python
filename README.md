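# perivasc

Vessel-relative 3D quantification of perivascular phospho-tau in
cleared-tissue imaging volumes.

In Alzheimer's disease, phosphorylated tau accumulates not only in
neurofibrillary tangles (NFTs) but also diffusely along the surface of some
cortical arterioles. Testing whether that vascular tau is spatially real —
enriched at the vessel surface rather than a coincidence of vessels passing
through tau-rich neuropil — and whether nearby neurons are more likely to
bear NFTs requires putting every voxel and every segmented object into
*vessel-relative* coordinates. `perivasc` implements that measurement
pipeline for anyone analyzing thick-section / cleared-tissue fluorescence
volumes with per-vessel masks: neuropathology and cerebrovascular labs, and
image-analysis methodologists who need a tested reference implementation.

## What it computes

Given a tau channel, per-vessel binary masks, an optional cortical-layer
label volume and object (neuron/NFT) tables:

* **Vessel geometry** — anisotropy-aware Euclidean distance-from-surface
  field d(v) (0 inside the mask), a skeleton-based centerline with arc-length
  parameterization s, and the vessel diameter (mean maximal cross-sectional
  chord at three sites).
* **Intensity normalization** — per-sample three-anchor piecewise-linear
  map: background, autofluorescence and tau-positive anchor means (3 depths
  × 10 measurements each) are sent to the canonical targets (0, 1, 2), with
  linear extrapolation beyond the end anchors.
* **Segment bins and deciles** — each vessel is tiled into 10 µm intervals
  along s; a bin's *surface tau* is the mean normalized intensity within
  3 µm of the surface; bins are ranked cohort-wide into deciles
  (decile 10 = most surface tau).
* **Radial profiles** — per donor and decile, the percent change of tau
  relative to the donor's whole-image mean as a function of distance from
  the surface (0% = indistinguishable from the image average).
* **Object densities** — neurons/NFTs within the 30 µm shell get s and
  d coordinates; per-bin voxel-counted shell volumes (mm³) give densities,
  and the percent of NFT-bearing neurons (NFT centroid within 5 µm of the
  soma) is tabulated per donor × decile.
* **Statistics** — a one-way within-subject (repeated-measures) ANOVA of
  NFT fraction across deciles with donor as the subject factor
  (F = MS_decile/MS_error, R² = SS_decile/(SS_decile+SS_error)),
  Shapiro–Wilk-gated two-group tests (t vs Mann–Whitney U), and
  control-normalized lane-intensity comparisons with one-tailed t tests.

A synthetic scene generator builds volumetric phantoms — tubular vessels,
three-regime tau fields with surface-anchored exponential enrichment,
Poisson neurons whose NFT probability rises with local surface tau — so the
whole pipeline is testable end to end without donor data.

## Worked example

```python
import numpy as np
from perivasc import (PipelineConfig, SceneSpec, scene_to_result,
                      analyze_cohort)
from perivasc.pipeline import simulate_cohort

config = PipelineConfig()                       # 3/10/30/100 um, deciles
scenes = simulate_cohort(SceneSpec(), n_donors=3, seed=7)
results = [scene_to_result(s, config, donor=f"donor_{i}")
           for i, s in enumerate(scenes)]
cohort = analyze_cohort(results, config)

d = np.concatenate([r.diameters_um for r in results])
print(f"vessels: {len(d)}, mean diameter {d.mean():.1f} um")
top = cohort.radial_summary.query("decile == 10 and distance_step < 3")
print("decile-10 tau vs distance (pct change):",
      np.round(top["pct_change_mean"].to_numpy(), 1))
print(cohort.anova.summary().splitlines()[2])
```

prints

```
vessels: 6, mean diameter 15.0 um
decile-10 tau vs distance (pct change): [574.6 527.  486.5]
  F(4, 8) = 4.0000   p = 0.04527   R2 (partial eta^2) = 0.667
```

The six simulated arterioles measure ~15 µm across. Vessel segments in the
top surface-tau decile carry ~5–6× more tau than the image average right at
the surface, decaying with distance — the enrichment the generator planted.
The repeated-measures ANOVA (3 donors × the decile levels with neurons in
every donor) detects the planted association between surface tau and the
fraction of nearby NFT-bearing neurons.

The same stages are available as a subcommand CLI over scene directories:

```bash
perivasc simulate --config cohort.json --out run/ --seed 5
perivasc geometry  --in run/
perivasc normalize --in run/
perivasc profile   --in run/
perivasc density   --in run/
perivasc stats     --in run/
perivasc report    --in run/ --out run/report.json
```

Every stage logs its parameters and writes a manifest (config, seed, input
hashes) next to its outputs.

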