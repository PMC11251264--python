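# Methods

## Scope and data model

`orgscreen` operates on three kinds of input: multi-channel 3D fluorescence
stacks (`(channel, z, y, x)`, 16-bit scale, default voxel size
0.415 × 0.415 μm in-plane and 0.9 μm axial), 32-bin spectral "lambda"
stacks for unmixing, and per-organoid record tables (one row per organoid
with line/day metadata, volume, and one mean-intensity column per probe).
Internal axis order is `(z, y, x)` everywhere; the acquisition convention
"0.415 × 0.415 × 0.9" is read as (x, y, z) μm.  Constants specified in
micrometres (blob scales, the 4 μm expansion, the 5000 μm³ volume filter)
are converted with the voxel spacing of the resolution they act at;
constants specified in voxels (smoothing sigmas 5 and 1, dilations 3 and 7,
the 100-voxel patch filter) are used as literal voxel counts.

## Organoid segmentation

The pipeline targets whole organoids, not nuclei or cells:

1. **Mean image** — voxel-wise arithmetic mean over channels, so every
   stained structure contributes to one detection volume.
2. **Clipping mask** — voxels with mean intensity strictly above 65000
   flag saturation; any final instance touching this mask is discarded,
   because clipped intensities corrupt mean-intensity readouts.
3. **Organoid masks** — Gaussian smoothing (sigma 5 voxels at full
   resolution, sigma 1 voxel after 5× in-plane block-mean down-sampling)
   followed by Otsu thresholding computed on the data at or below the 99th
   percentile.  The percentile clip stops rare saturated/debris voxels from
   stretching the histogram.  The low-resolution mask is further cleaned:
   26-connected components smaller than 100 voxels are removed (strict),
   holes are filled per z-slice, the mask is dilated by a 3-voxel ball, and
   holes are filled per slice again.  Slice-wise filling closes the lumen
   of cystic organoids even when it opens axially.
4. **Seeding** — the anisotropy-aware Euclidean distance transform (EDT,
   in μm) of the low-res mask is fed to multiscale Laplacian-of-Gaussian
   blob detection (10 scales, absolute threshold 1.0, overlap pruning at
   0.5).  The scale range comes from a per-line size group — small (5–9 μm),
   medium (7–11 μm), large (9–17 μm) — converted per axis to voxels, so
   detection scales are isotropic in physical space.  Size-group assignment
   is a required configuration input per line.
5. **Watershed** — seed centres are dilated by 7 voxels (nearest seed wins
   on overlap), labelled deterministically in (z, y, x) order, and the
   negated EDT is flooded within the mask.  Segmentation contains no
   randomness and is bit-reproducible.
6. **Post-processing** — instances smaller than 5000 μm³ (strictly; voxel
   count × voxel volume) are removed at low resolution; survivors are
   expanded by 4 μm (nearest-segment assignment), upsampled by nearest
   neighbour, intersected with the full-resolution organoid mask, purged of
   saturation overlaps, and relabelled consecutively.  Instances touching
   the stack border are kept by default (`exclude_border_instances`
   excludes them).
7. **Records** — per instance: volume in μm³ and the arithmetic mean of
   each channel over the instance voxels.

### Known bias: the mask halo

The organoid mask boundary sits where the smoothed edge crosses the Otsu
threshold.  Because the background class of the histogram is far tighter
than the signal class, Otsu settles near 25–30% of the interior intensity,
which places the boundary ~0.6 smoothing-sigma *outside* the true surface
(≈1.2 μm in-plane, ≈2.6 μm axially at full resolution).  On synthetic
hard-edged phantoms with dark background this halo makes instance masks
20–35% larger than the true organoid at radii 10–13 μm, so extracted mean
intensities are diluted by a similar fraction and the instance-level
intersection-over-union against ground truth plateaus around 0.6–0.8.  On
real data the halo largely covers the point-spread-function skirt of the
organoid signal, so the dilution is milder, and it is systematic — ratios
between lines and probes (percent positive, TBR, coverage) are essentially
unaffected, which is what the screen reads out.  A green end-to-end test
therefore establishes instance identity and relative quantification, not
absolute intensity recovery.

Degenerate inputs: a constant (flat) stack has no Otsu threshold; the
pipeline returns an empty label volume.  A pure-noise stack without any
real object can still produce spurious instances, since Otsu always splits
a unimodal histogram somewhere; the method assumes organoids are present.

## Spectral unmixing

Reference spectra are estimated from single-stain lambda stacks as the
mean spectrum of the brightest voxels (top 1% by across-bin total,
configurable), normalised to unit sum, so abundances carry intensity
units.  Mixed stacks are decomposed per voxel by non-negative least
squares against the fluorophore × 32 library; an unconstrained solve
handles voxels whose solution is already non-negative and NNLS re-solves
the rest.  A library condition number above 1e8 is treated as rank
deficient and reported with the most collinear fluorophore pair.  The
per-voxel RMS spectral residual is available as a diagnostic; no pass/fail
threshold is asserted for it.  The microscope vendor's online
fingerprinting is proprietary, so this module is a stated re-formulation
of the same linear mixing model rather than a re-implementation.

## Screening analytics

* **Positivity cutoffs** are annotator-derived in a real screen and should
  be supplied via `ScreenTable.cutoffs` for faithful re-analysis; absent
  that, a per-probe two-component valley (Otsu) estimate is used.  The
  cutoff is subtracted (floored at 0) and the flag is strict
  (`intensity > cutoff`).
* **Normalization** divides each (day, probe) group by its 95th percentile
  (linear-interpolation quantile), making the group's 95th percentile
  exactly 1.  The operation is idempotent and removes day-to-day
  acquisition drift.
* **TBR** is the mean intensity of a line's organoids over the pooled
  organoid-level mean of all healthy-control lines, computed per probe on
  day/probe-normalized intensities in `probe_summary` (a raw-intensity
  path exists, as does per-line-mean healthy pooling).  1.5 is used as the
  conventional clinical acceptability cut-off.
* **Coverage** flags an organoid for a probe when its *raw* intensity is
  at least (inclusive) one sample standard deviation above the pooled
  healthy mean; a combination covers an organoid when any member probe
  does.  All subsets of size ≥ 2 of a panel are enumerated in (size,
  panel-order) order — 57 for six probes.

## Heterogeneity profiling

Per-organoid day/probe-normalized intensities form an AnnData matrix with
deterministic row order (line, day, organoid id).  A 15-nearest-neighbour
Euclidean graph is built directly on the probe columns (no PCA — panels
have ≤ 7 probes), Leiden communities are detected at resolution 0.40
(breast cancer) or 0.45 (neuroblastoma), and labels are renumbered by
descending community size.  The neighbour count and metric are pinned in
code rather than inherited from library defaults so results stay
reproducible across library versions.  Note that modularity-style
community detection subdivides even homogeneous point clouds at moderate
resolution; "number of communities" is resolution-dependent and per-line
community *proportions* are the robust readout.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
optics: spheres or ellipsoids (optionally hollow, cyst-like shells) with
hard edges, constant per-channel interior intensity, flat background,
optional Poisson shot noise plus additive Gaussian noise, debris speckles
below the volume filter, and a fraction of voxels forced to 65535 —
clipping after noise is what creates realistic saturation.  No
point-spread function or spectral bleed-through beyond the linear mixing
model is simulated, which is why absolute mean-intensity recovery on
phantoms is pessimistic (see the halo note above).  Scenes are sampled by
rejection: overlapping organoids are never tolerated, because ground-truth
instance identity must stay unambiguous.  Default scene parameters:
background 100, interior intensities 5000–20000, organoid radii 10–13 μm
(inside the single-seed detection range of the medium size group while
keeping 15-organoid scenes packable in a 106 × 106 × 58 μm field), margin
3 μm between surfaces.  Screen tables draw lognormal intensities
parameterised so the expectation equals the specified line effect
(sigma = 0.3 by default), with optional mixture components for intra-line
heterogeneity and multiplicative day effects.  All generators are
deterministic for a fixed seed.

## Numerical conventions

* Quantiles: linear interpolation (NumPy default) everywhere.
* Otsu: 256-bin histogram; thresholds are bin centres, so comparisons are
  exact only up to one bin width.
* Connectivity: 26-neighbourhood for 3D components, full 2D connectivity
  for slice-wise hole filling; dilation structuring elements are voxel
  balls of the stated radius.
* Down-sampling: block mean (not decimation), preserving mean-intensity
  semantics; edge blocks average their partial window.
* Healthy-control standard deviation: sample (ddof = 1).
* Watershed ties: broken toward the lower label id; seed labels follow
  (z, y, x) order of seed centres.

## Limitations

* Absolute per-organoid mean intensities are biased low by the mask halo
  (systematic, ratio-preserving); see above.
* Very small organoids (below the size group's detection range) are missed
  by design; organoids below 5000 μm³ are removed by design.
* The annotator positivity cutoff cannot be reproduced computationally;
  the Otsu-valley estimator is a stand-in.
* Cluster counts from community detection are resolution- and
  density-dependent and should not be interpreted as an absolute number of
  biological states.
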