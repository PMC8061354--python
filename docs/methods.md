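# Methods

`pulmovox` re-implements, at desk scale, the quantitative chain used to
co-reconstruct whole-lung architecture and inhaled-particle deposition from
dual-channel serial-sectioning volumes (a structure channel with bright
airway/vessel walls and a fluorescence channel carrying micron-scale
particles), together with the cascade-impactor reduction used to
characterise the aerosol itself. Because real whole-lung datasets of this
kind run to terabytes and are not redistributable, every stage is validated
against a synthetic phantom whose ground truth is recorded in a ledger.

## The synthetic phantom

`phantom.generate_lung_phantom` emulates the statistical structure of the
data, not its anatomy:

- **Airway tree.** Monopodial by default (a dominant stem with lateral
  daughters — the murine pattern), with a bipodial human-like mode behind
  `tree_mode`. Branch radii and lengths decay geometrically
  (`radius_decay`, `length_decay`, defaults 0.6); daughters separate by the
  configured inter-daughter angle (default 47.7°). Walls are drawn as
  bright shells in grey range 110–255 around a dark lumen; parenchyma is
  band-limited texture in 20–100; two vessel tubes with bright walls are
  kept ≥ 2 voxels clear of the airway so seeded growing can distinguish
  them. Intensities are 8-bit throughout because all segmentation
  thresholds in this domain are quoted on that scale.
- **Regions.** The interior is partitioned into six z-slabs: the
  extrapulmonary trachea first, then the five lobes (left, accessory,
  right caudal, right middle, right cranial), with slab widths
  proportional to configurable relative volumes. The defaults derive lobe
  volumes as *fraction/density* from the published per-lobe deposition
  fractions (27.00 / 2.50 / 47.05 / 3.21 / 4.70 / 15.52 %) and densities
  (1.39 / 0.53 / 3.40 / 0.47 / 0.65). A slab partition sacrifices lobe
  shape realism for exactly controllable volumes, which the density
  recovery test needs; the stem crosses every slab so each region offers
  airway surface.
- **Particles.** Cubic particles (edge 1.221 µm) are rasterized as
  whole-voxel blocks; the block volume is the *particle quantum*, and every
  per-region request is honoured to within half a quantum. 18.6% of
  particle volume (configurable) is placed beyond `acinar_distance`
  (default 3 lumen radii) from the airway, the rest within one voxel of
  the airway surface; the trachea receives surface particles only, with
  the acinar budget redistributed over the lobes. 30% of components are
  compact clusters of 2–10 cubes (the field reports clustering but no
  distributional law; this mixture is declared, not fitted). Components
  never touch, so detection sees exactly one object per placed component.
- **Noise.** Additive Gaussian noise (default SD 12 grey levels) on both
  channels; particle intensity 230 gives SNR ≈ 19.
- **Tiles.** `generate_tiles` cuts overlapping mosaic tiles with integer
  stage jitter (tile 0 is the unjittered gauge anchor), a radial
  multiplicative vignette, and optional single-row gain-0.2 stripe
  defects, all recorded in the tile truth ledger.
- **Impactor runs.** `generate_impactor_run` integrates a log-normal
  aerodynamic mass distribution across the NGI cutoff ladder
  (7.73 / 4.20 / 2.68 / 1.63 / 0.90 / 0.52 / 0.32 µm at 65 L/min); the top
  stage takes everything above the first cutoff, the collector everything
  below the last; `gsd = 1` is the monodisperse limit.

What the phantom does **not** emulate: optical PSFs, chromatic
registration error, airflow-driven deposition physics, anatomical lobe
shapes, or the wall micro-texture of real bronchi. Tests passing on the
phantom therefore demonstrate that the *computational chain* is correct
and self-consistent, not that it would segment any particular real lung
without parameter adjustment.

## Preprocessing

Tiles are registered translation-only (rigid stage) by exhaustive
normalized cross-correlation within ±`search_radius` voxels of nominal
against already-placed neighbours, and blended with separable linear
feathering — overlaps of identical content reassemble exactly.
Featureless overlaps fall back to the nominal offset with a logged
warning. Illumination gain is estimated per slice by Gaussian smoothing
(default scale 50× the in-plane voxel size; sigma capped at the slice
extent), normalized to unit mean before division, so the global mean is
preserved. Line defects are rows/columns whose mean is both a robust
outlier (modified z-score > 3.5 against a size-5 median trend) and a
> 10% relative drop; they are rebuilt by linear interpolation between the
nearest clean lines. The relative-drop condition exists because pure
z-scores flag ordinary noise fluctuations on clean data. Contrast
enhancement is a percentile rescale (defaults 0.5/99.5, robust to hot
pixels); a constant volume maps to zero by declared convention.

## Segmentation

The airway recipe is invert → 3D bilateral filter (kernel 11³ default,
`sigma_spatial = kernel/4`, `sigma_range = 30` grey levels — chosen to
smooth parenchymal texture while preserving the wall edge at the
110-grey-level threshold) → seeded region growing through the wall grey
range. Both inversion and the bilateral filter commute with `v → 255−v`,
so growing `[110, 255]` on the raw volume is exactly equivalent to growing
`[0, 145]` on the inverted one; the pipeline uses the inverted order and
conjugated range, and the equivalence is property-tested. Region growing
is a vectorized wavefront flood fill whose output is, by construction, the
union of in-range connected components containing the seeds — identical
to threshold + connected-components restricted to seed components, which
the tests verify as an independent oracle. Default connectivity is 6:
with anisotropic voxels, 26-connectivity leaks through single-voxel
diagonal gaps in thin walls. Because growing recovers the bright *wall*,
`fill_airway_lumen` closes the tube (per-slice plus 3D hole filling)
before morphometry or distance classification.

## Morphometry

Masks are resampled to isotropic voxels (nearest-neighbour at the finest
axis) before 3D thinning to avoid anisotropy bias; coordinates are
reported in original physical µm. Three thinning pathologies found during
development shaped the design: axis-aligned tubes centred on a voxel
boundary are deleted outright; round tube caps retract completely; thick
junctions thin into blobs or small loops of short edges. Consequently the
phantom rasterizes flat-capped tubes snapped to voxel centres, and the
graph builder contracts junction–junction edges shorter than
`junction_merge` (default 10 µm) into single bifurcation nodes — branch
separations below this scale are reported as multifurcations, the method's
resolution limit. Leaf spurs shorter than `prune_length` (default 10 µm)
are pruned iteratively.

Inner radius is the physical Euclidean distance transform evaluated on
the centerline; generations follow strict Weibel numbering from the root
(every bifurcation increments) with an optional monopodial mode in which
the larger-radius daughter inherits the parent generation. Bifurcation
angles are measured on least-squares line fits to the first `fit_length`
(default 50 µm) of each branch leaving the junction — single-voxel
tangents are unusable under voxel quantization. Conventions (declared,
since the symbols are not formally defined in the source literature):
**alpha** is the angle between the two daughter directions, **beta** the
angle between a daughter and the parent direction, all vectors pointing
away from the junction, so a straight continuation has beta = 180°. On a
voxelized Y at 47.7° the measurement reads ≈ 48.8°: junction-adjacent
skeleton curvature biases the fit by ≈ +1°, within the ±2° acceptance
band, and the fit window is kept at 50 µm rather than tuned.

## Deposition quantification

Particles are 26-connected supra-threshold components (≥ `min_voxels`,
default 4 — at SNR ≥ 5 noise essentially never forms 4-voxel components)
of the fluorescence channel; a component larger than 1.5× the single
particle volume is flagged a cluster. Region assignment is by centroid
(particles are ~1 µm against millimetre-scale lobes); background
centroids are rescued to the nearest labelled voxel within 5 voxels, else
excluded and counted. Airway/acinar classification is by distance from
the centroid to the airway mask (airway if inside or within
`surface_distance`, default 10 µm); the acinar fraction is reported by
volume (primary) and by count. Densities are particle volume / lobe
volume × a configurable scale, five lobes only — the reporting units of
published densities are unstated, so recovery tests use the
self-consistent scale recorded in the phantom ledger. The right/left
ratio is (accessory + right caudal + right middle + right cranial) /
left, trachea excluded: this convention reproduces the published 2.13
from the published fractions exactly.

## Impactor reduction

Cumulative undersize at each cutoff is (mass on all finer stages +
collector) / total recovered mass. MMAD and GSD come from probit-vs-ln(d)
two-point bracketing interpolation (a full-regression mode is provided;
both coincide on exact log-normal data, where the probit plot is exactly
linear — hence the round trip recovers the generating parameters to
machine precision). GSD uses the 84.1st percentile, falling back to the
15.9th and then NaN when the ladder does not resolve the spread.
Extrapolation beyond the cutoff range is refused. FPF is the mass between
the cutoff diameters of the window stages (default 2–6: the respirable
band 0.52–4.20 µm at 65 L/min) over total recovered mass — on analytic
log-normal data this equals CDF(4.20) − CDF(0.52), consistent with the
published FPF arithmetic; the denominator can be switched to
impaction-stages-only.

## Problem sizes and numerical choices

Unit tests run on ~80³ isotropic phantoms (one lateral per lobe, reduced
particle load); acceptance-level recovery uses the full default
configuration, a 200³ anisotropic (1 × 0.35 × 0.35 µm) volume with ~1100
particle quanta, generated in ~10 s. The bilateral filter is O(kernel³ ×
voxels) and is exercised at kernel 5–11 on these sizes. Seeds: every
stochastic component takes an explicit seed; identical config + seed is
bit-identical end to end. Degenerate inputs have declared behaviour:
empty masks give empty meshes and zero volumes, constant volumes rescale
to zero, zero-variance overlaps fall back to nominal offsets, a zero left
lobe makes the right/left ratio an error rather than infinity.

## Known limitations

Slab regions cannot test lobe-shape-dependent effects; the acinar/airway
split is a geometric distance rule, not a histological one; stitching is
translation-only; the skeleton's `junction_merge` scale hides genuinely
close double bifurcations; cluster statistics use a declared, unfitted
mixture; and the bilateral filter is exact but not fast — production use
on instrument-scale volumes would need a tiled or GPU implementation.
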