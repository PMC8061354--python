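# pulmovox

Whole-lung volumetric image analysis at desk scale: co-reconstruction of
airway architecture and inhaled-particle deposition from dual-channel
serial-sectioning volumes, plus cascade-impactor aerosol metrics, with a
synthetic lung-phantom generator that makes every stage verifiable against
a ground-truth ledger.

## Who this is for

Researchers quantifying where inhaled micro-particles deposit in the lung
from high-resolution 3D imaging (micro-optical sectioning tomography and
similar modalities), and anyone needing a tested, scriptable version of
the standard processing chain those studies rely on:

1. **preprocess** — stitch overlapping mosaic tiles (translation-only NCC
   registration + linear feathering), correct luminance non-uniformity,
   remove line defects, enhance contrast;
2. **segment** — invert, 3D bilateral filter (default 11×11×11), seeded
   region growing through the airway-wall grey range 110–255, threshold
   segmentation, iso-surface meshing, mask volumes;
3. **morphometry** — centerline skeleton graph, inner-diameter profiles
   from the physical distance transform, Weibel-style generation indices
   (G0 = trachea), bifurcation angles from tangent fits;
4. **quantify** — fluorescent-particle detection (26-connected
   components), per-region deposition fractions, particle densities,
   right/left ratio, airway-surface vs acinar classification by distance
   to the airway, cluster-size statistics;
5. **aerosol** — cumulative undersize, MMAD, GSD and FPF from impactor
   stage-mass tables.

## The statistics at the core

For a particle set with per-region volumes $V_r$, the deposition fraction
is $f_r = 100\,V_r / \sum_s V_s$; the density is $\rho_r = (V_r / L_r)\,s$
with $L_r$ the lobe tissue volume and $s$ a reporting scale; the
right/left ratio is $(f_2+f_3+f_4+f_5)/f_1$ (trachea excluded). For an
impactor run with descending cutoffs $d_i$ and stage masses $m_i$, the
cumulative undersize $F(d_i)$ is plotted as probit$(F)$ vs $\ln d$:
$\mathrm{MMAD} = d_{50}$, $\mathrm{GSD} = d_{84.1}/d_{50}$, both by
two-point bracketing interpolation (exactly linear, hence exact, for a
log-normal aerosol), and FPF is the mass between the cutoff diameters of
the window stages (default 0.52–4.20 µm) over total recovered mass.

## Worked example

Generate the default study phantom (200³ voxels, 1 × 0.35 × 0.35 µm;
per-region particle allocations and lobe volumes set to published
deposition fractions and densities, 18.6% of particle volume placed
acinar) and quantify it:

```python
from pulmovox.phantom import PhantomConfig, generate_lung_phantom, generate_impactor_run
from pulmovox import quantify
from pulmovox.aerosol import compute_metrics

cfg = PhantomConfig(seed=1)
structure, fluor, truth = generate_lung_phantom(cfg)
particles = quantify.detect_particles(fluor, threshold=50, min_voxels=4,
                                      single_particle_volume=cfg.particle_quantum)
report = quantify.deposition_report(particles, truth.region_labels,
                                    airway_mask=truth.airway_mask,
                                    surface_distance=10.0,
                                    density_scale=truth.density_scale)
print(report.to_frame().round(3).to_string(index=False))
print(f"right/left ratio: {report.right_left_ratio:.2f}")
print(f"acinar fraction:  {report.acinar_fraction_pct:.1f}% (by volume)")

run = generate_impactor_run(mmad=2.912, gsd=1.624, noise_cv=0.0)
m = compute_metrics(run)
print(f"MMAD {m.mmad_um:.3f} um  GSD {m.gsd:.3f}  FPF {m.fpf_pct:.1f}%")
```

prints

```
 region            region_name  fraction_pct  density
      1              left lobe        27.019    1.379
      2         accessory lobe         2.481    0.532
      3      right caudal lobe        47.054    3.361
      4      right middle lobe         3.217    0.470
      5     right cranial lobe         4.687    0.655
      6 extrapulmonary trachea        15.542      NaN
right/left ratio: 2.13
acinar fraction:  18.7% (by volume)
MMAD 2.912 um  GSD 1.624  FPF 77.5%
```

Reading this: the detection + assignment chain recovers the phantom's
per-region allocations to a fraction of a percentage point (the right
caudal lobe carries nearly half the deposited volume); dividing by lobe
volume shows deposition is far from uniform (densities span ~7×); the
right lung receives 2.13× the left; and 18.7% of particle volume lies
beyond 10 µm of the airway surface — the acinar share. Density is
reported for the five lobes only, hence the trachea's NaN. The impactor
reduction recovers the generating MMAD/GSD exactly; the FPF printed here
is the analytic mass in the 0.52–4.20 µm band for that distribution.

The same stages are available as a CLI (`pulmovox phantom / tiles /
preprocess / segment / morphometry / quantify / aerosol / run`); `run`
executes the whole chain from a YAML config and writes every intermediate
plus a manifest that makes the report reproducible from parameters alone.

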