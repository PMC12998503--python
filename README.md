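# confinequant

Quantification toolkit for confined cell migration in embryonic tissue,
built around the measurements used to characterize primordial germ cells
(PGCs) migrating through the mouse embryo: cell and nuclear shape, cortical
actin distribution, extracellular-matrix and basement-membrane morphometry,
tissue stiffness from atomic force microscopy, intercellular space from
dextran-exclusion imaging, depth below the embryo surface from tracked 3-D
positions, and DNA-damage/nuclear-envelope scoring.

The package is aimed at researchers who have traced contours, annotated
ROIs, AFM force curves, or tracked positions in hand (from Fiji, Cellpose/
TrackMate, MaMuT, or similar tools) and want the downstream quantification
to be scripted, tested, and reproducible. Every analysis stage ships with a
seeded synthetic-scene generator that knows its own ground truth, so the
whole pipeline is testable without any imaging data.

## What it computes

| Module | Quantity |
| --- | --- |
| `morphometry` | area, perimeter, roundness `4A/(π·major²)`, aspect ratio (best-fit ellipse by exact polygon moments), protrusion length/width, perimeter variance over time, trailing displacement, event-aligned time courses |
| `intensity` | band means in contour-following bands (e.g. 20 px inside the membrane), front/body cortical enrichment over an annotated arc, thick-line profiles, region enrichment ratios, normalization to a reference population or ROI |
| `basement_membrane` | thickness as the FWHM of Savitzky–Golay-smoothed perpendicular profiles; discontinuity as the variance of smoothed, mean-subtracted along-membrane profiles |
| `afm_hertz` | elastic modulus E from the Hertz contact model `F = (4/3)·E/(1−μ²)·√R·δ^{3/2} + C` (spherical probe, default R = 3.31 μm, μ = 0.4), with contact-point detection and smoothing; fit over the first 250 nm of indentation |
| `confinement` | dextran-positive pixel fraction via white top-hat → Gaussian → adaptive local-mean threshold; intercellular-space widths from annotations or the mask skeleton |
| `geometry3d` | convex hull of somatic cell positions per timepoint; exact closest distance from each PGC to the triangulated surface, with a 100 μm display cutoff |
| `nuclear_integrity` | per-nucleus focus counts (γH2AX / RPA32 / 53BP1) by LoG blob detection or manual annotation; marker rules (>10, ≥1, ≥5); nuclear-envelope invaginations as concave contour arcs |
| `synthetic_data` | seeded generators for all of the above, each returning ground truth |

## Worked example

```python
import numpy as np
from confinequant import synthetic_data as syn, afm_hertz, confinement, geometry3d

# Hertz fit of a noisy synthetic force curve (E = 1200 Pa, with baseline)
curve, truth = syn.make_force_curve(E_pa=1200.0, C=5e-11, noise_sd=2e-11,
                                    precontact_nm=100, n_points=200, seed=7)
pre = afm_hertz.preprocess_force_curve(curve)   # smooth, find contact, re-zero
fit = afm_hertz.fit_hertz(pre)
print(f"E = {fit.E:.0f} Pa (truth 1200), C = {fit.C:.2e} N, n = {fit.n_fit}")

# intercellular-space fraction from a dextran scene with known truth
spec = syn.SceneSpec(seed=7, image_shape=(256, 256), pixel_size_um=0.5,
                     noise_sd=2.0, background_level=20.0)
img, t = syn.make_dextran_scene(spec, gap_width_um=2.0, target_fraction=0.30)
seg = confinement.segment_spaces(img, "dextran")
print(f"intercellular space: {100*seg.positive_fraction:.1f}% of pixels "
      f"(ground truth {100*t.scalar_truth['fraction']:.1f}%)")

# PGC depth below the embryo surface from a tracked point cloud
frames, t2 = syn.make_embryo_pointcloud(seed=7, n_somatic=300, n_pgc=3,
                                        pgc_depths_um=[10.0, 45.0, 90.0])
print(geometry3d.surface_distance_table(frames).to_string(index=False))
```

Output:

```
E = 1222 Pa (truth 1200), C = 4.81e-11 N, n = 142
intercellular space: 29.9% of pixels (ground truth 30.0%)
 time  pgc_id  distance_um  within_cutoff  outside_hull
    0       0     9.444352           True         False
    0       1    41.751401           True         False
    0       2    84.558592           True         False
```

The fitted modulus lands within 2% of the programmed stiffness at this
noise level; the dextran fraction matches the exact truth-mask fraction to
a tenth of a percent; and the measured depths sit within the hull's facet
discretization error (a few μm at 300 somatic cells) of the programmed
depths — depth 90 μm reads ~84.6 μm because the chordal hull surface lies
slightly inside the true spherical shell.

## Command line

A thin CLI wraps the library for shell use:

```
confinequant simulate dextran --seed 3 --out scene/       # scene + ground truth
confinequant spaces --image scene/dextran.tif --out spaces.csv
confinequant afm --curves curves_dir/ --out fits.csv
confinequant morpho --contours contours.csv --pixel-size 0.5 --out metrics.csv
confinequant depth --tracks tracks.csv --out depths.csv
confinequant foci --image img.tif --masks nuclei.tif --marker gammaH2AX --out counts.csv
confinequant invaginations --contours nuclei.csv --out inv.csv
```

Contours travel as tidy CSV (`object_id, frame, vertex, x, y`), tracks as
`time, id, class, x, y, z` in μm, force curves as two-column text with a
`# units: nm nN` header, images as TIFF with pixel size in metadata.

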