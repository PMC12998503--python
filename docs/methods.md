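# Methods

This note documents the models and conventions behind each analysis stage,
the tunable parameters and their defaults, what the synthetic fixtures
emulate, and the numerical choices made where the underlying protocol left
the design open.

## Conventions

All rasters use 0-based indices with x rightward, y downward, and pixel
centers at integer coordinates; physical quantities are derived through a
single `pixel_size_um`. Contours are simple polygons normalized to positive
shoelace orientation. Intensities are non-negative floats in memory and are
quantized to 16-bit only on TIFF export, so no analysis stage sees clipping
artifacts. Every variance reported by the package is the population
(divide-by-N) estimator; this is a fixed documented choice, not a claim
about the superiority of either estimator.

## Shape metrics

The best-fit ellipse of a contour is the moment-equivalent ellipse: exact
second central moments of the polygon interior are computed with
Green's-theorem closed forms (no rasterization), the eigendecomposition of
the 2×2 covariance gives axis directions and provisional axis lengths
(`4·sqrt(eigenvalue)` is exact for a true ellipse), and both axes are then
rescaled uniformly so the ellipse area equals the polygon area — the
convention of mainstream image-analysis tools. Roundness is
`4·Area/(π·major²)` (1 for a disc), not circularity `4πA/P²`; the two
disagree strongly for irregular outlines and the former is what the
ellipse-based workflow defines. Aspect ratio is major/minor.

Tracked-object dynamics: perimeter variance over time is the population
variance of the per-frame perimeter (μm²); "distance traveled over the past
5 min" is implemented as the net straight-line centroid displacement over
the trailing window, not the summed path length — the path-length reading
remains available by summing per-frame displacements, but net displacement
is the default because the quantity is used as a deformation-versus-motion
comparison at window scale. Event alignment places lag 0 at each object's
event frame and NaN-pads ragged ends; per-lag means and SDs use the values
available at that lag.

## Band and line intensities

Bands that follow a contour ("20 px inside the membrane", "10-px nuclear
lamina contour") are built from the Euclidean distance transform of the
rasterized polygon: every pixel whose distance to the opposite side is at
most the band thickness, on the requested side (inner/outer/centered).
Polygon erosion was rejected because it breaks topology on concave cell
outlines. The thickness is therefore measured perpendicular to the local
boundary. The "cell front" is an annotated arc (two vertex indices on the
contour); band pixels are assigned to the front or the body by their
nearest contour point, which partitions the band exactly — the front/body
enrichment of a noiseless synthetic cortex is recovered identically, with
no shared pixels at the arc ends. Line profiles sample every 1 px along the
path and average `thickness` bilinear samples along the local
perpendicular. Region enrichment divides the mean of one ROI by another of
exactly equal pixel count (enforced), non-overlapping.

## Basement-membrane morphometry

Thickness: perpendicular intensity profiles are Savitzky–Golay smoothed and
the full width at half maximum taken, with the half level placed midway
between the smoothed profile's minimum and its peak. The baseline is the
profile minimum rather than zero because profiles ride on tissue
background; this makes the FWHM exactly invariant to affine intensity
transforms. Crossings are located by linear interpolation; when several
peaks rise above the half level the outermost crossing pair is used and the
result flagged. Per-sample values average several profiles (five in the
reference workflow). Discontinuity: along-membrane profiles are smoothed,
mean-subtracted, and their population variance averaged over profiles; a
constant profile yields exactly zero (profiles are referenced to their
first sample before filtering, which the variance is blind to but floating
point is not).

Smoothing defaults are window 11, polynomial order 4, both configurable.
The order-4 choice is deliberate: a cubic at window 11 broadens a σ = 5 px
Gaussian's FWHM from 11.77 to 11.98 px, while the quartic keeps it at
11.79 px; since the FWHM *is* the thickness estimate, the peak-preserving
order is the right default. Sensitivity to the window is mild (window 7,
order 3 gives 11.81 px).

## AFM Hertz fitting

The Hertz model for a sphere of radius R on an elastic half-space,

    F(δ) = (4/3) · E/(1−μ²) · √R · δ^(3/2) + C,

is fitted with μ = 0.4 and R = 3.31 μm by default (spherical silica probe)
over indentation δ ∈ [0, 250 nm]. Because F is linear in (E, C) at fixed
μ and R, the fit is ordinary least squares of F on δ^(3/2) in a centered
closed form (the raw design matrix `[δ^{3/2}, 1]` spans ~10 orders of
magnitude in SI units and loses several significant digits in a naive
solver). E is constrained non-negative; at the boundary C refits as the
mean force.

Contact-point detection: the approach force is Savitzky–Golay smoothed
(window 11, order 3) and the first crossing of baseline mean + 3·SD
(baseline = first 25% of samples) gives an existence check. Localization by
threshold crossing alone is systematically late — the Hertz force leaves
the baseline with zero slope, so at realistic noise the crossing fires tens
of samples after contact. The contact sample is therefore located by
scanning candidate indices and fitting the piecewise model (flat baseline,
Hertz rise) to the raw approach segment, keeping the least-squares best;
this is exact on noiseless curves and lands within ±3 samples at an RMS
signal-to-noise ratio of 20. "First 250 nm" is interpreted as indentation
depth after contact re-zeroing (Hertz validity is expressed in
indentation); whether an instrument export is already contact-zeroed is
handled by fitting directly without preprocessing. Curves read from text
declare their units in a header (`# units: nm nN`); everything is stored in
SI internally, so unit mixes cannot silently scale E. Per-region summaries
are plain means over curves with n reported and no outlier rejection.

## Intercellular-space segmentation

The dextran channel is white-top-hat filtered (disc, radius 15 px) to
flatten structures wider than the spaces, Gaussian smoothed (σ = 1 px), and
adaptively thresholded: a pixel is space when it exceeds its local block
mean (block 51 px) by a margin of 15% of the filtered image's dynamic
range. Expressing the margin relative to the dynamic range makes the mask
exactly invariant to multiplying the image by a gain. The positive-pixel
fraction is an exact count over the analyzed region (optionally restricted
by a tissue mask).

The margin and σ were calibrated once on two-level truth scenes spanning
fractions 0.1–0.4 and channel widths 2–4 μm (the fraction-recovery checks
run on 384×384 px scenes, where the sampling scatter of the boundary
network is small relative to the recovery band): a small margin (5%) with σ=2
systematically over-segments thin channels by 0.04–0.09 because the blurred
edge crosses a low threshold well outside the true boundary; σ=1 with a 15%
margin keeps the worst-case error below 0.025 across fractions, widths and
seeds. All four parameters remain explicit configuration.

Width statistics support the manual protocol (per-cell annotated width
segments, at least three per cell, averaged) and an automated extension in
which widths are sampled as twice the distance transform along the mask
skeleton; the output labels which mode produced it.

## Embryo-surface distances

The embryo surface at each timepoint is the convex hull of all somatic
positions (recomputed independently per frame); each PGC's depth is the
exact minimum Euclidean distance to the triangulated surface, with face,
edge and vertex cases handled by plane projection plus barycentric tests
and edge clamping. Points outside the hull (possible with noisy tracking)
receive their positive distance and an `outside_hull` flag. A 100 μm
cutoff flag supports the display convention of showing only near-surface
cells. Distances are validated in the tests against an independent
brute-force per-facet oracle and against `trimesh`'s closest-point
routine to 1e-9.

Accuracy note: a hull of n points on a sphere of radius R under-estimates
depth by up to the facet sagitta (≈ 4 μm at n = 300, R = 100 μm) plus the
placement jitter; the synthetic depth-recovery tests compute this bound
per scene rather than assuming a fixed tolerance.

## Foci and envelope scoring

Classification rules are taken literally: γH2AX-positive means strictly
more than 10 foci; RPA32 presence means at least 1; 53BP1-positive means at
least 5. Classification is a pure function of the count table and accepts
manual counts (the reference workflow) as well as detector output. The
automated detector is Laplacian-of-Gaussian blob detection per labeled
nucleus around a spot scale of 1.5 px, with peaks merged below a 3 px
separation and peaks excluded unless they exceed twice the nucleus's median
intensity. These definitions of "one focus" are explicit stand-ins for a
human judgment and all parameters are configuration.

Envelope invaginations are maximal contiguous arcs of the nuclear contour
(resampled to 200 arc-length points, coordinates smoothed by a periodic
Gaussian of 2 samples) whose signed curvature is below −0.02 px⁻¹ for at
least 3 px of arc. A convex contour yields zero by construction; the count
is invariant to rigid motion and to moderate uniform up-scaling (curvature
scales as 1/s, so extreme magnification of a shallow notch can cross the
threshold — the threshold is in absolute image units on purpose, since
"indentation" is a resolution-relative judgment).

## Synthetic fixtures: what they do and do not show

Each generator draws from one `numpy` Generator seeded per scene, with
sub-draws in a documented order, so fixtures are byte-reproducible. Cells
are ellipses with cortical bands rendered by the same distance-transform
definition the measurement uses; membranes are Gaussian-cross-section
stripes with randomly placed zero gaps; intercellular space is the
boundary network of a Poisson–Voronoi tessellation, thresholded on exact
distance-to-edge so the truth mask fraction hits the target almost exactly
while the channel width stays near the requested value; force curves are
exact Hertz samples with optional flat pre-contact baseline; embryo clouds
are jittered spherical shells with PGCs placed on inward rays; nuclei are
circles with Gaussian foci and inward radial notches.

Noise is additive Gaussian clipped at zero — no shot noise, PSF, bleaching,
z-attenuation, or segmentation error is modeled, and real traced contours
are far noisier than rendered ellipses. Passing the recovery tests
therefore demonstrates that the *quantification* stages are correct and
stable under the stated noise, not that upstream tracing or tracking is
accurate. Default study conditions: 0.25–0.5 μm pixels, cell bodies
~8–15 μm, cortical bands 6 px, amplitudes ~100 intensity units over a
background of 20 with noise SD 2 — chosen once as typical confocal scales
for this tissue and held fixed.

## Known limitations

- The ellipse fit requires simple polygons; self-intersecting traces are
  rejected rather than repaired.
- FWHM thickness is undefined when the membrane peak touches the profile
  edge; the error names the offending profile instead of extrapolating.
- The adaptive threshold assumes spaces are bright on a locally darker
  background; inverted contrasts need the image inverted upstream.
- The Hertz fit assumes a parabolic-tip contact regime and returns E = 0
  (with C = mean force) rather than a negative modulus when a curve has no
  rise.
- Hull-based depth is a lower bound near the surface by the facet sagitta;
  dense somatic sampling tightens it.
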