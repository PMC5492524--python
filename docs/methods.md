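# Methods

## Flight geometry

The ground sample distance is the physical ground spacing of adjacent pixel
centers for a nadir camera: `GSD = Sw·H·100/(Fr·imW)` in cm/px.  It is
linear in flight height and invariant under joint rescaling of sensor width
and focal length.  Internal values are never rounded; the conventional
2-decimal figure is a presentation rule applied at report time only.
Flight heights are accepted anywhere above zero but emit a warning outside
40–80 m, the envelope over which detection quality was vetted for this
camera; the reference configuration is H = 60 m (GSD 2.60 cm/px, balancing
obstacle clearance and battery time).

The bundled calibration (pixel-unit focal lengths ≈ 2249.5/2249.8,
principal point ≈ (2015.9, 1508.8), skew −7.2265, radial (−0.0160,
−0.0336), tangential (0.0011, 5.6749·10⁻⁴)) feeds a **Brown-Conrady**
model with exactly two radial and two tangential terms.  The choice of
Brown-Conrady is an assumption: chessboard toolboxes report coefficients in
this parameterization, but the model form is fixed here by convention, not
measured.  Undistortion inverts the forward model by fixed-point iteration
in normalized coordinates and is accepted only when the reprojection
residual falls below 10⁻⁶ px; non-convergence raises with the achieved
residual.  Note the pixel-unit focal length and the physical 3.6 mm focal
length are independent fixtures: connecting them through the 1.5625 µm
pixel pitch gives ≈ 3.52 mm, so the two are deliberately *not* reconciled —
the GSD path uses the physical values, the distortion path the calibrated
ones.

## Color transform

RGB in [0, 1] (8-bit inputs scaled by 1/255, 16-bit by 1/65535) maps to
XYZ by the fixed matrix

    | 0.4125 0.3576 0.1804 |
    | 0.2125 0.7154 0.0721 |
    | 0.0193 0.1192 0.9502 |

and to L*a*b* by pure cube-root formulas against the reference white
defined as the matrix image of (1,1,1): (0.9505, 1.0000, 1.0887).  Two
design points deserve emphasis:

* **No gamma linearization by default.**  The matrix is applied to the
  stored [0,1] values directly.  Colorimetrically, sRGB-encoded imagery
  should be linearized first; that behaviour exists behind
  `linearize_srgb=True` but is off by default because the pipeline's
  clustering operates on whatever monotone color encoding it is given and
  the default keeps the transform an exact, reproducible formula of the
  stored pixel values.
* **Pure cube root, no CIE linear segment.**  Black maps to L* = −16
  rather than 0.  The standard piecewise CIE function is available via
  `cie_piecewise=True`; it differs only below (6/29)³ ≈ 0.0089 in the
  normalized channel, a regime vegetation/soil imagery rarely occupies.
* The implied white of the matrix (row sums) is used rather than the
  published D65 constants (0.95047, 1.0, 1.08883); the difference is in the
  5th decimal and using the matrix's own white makes RGB (1,1,1) map to
  exactly (100, 0, 0).

Gray inputs (r = g = b) have a* = b* = 0 by linearity, so chroma in this
space genuinely measures departure from neutrality — the property that lets
a Euclidean distance criterion discriminate glaucous crop from green weed.

## Segmentation

k-means is written from scratch (it is the analytical core, not a library
call): k-means++ seeding, Lloyd iterations, convergence when the largest
centroid displacement drops below 10⁻⁴ (L*a*b* units), max 300 iterations,
10 restarts keeping the lowest inertia, all driven by one integer seed.
Empty clusters are re-seeded from the point farthest from its centroid.
Assignment is a pointwise function of the centroids, so chunked prediction
is bit-identical to unchunked — parallel or blocked execution is an
execution detail, never a semantic one.  Ties in the nearest-centroid
assignment break toward the lowest cluster index.

Defaults: k = 3 (agave, weed, and a third cluster absorbing everything not
relevant), all three channels unweighted, model fitted on a seeded uniform
10% pixel sample and then applied to every pixel.  Cluster-to-class
mapping offers two strategies, since nothing in the clustering itself names
the clusters: `reference-colors` (nearest user-supplied L*a*b* reference
per centroid — the synthetic pipeline passes its palette through the same
color transform) and `manual` (explicit index → class).

## Georeferencing

Rasters are read and written as GeoTIFF through `tifffile`, with the
georeference in the standard tags (ModelPixelScale + ModelTiepoint for
north-up grids, ModelTransformation when rotation terms are present, a
GeoKeyDirectory carrying the EPSG code, GDAL_NODATA for the nodata value).
The CRS is treated as an opaque `EPSG:<code>` identifier; no reprojection
is performed — every product of one flight shares one UTM grid.
Annexation copies the source geotransform and CRS verbatim onto a derived
raster of the same shape and never touches pixel values.

Conventions fixed and tested: 0-based (col, row) indices, row-major
storage, map coordinates evaluated at the **pixel center** (col + 0.5,
row + 0.5).  Label rasters are single-band 8-bit with nodata 255.
Polygonization traces 4-connected components into unions of pixel
footprints, so polygon area equals pixel count × pixel area exactly; it is
restricted to axis-aligned grids.

## Evaluation protocol

Validation samples are square polygons drawn wholly inside single-class
regions of the reference raster (candidate centers found by binary erosion
with the polygon footprint), 15 over agave and 10 over weed by default,
sampled uniformly with a seed.  Inside the polygon union, with agave as the
positive class: precision = TP/(TP+FP); overall accuracy = fraction of
polygon pixels whose mapped semantic class equals the polygon's declared
class, so pixels falling in the "other" cluster count as errors.  A pixel
belongs to a polygon iff its center lies inside (matching the pixel-center
convention above).  Precision here is per-pixel; a per-polygon variant (one
verdict per sample) would be a coarser alternative and is intentionally not
implemented.  Reports print one row per study area with both scores to 5
decimals.

## Synthetic scenes

The generator emulates the structure a color-based classifier actually
exploits in agave fields: a soil background, compact glaucous rosettes of
roughly uniform size, and irregular brighter-green weed patches.  Defaults
define the reference study conditions: 2000×2000 px at 2.6 cm/px GSD
(the 60 m flight), 50 plants with radius ~ N(1.0 m, 0.15 m) placed by
non-overlapping rejection sampling, rosettes drawn as radially spiked discs
(9–15 leaves, boundary modulation ±18%), weed patches as the upper
quantile of a Gaussian-smoothed random field restricted to soil (exact
pixel-count coverage, 20% by default), a scene-wide multiplicative
illumination ramp of ±5% along a random direction, and i.i.d. Gaussian
channel noise σ = 0.02 clipped to [0, 1].  The palette — soil
(0.55, 0.44, 0.32), agave (0.35, 0.52, 0.50), weed (0.33, 0.58, 0.25) — is
synthetic, not measured; it separates the class means by ≳ 20 L*a*b* units,
standing in for the real spectral contrast between glaucous crop, green
weed and bare soil.  Everything is a deterministic function of the spec
(one seed, split into geometry and rendering streams), so fixtures are
byte-reproducible and regenerable from the JSON manifest.

What passing on these scenes shows — and does not.  The scenes have flat
relief, a single illumination ramp, no shadows, no mixed pixels beyond the
rasterized class borders, no plant-to-plant color variation, and no
ortho-mosaicking seams.  Near-perfect precision/accuracy here demonstrates
the pipeline's correctness (color transform, clustering, georeferencing and
scoring all compose without loss), not field-level performance; on real
mosaics the color separation, and hence the scores, are data-dependent.

## Problem sizes and numerical choices

The end-to-end check runs the full default 2000×2000 scene (4M pixels,
~400k fit points) in well under a minute on one core; unit tests use
300–400 px scenes.  The exhaustive k-means oracle enumerates all kⁿ
assignments for n ≤ 12 points, feasible only at toy size by design.
Degenerate inputs fail loudly: fewer distinct points than k, empty point
sets, rasters with fewer valid pixels than k, inverted altitude ranges,
non-positive camera parameters, shape or grid mismatches.
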