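# Methods

## Problem and model

A B-scan of the cornea shows a bright band (stromal backscatter) on a dark
background, bounded above by the anterior surface and below by the
posterior surface. Over the central ~2 mm that matter for central corneal
thickness, each surface is well approximated in image coordinates by a
parabola `row = a·col² + b·col + C` (rows increase downward, so a
convex-downward cornea has `a > 0`). The measurement reduces to estimating
the two parabolas and converting their vertical separation to micrometers.

### Axial scale

Fourier-domain OCT reconstructs each A-scan from the real part of the
interference spectrum, which yields the sample plus a mirror image about
the zero-delay line; only `N/2` of the `N` axial samples span the usable
imaging depth `h`. The depth per *sample* is therefore `2h/N` (4.066 µm for
`h` = 3.7 mm, `N` = 1820). Displayed images usually resample the usable
depth onto `rows` pixels, so the default pixel-to-sample ratio is
`(N/2)/rows` and the default scale is `h/rows` = 10.278 µm/row for 360-row
images. Both the ratio and the full system profile are configurable for
systems whose display mapping differs; `thickness.axial_scale` makes the
chain of units explicit. No refractive-index correction is applied (the
reported thickness is an optical path in tissue-free units); a group-index
division can be applied downstream if geometric thickness is needed.

### Central thickness

"Central" is defined as the vertex of the fitted anterior parabola — the
corneal apex — clamped into the measured column range if the fit places it
outside (reported via the `apex-clamped` quality flag). The per-column
profile, its mean, and the central value are all reported; columns where
the fitted surfaces cross are marked invalid and excluded from summaries
rather than silently clipped.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `w_init`, `w_max` | 3, 7 px | adaptive-median window range (odd) |
| `brightline_z` | 8.0 | column-mean outlier threshold in robust-SD (MAD) units |
| `binarize_method` | otsu | global threshold; `fixed` available |
| `min_island_area` | 5 px | remove smaller 8-connected islands after thresholding |
| `fit_method_{upper,lower}` | ransac | per-edge choice of `ransac` or `lsq` |
| `ransac_threshold` | 2 px | vertical inlier residual |
| `ransac_iterations` | 500 | minimal-sample hypotheses |
| `pixel_to_sample_ratio` | `(N/2)/rows` | axial samples per displayed row |
| `half_pixel_correction` | on | see below |

**Stage order.** Bright-line removal runs before the median filter: a 3-px
saturated stripe is largely destroyed by a 7-px median window, which would
blunt the column-outlier detector, while detection on the raw image is
near-certain (the stripe column mean sits hundreds of robust SDs above the
median). Removal interpolates flagged columns from their nearest clean
neighbours and is surfaced as the `line-removed` quality flag.

**Adaptive median.** The canonical two-stage rule is used. One convention
is worth stating: when `w_init == w_max` there is no window to grow into,
the adaptive impulse classification has no information to act on, and the
filter is defined to reduce to the plain median filter of that window. The
degenerate case is exercised in the tests against an independent
brute-force median.

**Binarization.** Otsu's global threshold is used because border following
assumes a clean two-class image; `skimage.filters.threshold_otsu` follows
the `img > t` convention, so the package derives its `>=`-style threshold
as the first value above the Otsu optimum. Islands smaller than 5 px are
removed so isolated surviving impulses cannot seed spurious boundaries.

**Border following.** A raster scan locates boundary starting points
(1-pixel with a 0 left neighbour → outer boundary; pixel ≥ 1 with a 0
right neighbour → hole boundary) and traces each boundary once, writing
±sequence-number markers into a working copy of the image. 1-components
are 8-connected and 0-components 4-connected — the pairing under which
every boundary is a closed curve and nesting is well defined. The image
frame acts as the root pseudo-hole (sequence number 1, represented
implicitly). The implementation is validated against a brute-force oracle:
on random images the traced outer/hole point sets must equal, exactly, the
sets of component pixels 4-adjacent to the surrounding background / to
each enclosed hole.

**Corneal contour and edge split.** The longest outer contour is taken as
the cornea (ties: smaller sequence number). Within its bounding rectangle
the per-column minimum contour row is an anterior-edge sample and the
maximum a posterior-edge sample; single-row columns contribute to the
anterior set only, so a degenerate band yields zero, not undefined,
thickness.

**Fitting.** RANSAC is applied to both edges by default (a per-edge switch
allows plain least squares). Defaults — 2 px threshold, 500 iterations,
minimal samples of 3 distinct-column points — follow common practice for
quadratic consensus fitting; consensus ties are broken by smaller inlier
RMS, then first found. Residuals are vertical: the edges are nearly
horizontal, so vertical distance closely tracks orthogonal distance at far
lower cost. The quadratic is the only curve family; a circular-arc model
was considered and dropped because the quadratic is the model the rest of
the chain (apex definition, ground truth) is built on.

**Half-pixel extent correction.** Contour rows are centers of the
outermost band pixels. A band whose true surfaces sit at rows `u` and `l`
binarizes to pixels `ceil(u)..floor(l)` (for a mid-coverage threshold), so
`rowmax − rowmin` underestimates `l − u` by one pixel in expectation.
The pipeline therefore shifts the fitted anterior surface up and the
posterior surface down by half a pixel each. The correction is exact for
the phantom's area-sampled edges and is the standard pixel-extent argument
for any binarized band; it can be disabled in the config.

## Phantom generator

The generator emulates the degradations the pipeline is designed for, on
top of a geometrically exact cornea:

* **Geometry.** Anterior apex near row 120 of 360 with curvature
  `a ≈ 0.001 row/col²` (≈32 px sag over the half-width); posterior surface
  20% more curved, so the periphery is thicker than the center, as in a
  real cornea. The default apex separation of 54.75 px equals 562.7 µm at
  the default scale — a physiologic CCT. Evaluation sweeps jitter apex
  position, curvature and thickness (48–62 px ≈ 490–640 µm).
* **Edges.** Anti-aliased over one pixel by area coverage (the
  weak-boundary regime); a hard-edge toggle produces exactly two gray
  levels for exact-recovery tests.
* **Speckle.** Multiplicative gamma noise, mean 1, variance
  `speckle_scale` (default 0.05). Gamma is the conventional compact model
  for multiplicative coherent-imaging noise; the generator makes no claim
  to full speckle statistics (no spatial correlation, no log-compression
  model).
* **Impulse noise.** Each pixel independently becomes 0 or 255 with
  probability `p` (default 0.05), equal split — the regime adaptive median
  filtering targets; the method is designed for `p` below about 0.2.
* **Bright line.** A saturated vertical stripe (default width 3 at the
  center column; odd widths centered, even widths left-anchored — fixed so
  pixel-counting tests are deterministic).

Ground truth is computed from the generating curves with the same
thickness formula and scale as the measurement path.

**What passing phantoms does not show.** The phantom has ideal band
contrast, spatially white noise, a perfectly parabolic cornea and no
neighbouring tissue (iris, lens, eyelid) or motion artifacts. Recovery
accuracy on phantoms therefore validates the algorithmic chain, not
clinical accuracy on patient scans.

## Numerical choices and degenerate inputs

* Determinism: all randomness (phantom noise, RANSAC sampling) flows from
  explicit integer seeds; report JSON is sorted-key and excludes wall-clock
  stage timings, so identical inputs give byte-identical reports.
* Filters use edge replication at borders (bit-stable, no reflection
  ambiguity at even offsets).
* A constant image cannot be Otsu-thresholded and contains no cornea; the
  pipeline raises a stage-attributed "no cornea found" error. Failures are
  always hard errors with stage identity — a thickness from a failed
  segmentation would be worse than no output.
* Robust SD for bright-line detection is `1.4826·MAD`, floored at 1e-9 so
  a constant background (MAD = 0) still flags a genuine stripe.
* Evaluation problem sizes: the standard validation sweep uses 20 phantoms
  per noise level at impulse p ∈ {0, 0.05, 0.1} on full 360×360 images,
  and the boundary-tracing oracle runs on 200 random images up to 32×32 —
  sizes at which the brute-force oracles are still exact and cheap.

## Known limitations

* Only the displayed-image path is exercised end to end; sample-native
  (1820-row) data is supported via `pixel_to_sample_ratio` but has no
  phantom preset.
* The bright-line remover assumes a roughly vertical stripe; oblique or
  curved saturation artifacts would need a different detector.
* Quadratic surfaces are a central-region approximation; peripheral
  pachymetry over a wide scan would need a higher-order or arc model.
* Pure-Python boundary tracing is O(image) with small constants (~0.2 s on
  a 360×360 scan); very large mosaics would warrant a compiled inner loop.
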