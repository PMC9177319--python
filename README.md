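# cornoct

Automatic measurement of **central corneal thickness (CCT)** from
anterior-segment optical coherence tomography (AS-OCT) B-scans.

AS-OCT can image the cornea in cross-section with micrometer axial
resolution, but in routine acquisitions the corneal band is degraded by
speckle, impulse noise from the detection electronics, and a saturated
vertical bright line at the scan center caused by specular reflection at
zero path delay. These degradations produce weak, broken boundaries that
defeat naive edge detection. `cornoct` implements a robust measurement
chain for this setting, aimed at researchers and engineers who need
unattended pachymetry from B-scan images:

1. **Bright-line removal** — columns whose mean intensity is a robust
   outlier (median/MAD test) are replaced by lateral interpolation.
2. **Adaptive median filtering** — the two-stage adaptive median: per pixel
   the window grows from `w_init` until the window median is no longer an
   impulse (strictly between window min and max) or `w_max` is reached;
   only impulse-classified centers are replaced, preserving thin edges.
3. **Binarization** — global Otsu threshold plus small-island removal.
4. **Border following** — raster-scan boundary tracing with marker
   bookkeeping extracts every outer and hole boundary of the binary image,
   with their nesting hierarchy; the longest outer contour is the cornea.
5. **Edge split and robust fitting** — within the contour's minimum
   bounding rectangle, the per-column topmost/bottommost contour points form
   the anterior and posterior edge sets, each fitted with a quadratic
   `y = a x² + b x + C` by RANSAC (least squares on the consensus set).
6. **Thickness** — for surfaces `y₁` (anterior) and `y₂` (posterior) the
   thickness at a column is

   `D = (y₂ − y₁) · (2h/N) · ρ`

   where `h` is the imaging depth, `N` the number of samples per A-scan
   (only `N/2` cover `h`; the other half is the Fourier mirror image), and
   `ρ` the samples-per-displayed-row ratio. With the default profile
   (`h` = 3.7 mm, `N` = 1820, 360-row images) the axial scale is
   `h/360 ≈ 10.278 µm` per row. CCT is reported at the anterior apex.

Because clinical B-scans are rarely redistributable, the package ships a
**phantom generator**: synthetic B-scans with a corneal band bounded by two
known parabolic surfaces, anti-aliased edges, multiplicative gamma speckle,
salt-and-pepper impulse noise and the bright-line artifact — together with
exact ground truth, so the whole chain is validated end to end.

## Worked example

```sh
$ cornoct phantom --out demo --n 1 --seed 7 --impulse-p 0.1 --speckle 0.05 --bright-line 180
wrote 1 phantom(s) to demo
$ cornoct measure demo/phantom_000.png --out demo/out
central thickness: 605.4 um  (mean 621.7 um, flags: line-removed)
report written to demo/out
```

The phantom's ground truth (`demo/phantom_000_truth.json`) records a true
CCT of 604.9 µm; the pipeline measures 605.4 µm — an error of 0.5 µm, about
0.05 axial pixels — while flagging that a bright-line artifact was detected
and removed. `demo/out/` contains the report JSON, a per-column thickness
CSV and an overlay PNG with the fitted surfaces drawn on the input.

The same run is available from Python:

```python
from cornoct import NoiseModel, generate_phantom, measure_cornea

img, truth = generate_phantom(noise=NoiseModel(impulse_probability=0.1,
                                               speckle_scale=0.05,
                                               bright_line_column=180))
report = measure_cornea(img)
print(report.thickness.central_thickness_um, truth.central_thickness_true_um)
```

`cornoct eval --n 20 --seed 1` scores the pipeline over a grid of noise
levels and prints per-level mean thickness, mean absolute error and the
relative-error histogram in integer axial-pixel bins.

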