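"""Denoising and binarization of a B-scan.

Three steps prepare an image for boundary tracking:

1. ``remove_central_bright_line`` — the saturated vertical stripe caused by
   specular reflection at zero path delay is detected as a robust outlier in
   the per-column mean intensity and replaced by lateral interpolation.
2. ``adaptive_median_filter`` — the two-stage adaptive median: per pixel the
   window grows from ``w_init`` until the window median is not an impulse
   (strictly between the window minimum and maximum) or ``w_max`` is
   reached; a center pixel that is itself not an impulse within that window
   is kept, otherwise it is replaced by the window median.  A plain median
   filter blurs edges and fails once the impulse probability approaches
   0.2; the adaptive variant removes denser impulse noise while preserving
   the thin corneal boundaries.
3. ``binarize`` — global (Otsu) or fixed thresholding into a {0,1} image,
   optionally followed by removal of small isolated islands that would
   otherwise seed spurious boundaries during tracking.

Window borders are handled by edge replication so results are bit-stable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import CornoctError
from .image import BinaryImage, BScanImage


def adaptive_median_filter(image: BScanImage, w_init: int = 3, w_max: int = 7) -> BScanImage:
    """Two-stage adaptive median filter for impulse noise.

    ``w_init`` and ``w_max`` are odd window sizes with
    ``1 <= w_init <= w_max``.  When ``w_init == w_max`` there is no window
    to grow into and the adaptive classification is inert: the filter
    reduces to the plain median filter of that window.
    """
    for w in (w_init, w_max):
        if w < 1 or w % 2 == 0:
            raise CornoctError(f"window sizes must be positive odd integers, got {w}")
    if w_init > w_max:
        raise CornoctError("w_init must not exceed w_max")

    pix = image.pixels
    if w_init == w_max:
        return image.copy_with(ndimage.median_filter(pix, size=w_max, mode="nearest"))

    center = pix
    result = np.empty_like(pix)
    decided = np.zeros(pix.shape, dtype=bool)
    for size in range(w_init, w_max + 1, 2):
        med = ndimage.median_filter(pix, size=size, mode="nearest")
        mn = ndimage.minimum_filter(pix, size=size, mode="nearest")
        mx = ndimage.maximum_filter(pix, size=size, mode="nearest")
        median_ok = (med > mn) & (med < mx)
        sel = ~decided & (median_ok | (size == w_max))
        keep_center = (center > mn) & (center < mx)
        result[sel] = np.where(keep_center[sel], center[sel], med[sel])
        decided |= sel
    return image.copy_with(result)


def detect_bright_line_columns(image: BScanImage, detection_z: float = 8.0) -> np.ndarray:
    """Columns whose mean intensity is a robust outlier (z in MAD units)."""
    if image.cols < 3:
        raise CornoctError("bright-line detection needs at least 3 columns")
    col_means = image.pixels.mean(axis=0)
    med = np.median(col_means)
    mad = np.median(np.abs(col_means - med))
    robust_sd = max(1.4826 * mad, 1e-9)
    z = (col_means - med) / robust_sd
    return np.nonzero(z > detection_z)[0]


def remove_central_bright_line(image: BScanImage, detection_z: float = 8.0) -> BScanImage:
    """Replace bright-line columns by the mean of the nearest clean neighbours.

    Returns the input unchanged (as a copy) when no column is flagged;
    raises if every column is flagged (the image is unusable).
    """
    flagged = detect_bright_line_columns(image, detection_z)
    if flagged.size == 0:
        return image.copy_with(image.pixels.copy())
    if flagged.size == image.cols:
        raise CornoctError("every column flagged as bright line: image unusable")

    bad = np.zeros(image.cols, dtype=bool)
    bad[flagged] = True
    good_idx = np.nonzero(~bad)[0]
    out = image.pixels.astype(np.float64)
    for c in flagged:
        left = good_idx[good_idx < c]
        right = good_idx[good_idx > c]
        if left.size and right.size:
            repl = (out[:, left[-1]] + out[:, right[0]]) / 2.0
        elif left.size:
            repl = out[:, left[-1]]
        else:
            repl = out[:, right[0]]
        out[:, c] = repl
    return image.copy_with(np.clip(np.rint(out), 0, 255).astype(np.uint8))


def binarize(
    image: BScanImage,
    method: str = "otsu",
    fixed_threshold: int | None = None,
    min_island_area: int = 0,
) -> BinaryImage:
    """Threshold a B-scan into a {0,1} image (pixel -> 1 iff gray >= threshold).

    ``method`` is "otsu" (global Otsu threshold; errors on a constant image,
    which has no separable classes) or "fixed" (requires
    ``fixed_threshold``).  ``min_island_area`` > 0 removes 8-connected
    foreground islands smaller than that many pixels.
    """
    pix = image.pixels
    if method == "otsu":
        if pix.min() == pix.max():
            raise CornoctError("cannot Otsu-threshold a constant image: no separable classes")
        # threshold_otsu follows the `img > t` convention; shift to the first
        # value above the optimum so the `>=` rule selects the upper class
        t = np.nextafter(float(threshold_otsu(pix)), np.inf)
    elif method == "fixed":
        if fixed_threshold is None:
            raise CornoctError("method='fixed' requires fixed_threshold")
        t = fixed_threshold
    else:
        raise CornoctError(f"unknown binarization method: {method!r}")
    mask = pix >= t
    if min_island_area > 0:
        # remove islands of area < min_island_area (max_size is inclusive)
        mask = remove_small_objects(mask, max_size=min_island_area - 1, connectivity=2)
    return BinaryImage.from_mask(mask)
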