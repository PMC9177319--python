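"""Synthetic anterior-segment OCT B-scan phantoms with known ground truth.

A phantom emulates what the measurement pipeline sees in practice: a bright
corneal band bounded by two smooth convex-downward parabolic surfaces on a
dark background, degraded by multiplicative speckle (the interference noise
intrinsic to coherent imaging), salt-and-pepper impulse noise (detector and
circuit transients), a saturated vertical bright line near the scan center
(specular reflection at zero path delay), and optional horizontal streaks.
The exact surface geometry and the thickness it implies — computed with the
same axial-scale formula the measurement path uses — are returned alongside
the image, so end-to-end recovery can be scored without any external data.

Speckle is modelled as gamma-distributed multiplicative noise with mean 1
and variance ``speckle_scale``; impulse noise replaces each pixel
independently with probability ``p`` by the minimum or maximum gray value
(equal split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import json

import numpy as np

from .errors import CornoctError
from .fitting import QuadraticCurve, evaluate_curve
from .image import BScanImage, GRAY_MAX, GRAY_MIN
from .profile import SystemProfile
from .thickness import ThicknessProfile, axial_scale, thickness_profile


@dataclass
class CornealGeometry:
    """True corneal surfaces and band rendering intensities.

    Curves map column -> row (row = a*col^2 + b*col + C); the lower
    (posterior) surface must lie strictly below the upper (anterior) one at
    every column so the band has positive thickness.
    """

    upper_curve: QuadraticCurve
    lower_curve: QuadraticCurve
    band_intensity: int = 180
    background_intensity: int = 30

    def validate_within(self, profile: SystemProfile) -> None:
        cols = np.arange(profile.cols)
        up = np.asarray(evaluate_curve(self.upper_curve, cols))
        lo = np.asarray(evaluate_curve(self.lower_curve, cols))
        if not np.all(lo > up):
            raise CornoctError("lower surface must lie strictly below the upper surface")
        if up.min() < 0 or lo.max() > profile.rows - 1:
            raise CornoctError("corneal surfaces fall outside the image row range")


@dataclass
class NoiseModel:
    """Degradations applied to the clean render, in order: speckle, impulse, artifacts."""

    impulse_probability: float = 0.05
    speckle_scale: float = 0.05
    bright_line_column: Optional[int] = None
    bright_line_width: int = 3
    bright_line_intensity: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.impulse_probability <= 1.0:
            raise CornoctError("impulse_probability must be in [0, 1]")
        if self.bright_line_width < 0:
            raise CornoctError("bright_line_width must be >= 0")
        if self.speckle_scale < 0:
            raise CornoctError("speckle_scale must be >= 0")


@dataclass
class PhantomGroundTruth:
    """Exact geometry and the thickness it implies, on the measurement scale."""

    geometry: CornealGeometry
    thickness_profile_true: ThicknessProfile
    central_thickness_true_um: float

    def to_dict(self) -> dict:
        tp = self.thickness_profile_true
        return {
            "upper_curve": self.geometry.upper_curve.to_dict(),
            "lower_curve": self.geometry.lower_curve.to_dict(),
            "central_thickness_true_um": self.central_thickness_true_um,
            "axial_scale_um_per_pixel": tp.axial_scale_um_per_pixel,
            "thickness_um": [float(t) for t in tp.thickness_um],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def make_geometry(
    profile: SystemProfile,
    apex_row: float = 120.0,
    central_thickness_px: float = 54.75,
    a_upper: float = 0.001,
    a_lower: float = 0.0012,
    apex_col: float | None = None,
    band_intensity: int = 180,
    background_intensity: int = 30,
) -> CornealGeometry:
    """Build a physiologic default geometry for a given image size.

    The anterior apex sits near mid-width at ``apex_row``; the posterior
    surface is slightly more curved, so the periphery is thicker than the
    center (as in a real cornea).  At the default axial scale the default
    54.75 px central separation corresponds to ~562.7 um.
    """
    if apex_col is None:
        apex_col = profile.cols / 2.0
    upper = QuadraticCurve(a=a_upper, b=-2.0 * a_upper * apex_col, C=apex_row + a_upper * apex_col**2)
    lo_apex = apex_row + central_thickness_px
    lower = QuadraticCurve(a=a_lower, b=-2.0 * a_lower * apex_col, C=lo_apex + a_lower * apex_col**2)
    geom = CornealGeometry(
        upper_curve=upper,
        lower_curve=lower,
        band_intensity=band_intensity,
        background_intensity=background_intensity,
    )
    geom.validate_within(profile)
    return geom


def render_clean(
    profile: SystemProfile, geometry: CornealGeometry, soft_edges: bool = True
) -> np.ndarray:
    """Render the noise-free band as float64 gray values.

    With ``soft_edges`` the band boundary is anti-aliased over one pixel
    (fractional surface coverage), exercising the weak-boundary regime;
    without it the image has exactly two gray levels.
    """
    geometry.validate_within(profile)
    cols = np.arange(profile.cols)
    rows = np.arange(profile.rows)[:, None]
    up = np.asarray(evaluate_curve(geometry.upper_curve, cols))[None, :]
    lo = np.asarray(evaluate_curve(geometry.lower_curve, cols))[None, :]
    if soft_edges:
        cov = np.clip(rows - up + 0.5, 0.0, 1.0) * np.clip(lo - rows + 0.5, 0.0, 1.0)
    else:
        cov = ((rows >= up) & (rows <= lo)).astype(np.float64)
    bg, band = float(geometry.background_intensity), float(geometry.band_intensity)
    return bg + (band - bg) * cov


def band_mask(profile: SystemProfile, geometry: CornealGeometry) -> np.ndarray:
    """Boolean mask of pixels whose centers lie between the two surfaces."""
    cols = np.arange(profile.cols)
    rows = np.arange(profile.rows)[:, None]
    up = np.asarray(evaluate_curve(geometry.upper_curve, cols))[None, :]
    lo = np.asarray(evaluate_curve(geometry.lower_curve, cols))[None, :]
    return (rows >= up) & (rows <= lo)


def _apply_impulse(pixels: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = pixels.copy()
    if p == 0.0:
        return out
    u = rng.random(pixels.shape)
    hit = u < p
    # equal split between pepper and salt, decided by a second draw
    salt = rng.random(pixels.shape) < 0.5
    out[hit & salt] = GRAY_MAX
    out[hit & ~salt] = GRAY_MIN
    return out


def add_impulse_noise(image: BScanImage, p: float, seed: int = 0) -> BScanImage:
    """Salt-and-pepper corruption: each pixel independently becomes 0 or 255
    with probability ``p`` (equal split); other pixels are unchanged."""
    if not 0.0 <= p <= 1.0:
        raise CornoctError("impulse probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return image.copy_with(_apply_impulse(image.pixels, p, rng))


def _stripe_columns(column: int, width: int, n_cols: int) -> np.ndarray:
    """Columns covered by a bright line: odd widths centered on ``column``,
    even widths left-anchored at it; clipped to the image."""
    if width == 0:
        return np.array([], dtype=int)
    if width % 2 == 1:
        start = column - (width - 1) // 2
    else:
        start = column
    cols = np.arange(start, start + width)
    return cols[(cols >= 0) & (cols < n_cols)]


def add_central_bright_line(
    image: BScanImage, column: int, width: int = 3, intensity: int = 255
) -> BScanImage:
    """Saturated vertical stripe emulating the zero-delay specular reflection."""
    if not 0 <= column < image.cols:
        raise CornoctError(f"bright-line column {column} outside [0, {image.cols})")
    out = image.pixels.copy()
    cols = _stripe_columns(column, width, image.cols)
    if cols.size:
        out[:, cols] = np.uint8(intensity)
    return image.copy_with(out)


def generate_phantom(
    profile: SystemProfile | None = None,
    geometry: CornealGeometry | None = None,
    noise: NoiseModel | None = None,
    soft_edges: bool = True,
) -> tuple[BScanImage, PhantomGroundTruth]:
    """Produce one degraded B-scan and its exact ground truth.

    Degradations are applied in order: multiplicative speckle, impulse
    noise, then the bright-line artifact.  Identical inputs and seed yield a
    byte-identical image.
    """
    profile = profile or SystemProfile()
    geometry = geometry or make_geometry(profile)
    noise = noise or NoiseModel()

    clean = render_clean(profile, geometry, soft_edges=soft_edges)
    rng = np.random.default_rng(noise.seed)

    pix = clean
    if noise.speckle_scale > 0:
        shape = 1.0 / noise.speckle_scale
        pix = pix * rng.gamma(shape=shape, scale=1.0 / shape, size=pix.shape)
    pix = np.clip(np.rint(pix), GRAY_MIN, GRAY_MAX).astype(np.uint8)
    pix = _apply_impulse(pix, noise.impulse_probability, rng)
    img = BScanImage(pixels=pix, profile=profile)
    if noise.bright_line_column is not None and noise.bright_line_width > 0:
        img = add_central_bright_line(
            img, noise.bright_line_column, noise.bright_line_width, noise.bright_line_intensity
        )

    scale = axial_scale(profile)
    tp = thickness_profile(
        geometry.upper_curve, geometry.lower_curve, np.arange(profile.cols), scale
    )
    truth = PhantomGroundTruth(
        geometry=geometry,
        thickness_profile_true=tp,
        central_thickness_true_um=tp.central_thickness_um,
    )
    return img, truth


def random_geometry(profile: SystemProfile, rng: np.random.Generator) -> CornealGeometry:
    """Jittered physiologic geometry for evaluation sweeps."""
    a_up = rng.uniform(0.0008, 0.0012)
    return make_geometry(
        profile,
        apex_row=rng.uniform(100.0, 140.0) * profile.rows / 360.0,
        central_thickness_px=rng.uniform(48.0, 62.0) * profile.rows / 360.0,
        a_upper=a_up,
        a_lower=a_up * rng.uniform(1.1, 1.3),
        apex_col=profile.cols / 2.0 + rng.uniform(-15.0, 15.0) * profile.cols / 360.0,
    )
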