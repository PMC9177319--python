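"""Corneal thickness from fitted surfaces.

The physical thickness at a column is the row separation of the posterior
and anterior surfaces times the axial scale.  Because a Fourier-domain OCT
A-scan devotes only half of its ``N`` samples to the usable imaging depth
``h`` (the other half is the zero-delay mirror image), the scale per axial
*sample* is ``2h/N``; a displayed image whose rows resample that depth uses
``(2h/N) * pixel_to_sample_ratio`` micrometers per row.

Central corneal thickness (CCT) is reported at the apex of the fitted
anterior surface — the vertex of its parabola — clamped into the measured
column range when the fit places the vertex outside the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CornoctError
from .fitting import QuadraticCurve, evaluate_curve
from .profile import SystemProfile


@dataclass
class ThicknessProfile:
    """Per-column corneal thickness in micrometers with summary statistics.

    ``thickness_um`` holds NaN at columns where the fitted surfaces cross
    (``valid`` False there); summaries are computed over valid columns only.
    """

    columns: np.ndarray
    thickness_um: np.ndarray
    central_thickness_um: float
    mean_thickness_um: float
    axial_scale_um_per_pixel: float
    central_column: int = 0
    apex_clamped: bool = False
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns)
        self.thickness_um = np.asarray(self.thickness_um, dtype=np.float64)
        if self.valid is None:
            self.valid = np.isfinite(self.thickness_um)
        self.valid = np.asarray(self.valid, dtype=bool)


def axial_scale(profile: SystemProfile, pixel_to_sample_ratio: float | None = None) -> float:
    """Micrometers of depth per image row.

    ``pixel_to_sample_ratio`` is the number of axial samples represented by
    one image row; 1 means rows are raw samples (scale ``2h/N``).  The
    default, ``(N/2)/rows``, maps the full usable depth onto the image
    (scale ``h/rows``).
    """
    if pixel_to_sample_ratio is None:
        pixel_to_sample_ratio = profile.default_pixel_to_sample_ratio
    if pixel_to_sample_ratio <= 0:
        raise CornoctError("pixel_to_sample_ratio must be > 0")
    return profile.sample_pitch_um * pixel_to_sample_ratio


def thickness_at(
    upper: QuadraticCurve, lower: QuadraticCurve, col: float, scale_um_per_pixel: float
) -> float:
    """Thickness at one column: (lower(col) - upper(col)) * scale, in um."""
    diff = evaluate_curve(lower, col) - evaluate_curve(upper, col)
    if diff < 0:
        raise CornoctError(f"surfaces cross at column {col}: negative thickness")
    return float(diff * scale_um_per_pixel)


def thickness_profile(
    upper: QuadraticCurve,
    lower: QuadraticCurve,
    cols: np.ndarray,
    scale_um_per_pixel: float,
) -> ThicknessProfile:
    """Per-column thickness profile with central and mean summaries.

    The central value is taken at the anterior-surface apex column, clamped
    into the column range (``apex_clamped`` flags clamping); columns where
    the surfaces cross are marked invalid and excluded from summaries.
    """
    cols = np.asarray(cols)
    if cols.size == 0:
        raise CornoctError("thickness profile needs a non-empty column range")
    diff = np.asarray(evaluate_curve(lower, cols)) - np.asarray(evaluate_curve(upper, cols))
    valid = diff >= 0
    if not valid.any():
        raise CornoctError("surfaces cross everywhere: no valid thickness column")
    thick = np.where(valid, diff * scale_um_per_pixel, np.nan)

    apex = upper.apex_col
    if apex is None:
        apex = float(cols[0] + cols[-1]) / 2.0
    clamped = apex < cols.min() or apex > cols.max()
    apex = min(max(apex, float(cols.min())), float(cols.max()))
    # nearest valid column to the apex
    valid_cols = cols[valid]
    central_col = int(valid_cols[np.argmin(np.abs(valid_cols - apex))])
    central = float(thick[np.nonzero(cols == central_col)[0][0]])
    return ThicknessProfile(
        columns=cols,
        thickness_um=thick,
        central_thickness_um=central,
        mean_thickness_um=float(np.nanmean(thick)),
        axial_scale_um_per_pixel=float(scale_um_per_pixel),
        central_column=central_col,
        apex_clamped=bool(clamped),
        valid=valid,
    )


def relative_error(
    measured: ThicknessProfile, truth: ThicknessProfile, unit: str = "pixel"
) -> float | int:
    """Central-thickness measurement error against ground truth.

    ``pixel`` mode: signed error in axial pixels rounded to the nearest
    integer (the integer bins an error histogram is reported in); ``percent``
    mode: signed percentage of the true value.
    """
    if measured.columns.shape != truth.columns.shape or not np.array_equal(
        measured.columns, truth.columns
    ):
        raise CornoctError("relative_error requires matching column ranges")
    diff_um = measured.central_thickness_um - truth.central_thickness_um
    if unit == "pixel":
        return int(np.rint(diff_um / truth.axial_scale_um_per_pixel))
    if unit == "percent":
        if truth.central_thickness_um == 0:
            raise CornoctError("percent relative error undefined for zero true thickness")
        return float(100.0 * diff_um / truth.central_thickness_um)
    raise CornoctError(f"unknown relative_error unit: {unit!r}")
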