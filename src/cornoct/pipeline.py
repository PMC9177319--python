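"""End-to-end orchestration: B-scan in, audited thickness report out.

Stage order: bright-line removal (detection is sharpest on the raw image,
before the median filter smears the stripe) -> adaptive median filtering ->
binarization with island cleanup -> border following -> corneal contour
selection -> bounding rectangle and edge split -> per-edge curve fitting
(RANSAC by default) -> thickness profile.  Any stage failure raises a
:class:`StageError` carrying the stage name; a thickness computed from a
failed segmentation would be worse than no output, so there are no silent
fallbacks — recoverable anomalies (bright line removed, apex clamped) are
surfaced as quality flags instead.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import contours as ct
from . import preprocess as pp
from .errors import CornoctError, StageError
from .fitting import QuadraticCurve, fit_quadratic_lsq, fit_quadratic_ransac
from .image import BScanImage
from .phantom import NoiseModel, generate_phantom, random_geometry
from .profile import SystemProfile
from .thickness import ThicknessProfile, axial_scale, thickness_profile


@dataclass
class PipelineConfig:
    """Every tunable of the measurement pipeline, with serializable defaults."""

    w_init: int = 3
    w_max: int = 7
    brightline_enabled: bool = True
    brightline_z: float = 8.0
    binarize_method: str = "otsu"
    fixed_threshold: Optional[int] = None
    min_island_area: int = 5
    fit_method_upper: str = "ransac"  # "ransac" | "lsq"
    fit_method_lower: str = "ransac"
    ransac_threshold: float = 2.0
    ransac_iterations: int = 500
    pixel_to_sample_ratio: Optional[float] = None  # None -> (N/2)/rows
    half_pixel_correction: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class MeasurementReport:
    """Complete audit trail of one measurement."""

    thickness: ThicknessProfile
    upper_curve: QuadraticCurve
    lower_curve: QuadraticCurve
    contour_stats: dict
    stage_timings: dict
    quality_flags: list[str]
    config: PipelineConfig

    def to_dict(self, include_timings: bool = False) -> dict:
        tp = self.thickness
        d = {
            "central_thickness_um": tp.central_thickness_um,
            "mean_thickness_um": tp.mean_thickness_um,
            "axial_scale_um_per_pixel": tp.axial_scale_um_per_pixel,
            "central_column": tp.central_column,
            "curves": {
                "upper": {**self.upper_curve.to_dict(), "side": "upper",
                          "method": self.config.fit_method_upper},
                "lower": {**self.lower_curve.to_dict(), "side": "lower",
                          "method": self.config.fit_method_lower},
            },
            "contour_stats": self.contour_stats,
            "quality_flags": sorted(self.quality_flags),
            "config": asdict(self.config),
        }
        if include_timings:
            d["stage_timings_s"] = self.stage_timings
        return d

    def to_json(self, include_timings: bool = False) -> str:
        return json.dumps(self.to_dict(include_timings=include_timings),
                          indent=2, sort_keys=True)

    def profile_csv(self, path: str | Path) -> None:
        tp = self.thickness
        cols = np.asarray(tp.columns, dtype=float)
        up = self.upper_curve(cols)
        lo = self.lower_curve(cols)
        pd.DataFrame(
            {
                "column": tp.columns,
                "upper_row": up,
                "lower_row": lo,
                "thickness_um": tp.thickness_um,
                "valid": tp.valid.astype(int),
            }
        ).to_csv(path, index=False)


def _fit_edge(points, method, cfg: PipelineConfig, seed: int):
    if method == "lsq":
        return fit_quadratic_lsq(points), None
    if method == "ransac":
        res = fit_quadratic_ransac(
            points, threshold=cfg.ransac_threshold,
            max_iterations=cfg.ransac_iterations, seed=seed,
        )
        return res.curve, res
    raise CornoctError(f"unknown fit method: {method!r}")


def measure_cornea(image: BScanImage, config: PipelineConfig | None = None) -> MeasurementReport:
    """Run the full measurement on one B-scan.

    Deterministic given the image bytes and the config (the only randomness
    is RANSAC sampling, seeded from ``config.seed``).
    """
    cfg = config or PipelineConfig()
    flags: list[str] = []
    timings: dict[str, float] = {}

    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except CornoctError as e:
            raise StageError(name, str(e)) from e
        timings[name] = time.perf_counter() - t0
        return out

    img = image
    if cfg.brightline_enabled:
        flagged = stage("brightline", pp.detect_bright_line_columns, img, cfg.brightline_z)
        if flagged.size:
            img = stage("brightline", pp.remove_central_bright_line, img, cfg.brightline_z)
            flags.append("line-removed")

    img = stage("filter", pp.adaptive_median_filter, img, cfg.w_init, cfg.w_max)

    if img.pixels.min() == img.pixels.max() and cfg.binarize_method == "otsu":
        raise StageError("binarize", "no cornea found: image is constant after filtering")
    binary = stage(
        "binarize", pp.binarize, img,
        method=cfg.binarize_method, fixed_threshold=cfg.fixed_threshold,
        min_island_area=cfg.min_island_area,
    )

    boundaries = stage("contours", ct.trace_boundaries, binary)
    try:
        corneal = ct.select_corneal_contour(boundaries)
    except CornoctError as e:
        raise StageError("contours", str(e)) from e
    rect = ct.min_bounding_rect(corneal)
    upper_pts, lower_pts = ct.split_edges(corneal, rect)
    contour_stats = {
        "n_boundaries": len(boundaries),
        "n_outer": sum(1 for b in boundaries if b.boundary_type == "outer"),
        "n_holes": sum(1 for b in boundaries if b.boundary_type == "hole"),
        "corneal_contour_length": len(corneal),
        "bounding_rect": list(rect),
        "n_upper_points": len(upper_pts),
        "n_lower_points": len(lower_pts),
    }

    ss = np.random.SeedSequence(cfg.seed)
    s_up, s_lo = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    t0 = time.perf_counter()
    try:
        upper_curve, up_res = _fit_edge(upper_pts, cfg.fit_method_upper, cfg, s_up)
        lower_curve, lo_res = _fit_edge(lower_pts, cfg.fit_method_lower, cfg, s_lo)
    except CornoctError as e:
        raise StageError("fitting", str(e)) from e
    timings["fitting"] = time.perf_counter() - t0
    if cfg.half_pixel_correction:
        # Contour rows are centers of the outermost band pixels, which sit
        # ~0.5 px inside the true surfaces; widen each fitted surface by half
        # a pixel so the band extent is not underestimated by one pixel.
        upper_curve = QuadraticCurve(upper_curve.a, upper_curve.b, upper_curve.C - 0.5)
        lower_curve = QuadraticCurve(lower_curve.a, lower_curve.b, lower_curve.C + 0.5)
    for res, side in ((up_res, "upper"), (lo_res, "lower")):
        if res is not None and not res.inlier_flags.all():
            flags.append(f"{side}-edge-outliers-rejected")
    # weak-edge heuristic: the traced edge covers too little of the image width
    if len(upper_pts) < 0.5 * image.cols or len(lower_pts) < 0.5 * image.cols:
        flags.append("weak-edge")

    scale = axial_scale(image.profile, cfg.pixel_to_sample_ratio)
    cols = np.arange(rect[2], rect[3] + 1)
    tp = stage("thickness", thickness_profile, upper_curve, lower_curve, cols, scale)
    if tp.apex_clamped:
        flags.append("apex-clamped")

    return MeasurementReport(
        thickness=tp,
        upper_curve=upper_curve,
        lower_curve=lower_curve,
        contour_stats=contour_stats,
        stage_timings=timings,
        quality_flags=flags,
        config=cfg,
    )


def evaluate_on_phantoms(
    n: int,
    noise_grid: list[NoiseModel],
    config: PipelineConfig | None = None,
    seed: int = 0,
    profile: SystemProfile | None = None,
    vary_geometry: bool = True,
) -> pd.DataFrame:
    """Score the pipeline on seeded phantoms across a grid of noise levels.

    For each noise level, ``n`` phantoms with jittered physiologic geometry
    are generated, measured, and compared to their ground truth.  Returns one
    row per noise level with recovery statistics and the integer-pixel
    relative-error histogram; pipeline failures are counted, not fatal.
    """
    if n < 1:
        raise CornoctError("evaluate_on_phantoms requires n >= 1")
    cfg = config or PipelineConfig()
    profile = profile or SystemProfile()
    rows = []
    for level_idx, noise in enumerate(noise_grid):
        rng = np.random.default_rng(np.random.SeedSequence((seed, level_idx)))
        errs_um: list[float] = []
        errs_px: list[int] = []
        raw_px: list[float] = []
        centrals: list[float] = []
        truths: list[float] = []
        n_failed = 0
        for rep in range(n):
            geom = random_geometry(profile, rng) if vary_geometry else None
            phantom_seed = int(rng.integers(2**31))
            nm = NoiseModel(
                impulse_probability=noise.impulse_probability,
                speckle_scale=noise.speckle_scale,
                bright_line_column=noise.bright_line_column,
                bright_line_width=noise.bright_line_width,
                bright_line_intensity=noise.bright_line_intensity,
                seed=phantom_seed,
            )
            img, truth = generate_phantom(profile, geom, nm)
            try:
                rep_out = measure_cornea(img, cfg)
            except StageError:
                n_failed += 1
                continue
            tp_true = truth.thickness_profile_true
            err_um = rep_out.thickness.central_thickness_um - tp_true.central_thickness_um
            errs_um.append(err_um)
            raw_px.append(err_um / tp_true.axial_scale_um_per_pixel)
            errs_px.append(int(np.rint(err_um / tp_true.axial_scale_um_per_pixel)))
            centrals.append(rep_out.thickness.central_thickness_um)
            truths.append(tp_true.central_thickness_um)
        hist: dict[int, int] = {}
        for e in errs_px:
            hist[e] = hist.get(e, 0) + 1
        rows.append(
            {
                "impulse_p": noise.impulse_probability,
                "speckle_scale": noise.speckle_scale,
                "bright_line": noise.bright_line_column is not None,
                "n": n,
                "n_failed": n_failed,
                "mean_central_um": float(np.mean(centrals)) if centrals else np.nan,
                "mean_true_um": float(np.mean(truths)) if truths else np.nan,
                "mae_um": float(np.mean(np.abs(errs_um))) if errs_um else np.nan,
                "median_abs_err_px": float(np.median(np.abs(errs_px))) if errs_px else np.nan,
                "within_2px_rate": float(np.mean([abs(e) <= 2.0 for e in raw_px])) if raw_px else np.nan,
                "max_abs_err_px": float(np.max(np.abs(raw_px))) if raw_px else np.nan,
                "relative_error_hist": dict(sorted(hist.items())),
            }
        )
    return pd.DataFrame(rows)
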