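"""Quadratic surface fitting for corneal edges: least squares and RANSAC.

Each corneal surface (anterior or posterior) is modelled as a parabola in
image coordinates, ``row = a*col**2 + b*col + C``.  Edge point sets extracted
from the traced contour are fitted either by ordinary least squares or, for
robustness against residual speckle, artifact remnants and weak-boundary
misdetections, by random sample consensus (RANSAC): repeatedly fit an exact
quadratic through 3 randomly sampled points, score it by the number of points
within a vertical residual threshold, keep the consensus-maximal model, and
polish it with a least-squares refit on the winning inlier set.

Residuals are vertical (row) distances; corneal edges in a B-scan are close
to horizontal, so the vertical residual is a good proxy for the orthogonal
distance at a fraction of its cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import EdgePointSet
from .errors import CornoctError


@dataclass(frozen=True)
class QuadraticCurve:
    """Coefficients of ``row = a*col**2 + b*col + C`` for one corneal surface."""

    a: float
    b: float
    C: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a, self.b, self.C])):
            raise ValueError("curve coefficients must be finite")

    def __call__(self, col) -> np.ndarray | float:
        return evaluate_curve(self, col)

    @property
    def apex_col(self) -> float | None:
        """Column of the parabola vertex, or None for a degenerate (linear) curve."""
        if self.a == 0.0:
            return None
        return -self.b / (2.0 * self.a)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "C": self.C}


@dataclass
class RansacFitResult:
    """Outcome of a RANSAC quadratic fit.

    ``inlier_flags`` marks points whose vertical residual against the final
    (refitted) curve is at most ``inlier_threshold``.
    """

    curve: QuadraticCurve
    inlier_flags: np.ndarray
    n_iterations_used: int
    inlier_threshold: float


def evaluate_curve(curve: QuadraticCurve, col) -> np.ndarray | float:
    """Evaluate ``a*col**2 + b*col + C`` (real-valued, not rounded)."""
    col = np.asarray(col, dtype=np.float64)
    out = curve.a * col**2 + curve.b * col + curve.C
    return out if out.ndim else float(out)


def _as_xy(points: "EdgePointSet | tuple") -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, EdgePointSet):
        return (
            np.asarray(points.cols, dtype=np.float64),
            np.asarray(points.rows, dtype=np.float64),
        )
    cols, rows = points
    return np.asarray(cols, dtype=np.float64), np.asarray(rows, dtype=np.float64)


def fit_quadratic_lsq(points) -> QuadraticCurve:
    """Least-squares quadratic through an edge point set.

    Minimizes the sum of squared vertical (row) residuals.  Requires at least
    3 points with 3 distinct columns; otherwise the normal equations are
    rank-deficient and a :class:`CornoctError` is raised.
    """
    cols, rows = _as_xy(points)
    if cols.size < 3 or np.unique(cols).size < 3:
        raise CornoctError("quadratic fit requires >= 3 points with >= 3 distinct columns")
    a, b, C = np.polyfit(cols, rows, 2)
    return QuadraticCurve(a=float(a), b=float(b), C=float(C))


def _exact_quadratic(cols: np.ndarray, rows: np.ndarray) -> QuadraticCurve | None:
    """Quadratic through exactly 3 points; None if the columns are degenerate."""
    v = np.column_stack([cols**2, cols, np.ones(3)])
    try:
        a, b, C = np.linalg.solve(v, rows)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite([a, b, C])):
        return None
    return QuadraticCurve(a=float(a), b=float(b), C=float(C))


def fit_quadratic_ransac(
    points,
    threshold: float = 2.0,
    max_iterations: int = 500,
    seed: int = 0,
) -> RansacFitResult:
    """RANSAC quadratic fit robust to outlying edge points.

    Parameters
    ----------
    threshold
        Vertical residual (pixels) below which a point counts as an inlier.
    max_iterations
        Number of minimal-sample hypotheses to evaluate.
    seed
        Seed for the sampling RNG; a fixed seed makes the fit deterministic.

    Ties in consensus count are broken by smaller inlier RMS residual, then by
    the first-found model.
    """
    cols, rows = _as_xy(points)
    n = cols.size
    if n < 3:
        raise CornoctError("RANSAC requires at least 3 points")
    if threshold <= 0:
        raise CornoctError("RANSAC inlier threshold must be > 0")
    rng = np.random.default_rng(seed)

    best_count = -1
    best_rms = np.inf
    best_mask: np.ndarray | None = None
    for _ in range(max_iterations):
        idx = rng.choice(n, size=3, replace=False)
        c3, r3 = cols[idx], rows[idx]
        if np.unique(c3).size < 3:
            continue
        model = _exact_quadratic(c3, r3)
        if model is None:
            continue
        resid = np.abs(rows - (model.a * cols**2 + model.b * cols + model.C))
        mask = resid <= threshold
        count = int(mask.sum())
        if count < 3:
            continue
        rms = float(np.sqrt(np.mean(resid[mask] ** 2)))
        if count > best_count or (count == best_count and rms < best_rms):
            best_count, best_rms, best_mask = count, rms, mask

    if best_mask is None:
        raise CornoctError("RANSAC found no 3-point sample with distinct columns")

    curve = fit_quadratic_lsq((cols[best_mask], rows[best_mask]))
    final_resid = np.abs(rows - (curve.a * cols**2 + curve.b * cols + curve.C))
    flags = final_resid <= threshold
    if int(flags.sum()) < 3:
        raise CornoctError("RANSAC consensus collapsed below 3 inliers after refit")
    return RansacFitResult(
        curve=curve,
        inlier_flags=flags,
        n_iterations_used=max_iterations,
        inlier_threshold=float(threshold),
    )
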