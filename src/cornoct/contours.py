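"""Raster-scan border following and corneal edge extraction.

The binary image produced by preprocessing is scanned row by row.  Whenever
the scan hits the starting condition of an outer boundary (a 1-pixel whose
left neighbour is 0) or of a hole boundary (a pixel >= 1 whose right
neighbour is 0), the boundary between that 1-pixel connected component and
the adjacent 0-pixel connected component is traced as a closed, 8-connected
sequence of pixel coordinates.  Marker values (+/- the boundary sequence
number) written into a working copy of the image ensure each boundary is
traced exactly once and let the scan recover the hierarchical nesting of
boundaries: each hole boundary's parent is the outer boundary of the
component enclosing the hole, and each outer boundary's parent is the hole
(or the image frame) that directly surrounds the component.

Connectivity pairing: 1-pixel components are 8-connected, 0-pixel components
4-connected — the standard combination under which every boundary is a
closed curve and the nesting relation is well defined.

Sequence numbers start at 2; number 1 is reserved for the image frame, which
acts as a pseudo hole boundary at the root of the hierarchy and is
represented implicitly (contours whose parent is the frame report
``parent=None``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import CornoctError
from .image import BinaryImage

# 8-neighbourhood offsets in clockwise order (screen coordinates, row down),
# starting from East.  Counterclockwise traversal decrements the index.
_OFFS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
_OFF_INDEX = {off: i for i, off in enumerate(_OFFS)}
_EAST = (0, 1)

FRAME_SEQ = 1  # implicit frame pseudo-boundary


@dataclass
class Contour:
    """One closed boundary: ordered pixel coordinates plus hierarchy info.

    ``points`` are (row, col) pairs; consecutive points are 8-adjacent and the
    first and last points are 8-adjacent (single-point contours excepted).
    ``parent`` is the sequence number of the enclosing boundary, or None when
    the parent is the image frame.
    """

    points: list[tuple[int, int]]
    boundary_type: str  # "outer" | "hole"
    sequence_number: int
    parent: Optional[int] = None

    def __len__(self) -> int:
        return len(self.points)

    def point_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.points)


@dataclass
class EdgePointSet:
    """Per-column samples of one corneal surface.

    ``cols`` are strictly increasing with at most one row per column;
    ``side`` is "upper" (anterior) or "lower" (posterior).
    """

    cols: np.ndarray
    rows: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.cols = np.asarray(self.cols)
        self.rows = np.asarray(self.rows)
        if self.cols.shape != self.rows.shape:
            raise ValueError("cols and rows must have equal length")
        if self.cols.size > 1 and not np.all(np.diff(self.cols) > 0):
            raise ValueError("edge point columns must be strictly increasing")

    def __len__(self) -> int:
        return int(self.cols.size)


def _follow(f: np.ndarray, r0: int, c0: int, r2: int, c2: int, nbd: int) -> list[tuple[int, int]]:
    """Trace one boundary starting at (r0, c0) with initial neighbour (r2, c2)."""
    rows, cols = f.shape

    def val(r: int, c: int) -> int:
        if 0 <= r < rows and 0 <= c < cols:
            return int(f[r, c])
        return 0

    # Clockwise search around the start pixel for the first nonzero neighbour.
    start_idx = _OFF_INDEX[(r2 - r0, c2 - c0)]
    r1 = c1 = None
    for k in range(8):
        dr, dc = _OFFS[(start_idx + k) % 8]
        if val(r0 + dr, c0 + dc) != 0:
            r1, c1 = r0 + dr, c0 + dc
            break
    if r1 is None:  # isolated pixel: single-point closed contour
        f[r0, c0] = -nbd
        return [(r0, c0)]

    pts: list[tuple[int, int]] = []
    r2, c2 = r1, c1
    r3, c3 = r0, c0
    while True:
        # Counterclockwise search around the current point, starting just
        # after the previous point; note whether the East neighbour was
        # examined and found to be 0 (right-edge marking condition).
        idx = _OFF_INDEX[(r2 - r3, c2 - c3)]
        east_zero = False
        r4 = c4 = 0
        for k in range(1, 9):
            dr, dc = _OFFS[(idx - k) % 8]
            if val(r3 + dr, c3 + dc) != 0:
                r4, c4 = r3 + dr, c3 + dc
                break
            if (dr, dc) == _EAST:
                east_zero = True
        if east_zero:
            f[r3, c3] = -nbd
        elif f[r3, c3] == 1:
            f[r3, c3] = nbd
        pts.append((r3, c3))
        if (r4, c4) == (r0, c0) and (r3, c3) == (r1, c1):
            break
        r2, c2 = r3, c3
        r3, c3 = r4, c4
    return pts


def trace_boundaries(binary: BinaryImage) -> list[Contour]:
    """Extract every outer and hole boundary of a binary image.

    Returns the boundaries in raster-scan discovery order with sequence
    numbers 2, 3, ... (1 is the implicit frame).  An all-zero image returns
    an empty list.
    """
    img = binary.pixels
    f = img.astype(np.int64)
    n_rows, n_cols = f.shape

    # Start candidates never change during tracing: the 0/nonzero pattern is
    # static, so a start pixel must be a 1-pixel with a 0 (or frame) left or
    # right neighbour.  Only these pixels are visited; the row-local marker
    # context (LNBD) is recovered on demand by looking left in the row.
    b = img != 0
    left_zero = np.ones_like(b)
    left_zero[:, 1:] = ~b[:, :-1]
    right_zero = np.ones_like(b)
    right_zero[:, :-1] = ~b[:, 1:]
    cand_r, cand_c = np.nonzero(b & (left_zero | right_zero))

    # sequence number -> (type, parent sequence number); frame is a hole.
    info: dict[int, tuple[str, Optional[int]]] = {FRAME_SEQ: ("hole", None)}
    out: list[Contour] = []
    nbd = FRAME_SEQ

    for r, c in zip(cand_r.tolist(), cand_c.tolist()):
        v = f[r, c]
        lz = c == 0 or f[r, c - 1] == 0
        rz = c == n_cols - 1 or f[r, c + 1] == 0
        if v == 1 and lz:
            kind, (sr, sc) = "outer", (r, c - 1)
        elif v >= 1 and rz:
            kind, (sr, sc) = "hole", (r, c + 1)
        else:
            continue

        # LNBD: the last boundary marker encountered before (r, c) in this row.
        if kind == "hole" and v > 1:
            lnbd = int(v)
        else:
            prev = np.nonzero(np.abs(f[r, :c]) > 1)[0]
            lnbd = int(abs(f[r, prev[-1]])) if prev.size else FRAME_SEQ

        nbd += 1
        ptype, pparent = info[lnbd]
        parent = pparent if ptype == kind else lnbd
        info[nbd] = (kind, parent)
        pts = _follow(f, r, c, sr, sc, nbd)
        out.append(
            Contour(
                points=pts,
                boundary_type=kind,
                sequence_number=nbd,
                parent=None if parent == FRAME_SEQ else parent,
            )
        )
    return out


def select_corneal_contour(contours: list[Contour]) -> Contour:
    """Pick the corneal region: the longest outer contour.

    Ties are broken by the smaller sequence number (earlier in raster order).
    """
    outers = [c for c in contours if c.boundary_type == "outer"]
    if not outers:
        raise NoCorneaFound("no cornea found: image contains no outer boundaries")
    return min(outers, key=lambda c: (-len(c), c.sequence_number))


class NoCorneaFound(CornoctError):
    pass


def min_bounding_rect(contour: Contour) -> tuple[int, int, int, int]:
    """Axis-aligned tight bounds (row_min, row_max, col_min, col_max)."""
    if not contour.points:
        raise CornoctError("cannot bound an empty contour")
    rows = [p[0] for p in contour.points]
    cols = [p[1] for p in contour.points]
    return (min(rows), max(rows), min(cols), max(cols))


def split_edges(
    contour: Contour, rect: tuple[int, int, int, int]
) -> tuple[EdgePointSet, EdgePointSet]:
    """Split a corneal contour into upper (anterior) and lower (posterior) edges.

    Within the bounding rectangle, the minimum contour row per column is an
    upper-edge point and the maximum a lower-edge point.  Columns where the
    two coincide (single-row band) contribute to the upper edge only, so the
    thickness there is 0 rather than undefined.
    """
    _, _, col_min, col_max = rect
    per_col: dict[int, tuple[int, int]] = {}
    for r, c in contour.points:
        if col_min <= c <= col_max:
            lohi = per_col.get(c)
            if lohi is None:
                per_col[c] = (r, r)
            else:
                per_col[c] = (min(lohi[0], r), max(lohi[1], r))

    cols_sorted = sorted(per_col)
    up_c, up_r, lo_c, lo_r = [], [], [], []
    for c in cols_sorted:
        rmin, rmax = per_col[c]
        up_c.append(c)
        up_r.append(rmin)
        if rmax > rmin:
            lo_c.append(c)
            lo_r.append(rmax)
    upper = EdgePointSet(cols=np.array(up_c, dtype=int), rows=np.array(up_r, dtype=int), side="upper")
    lower = EdgePointSet(cols=np.array(lo_c, dtype=int), rows=np.array(lo_r, dtype=int), side="lower")
    return upper, lower


def contours_to_csv(contours: list[Contour], path) -> None:
    """Export contours as CSV: sequence_number, type, parent, point index, row, col."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sequence_number", "type", "parent", "point_index", "row", "col"])
        for c in contours:
            for i, (r, col) in enumerate(c.points):
                w.writerow([c.sequence_number, c.boundary_type, c.parent if c.parent is not None else "", i, r, col])
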