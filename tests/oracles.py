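"""Independent brute-force oracles used to validate the package's algorithms.

These deliberately avoid the implementation paths they check: boundary sets
are derived from connected-component labelling and 4-adjacency scans, and
the median oracle sorts explicit window copies pixel by pixel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_S8 = np.ones((3, 3), dtype=int)
_S4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)
_N4 = ((0, 1), (0, -1), (1, 0), (-1, 0))


def brute_force_boundaries(img: np.ndarray):
    """Expected boundary point sets of a binary image.

    Returns ``(outers, holes)``:

    * ``outers``: dict mapping 1-component label -> frozenset of (row, col)
      pixels of that component 4-adjacent to its directly surrounding
      0-component (the image frame counts as background).
    * ``holes``: list of (enclosing 1-component label, frozenset of pixels of
      that component 4-adjacent to the hole), one entry per 4-connected
      0-component not connected to the frame.

    1-components are 8-connected, 0-components 4-connected.
    """
    img = np.asarray(img) != 0
    lab1, n1 = ndimage.label(img, structure=_S8)
    pad0 = np.pad(~img, 1, constant_values=True)
    lab0, _ = ndimage.label(pad0, structure=_S4)
    bg_root = lab0[0, 0]

    def zero_label(r, c):  # unpadded coords -> 0-component label (frame = bg_root)
        return lab0[r + 1, c + 1]

    outers = {}
    for comp in range(1, n1 + 1):
        rs, cs = np.nonzero(lab1 == comp)
        r0 = rs.min()
        c0 = cs[rs == r0].min()
        surround = zero_label(r0, c0 - 1)  # left of topmost-leftmost pixel
        pts = set()
        for r, c in zip(rs, cs):
            if any(zero_label(r + dr, c + dc) == surround for dr, dc in _N4):
                pts.add((int(r), int(c)))
        outers[comp] = frozenset(pts)

    holes = []
    n0 = lab0.max()
    for z in range(1, n0 + 1):
        if z == bg_root:
            continue
        rs, cs = np.nonzero(lab0 == z)
        rs, cs = rs - 1, cs - 1  # back to unpadded coords
        r0 = rs.min()
        c0 = cs[rs == r0].min()
        cc = c0 - 1
        while not img[r0, cc]:  # first 1-pixel walking left: enclosing component
            cc -= 1
        owner = int(lab1[r0, cc])
        pts = set()
        zmask_pad = lab0 == z
        for r, c in zip(np.nonzero(lab1 == owner)[0], np.nonzero(lab1 == owner)[1]):
            if any(zmask_pad[r + 1 + dr, c + 1 + dc] for dr, dc in _N4):
                pts.add((int(r), int(c)))
        holes.append((owner, frozenset(pts)))
    return outers, holes


def brute_force_median(img: np.ndarray, size: int) -> np.ndarray:
    """Plain median filter with edge replication, computed window by window."""
    img = np.asarray(img)
    half = size // 2
    padded = np.pad(img, half, mode="edge")
    out = np.empty_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            win = padded[r : r + size, c : c + size]
            out[r, c] = np.median(win)
    return out


def random_binary_image(rng: np.random.Generator, max_side: int = 32) -> np.ndarray:
    """Random test images mixing sparse noise, blobs and rings."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    kind = rng.integers(0, 3)
    if kind == 0:  # iid pixels at a random density
        img = (rng.random((h, w)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
    elif kind == 1:  # smoothed blobs with holes
        field = ndimage.gaussian_filter(rng.random((h, w)), sigma=rng.uniform(0.5, 2.0))
        img = (field > np.quantile(field, rng.uniform(0.3, 0.7))).astype(np.uint8)
    else:  # rectangles and rings
        img = np.zeros((h, w), dtype=np.uint8)
        for _ in range(int(rng.integers(1, 4))):
            r0, c0 = rng.integers(0, h), rng.integers(0, w)
            r1, c1 = rng.integers(0, h), rng.integers(0, w)
            sl = (slice(min(r0, r1), max(r0, r1) + 1), slice(min(c0, c1), max(c0, c1) + 1))
            img[sl] = 1
            if rng.random() < 0.5 and img[sl].shape >= (3, 3):
                inner = (slice(sl[0].start + 1, sl[0].stop - 1),
                         slice(sl[1].start + 1, sl[1].stop - 1))
                img[inner] = 0
    return img
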