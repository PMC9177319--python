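"""In-memory containers for B-scan images and binary masks, with PNG/TIFF I/O.

Coordinate convention used throughout the package: rows are indexed top-down
from 0 (axial/depth direction), columns left-right from 0 (lateral direction).
A corneal surface is a function mapping column -> row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .profile import SystemProfile

GRAY_MIN = 0
GRAY_MAX = 255


@dataclass
class BScanImage:
    """A single grayscale OCT B-scan plus its acquisition profile.

    ``pixels`` is a ``rows x cols`` uint8 array of gray values in [0, 255].
    """

    pixels: np.ndarray
    profile: SystemProfile = field(default_factory=SystemProfile)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"B-scan pixels must be 2-D, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.size and (arr.min() < GRAY_MIN or arr.max() > GRAY_MAX):
                raise ValueError("gray values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    def copy_with(self, pixels: np.ndarray) -> "BScanImage":
        return BScanImage(pixels=pixels, profile=self.profile)

    def save(self, path: str | Path) -> None:
        iio.imwrite(Path(path), self.pixels)

    @classmethod
    def load(cls, path: str | Path, profile: SystemProfile | None = None) -> "BScanImage":
        arr = iio.imread(Path(path))
        if arr.ndim == 3:  # collapse RGB(A) to luma
            arr = np.round(arr[..., :3].astype(np.float64).mean(axis=-1)).astype(np.uint8)
        if arr.dtype != np.uint8:
            arr = np.clip(arr, GRAY_MIN, GRAY_MAX).astype(np.uint8)
        return cls(pixels=arr, profile=profile or SystemProfile())


@dataclass
class BinaryImage:
    """A two-valued image: pixels are exactly 0 or 1 (``0 pixel`` / ``1 pixel``)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"binary pixels must be 2-D, got shape {arr.shape}")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("binary image values must be exactly 0 or 1")
        self.pixels = arr.astype(np.uint8)

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "BinaryImage":
        return cls(pixels=np.asarray(mask, dtype=bool).astype(np.uint8))
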