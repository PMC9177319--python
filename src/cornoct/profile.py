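"""Acquisition geometry of a spectral-domain anterior-segment OCT system.

A Fourier-domain OCT A-scan is reconstructed from the real part of the
interference spectrum, so the tomogram contains the sample together with its
mirror image about the zero-delay line; only half of the ``N`` axial samples
cover the usable imaging depth ``h``.  The physical depth per axial sample is
therefore ``2h/N`` — the factor that converts pixel distances between the two
corneal surfaces into micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class SystemProfile:
    """Instrument constants of the imaging system.

    Defaults describe the swept-source system used for anterior-segment
    corneal B-scans: 3.7 mm imaging depth, 1820 samples per A-scan,
    360 A-scans per B-scan rendered as a 360 x 360 pixel image, 7.5 um
    axial and 57.0 um lateral resolution at a 1060 nm center wavelength.

    Parameters
    ----------
    imaging_depth_mm
        Usable imaging depth ``h`` in millimeters.
    samples_per_ascan
        Number of axial samples ``N`` per A-scan (before mirror-image
        truncation, i.e. ``N/2`` samples span ``h``).
    ascans_per_bscan
        Number of A-scans (lateral positions) per B-scan.
    rows, cols
        Pixel dimensions of the rendered B-scan image.
    """

    imaging_depth_mm: float = 3.7
    samples_per_ascan: int = 1820
    ascans_per_bscan: int = 360
    rows: int = 360
    cols: int = 360
    axial_resolution_um: float = 7.5
    lateral_resolution_um: float = 57.0
    center_wavelength_nm: float = 1060.0

    def __post_init__(self) -> None:
        if self.imaging_depth_mm <= 0:
            raise ValueError("imaging_depth_mm must be > 0")
        if self.samples_per_ascan < 2:
            raise ValueError("samples_per_ascan must be >= 2")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("image dimensions must be >= 1")

    @property
    def sample_pitch_um(self) -> float:
        """Physical depth per axial sample, ``2h/N``, in micrometers."""
        return 2.0 * self.imaging_depth_mm * 1000.0 / self.samples_per_ascan

    @property
    def default_pixel_to_sample_ratio(self) -> float:
        """Axial samples per image row when ``rows`` resample the usable depth.

        The ``N/2`` usable samples span ``h``; displayed as ``rows`` pixels the
        ratio is ``(N/2)/rows``, making the default axial scale ``h/rows``.
        """
        return self.samples_per_ascan / (2.0 * self.rows)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SystemProfile":
        return cls(**d)
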