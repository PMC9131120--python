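"""Shared data containers for colony structural-colour analyses.

Conventions used throughout the package:

* all angles are in degrees and measured from the sample normal;
* illumination angles are negative, detection angles span both sides of
  the normal, and the specular direction of illumination ``theta`` is
  ``-theta``;
* wavelengths and lengths at the cell scale are in nanometres, cell
  lengths in micrometres, image pixel pitch in nm/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralMap", "CellProfile", "DomainImage"]


@dataclass
class SpectralMap:
    """Normalized angular-resolved reflectance at a fixed illumination angle.

    ``intensity[i, j]`` is the reflectance (normalized against a white
    diffuser) at ``wavelengths[i]`` and detection angle ``angles[j]``.
    The goniometer cannot detect at the illumination angle itself, so a
    dark band of ``dark_band_halfwidth`` degrees around ``theta_illum``
    is masked to zero.  ``specular_window`` marks the angle interval
    containing the specular reflection, whose intensity is far stronger
    than the diffracted signal; on disk that window is stored divided by
    300 (the display convention) but in memory it is always physical.

    Attributes
    ----------
    wavelengths : ndarray
        Strictly increasing wavelength grid (nm).
    angles : ndarray
        Strictly increasing detection-angle grid (deg).
    intensity : ndarray, shape (len(wavelengths), len(angles))
        Non-negative normalized reflectance.
    theta_illum : float
        Illumination angle (deg, negative by convention).
    dark_band_halfwidth : float
        Half-width of the masked band around ``theta_illum`` (deg).
    specular_window : tuple of float, optional
        ``(lo, hi)`` angle interval containing the specular peak.
    """

    wavelengths: np.ndarray
    angles: np.ndarray
    intensity: np.ndarray
    theta_illum: float = -60.0
    dark_band_halfwidth: float = 3.0
    specular_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.wavelengths.ndim != 1 or self.angles.ndim != 1:
            raise ValueError("wavelength and angle grids must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angle grid must be strictly increasing")
        if self.intensity.shape != (self.wavelengths.size, self.angles.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"({self.wavelengths.size}, {self.angles.size})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if not -90.0 < self.theta_illum < 90.0:
            raise ValueError("theta_illum must lie in (-90, 90) deg")
        if np.any(self.intensity[:, self.dark_band_mask()] != 0.0):
            raise ValueError("dark band around theta_illum must be masked to zero")

    @property
    def specular_angle(self) -> float:
        """Lab angle of the specular reflection (deg)."""
        return -self.theta_illum

    def dark_band_mask(self) -> np.ndarray:
        """Boolean mask over ``angles`` of the undetectable band."""
        return np.abs(self.angles - self.theta_illum) <= self.dark_band_halfwidth

    def specular_mask(self) -> np.ndarray:
        """Boolean mask over ``angles`` of the specular window (all-False if unset)."""
        if self.specular_window is None:
            return np.zeros(self.angles.size, dtype=bool)
        lo, hi = self.specular_window
        return (self.angles >= lo) & (self.angles <= hi)


@dataclass
class CellProfile:
    """Diameter of one cell sampled at fixed intervals along its length.

    Emulates the cryo-TEM measurement protocol in which the cell width is
    read off every 300 nm along the cell axis.
    """

    cell_id: str
    positions_nm: np.ndarray
    diameters_nm: np.ndarray
    length_um: float

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.diameters_nm = np.asarray(self.diameters_nm, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.positions_nm.size < 2:
            raise ValueError("a cell profile needs at least two samples")
        if self.positions_nm.shape != self.diameters_nm.shape:
            raise ValueError("positions and diameters must have equal length")
        steps = np.diff(self.positions_nm)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("positions must be evenly spaced")
        if np.any(self.diameters_nm <= 0):
            raise ValueError("diameters must be positive")
        if self.length_um <= 0:
            raise ValueError("cell length must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.positions_nm.size)

    @property
    def spacing_nm(self) -> float:
        return float(self.positions_nm[1] - self.positions_nm[0])


@dataclass
class DomainImage:
    """Microscopy-like intensity field of a crystalline-domain mosaic.

    ``pixels`` is either a 2-D greyscale array or an (ny, nx, 3) RGB
    array; ``pixel_pitch_nm`` converts pixel coordinates to physical
    length.
    """

    pixels: np.ndarray
    pixel_pitch_nm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.pixels.ndim == 3:
            if self.pixels.shape[2] != 3:
                raise ValueError("colour images must have 3 channels")
        elif self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D greyscale or (ny, nx, 3) RGB")
        if min(self.pixels.shape[:2]) < 64:
            raise ValueError("image sides must be at least 64 px")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]
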