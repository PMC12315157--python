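"""Core in-memory containers for hyperspectral data.

A :class:`HyperspectralCube` is the package's central object: a
``rows x cols x bands`` reflectance array with its wavelength axis and a
boolean region-of-interest (ROI) mask marking analysable sediment pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["HyperspectralCube", "ReferenceSpectra", "ReflectanceSpectrum"]


@dataclass
class HyperspectralCube:
    """Calibrated reflectance cube with wavelength axis and ROI mask.

    Parameters
    ----------
    reflectance : ndarray, shape (rows, cols, bands)
        Unitless reflectance, finite, typically in [0, ~1.2].
    wavelengths_nm : ndarray, shape (bands,)
        Strictly increasing band-centre wavelengths in nanometres.
    roi_mask : ndarray of bool, shape (rows, cols)
        True marks analysable pixels. Defaults to all-true.
    meta : dict
        Free-form acquisition record (exposure, timestamps, provenance).
    """

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    roi_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be a 3-D (rows, cols, bands) array")
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size != self.n_bands:
            raise ValueError(
                f"wavelengths_nm length {self.wavelengths_nm.size} does not match "
                f"band count {self.n_bands}"
            )
        if self.wavelengths_nm.size > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if self.roi_mask is None:
            self.roi_mask = np.ones(self.spatial_shape, dtype=bool)
        else:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.spatial_shape:
                raise ValueError(
                    f"roi_mask shape {self.roi_mask.shape} does not match spatial "
                    f"shape {self.spatial_shape}"
                )

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.reflectance.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Nearest-neighbour band lookup on the wavelength axis."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))

    def copy(self) -> "HyperspectralCube":
        return HyperspectralCube(
            reflectance=self.reflectance.copy(),
            wavelengths_nm=self.wavelengths_nm.copy(),
            roi_mask=self.roi_mask.copy(),
            meta=dict(self.meta),
        )


@dataclass
class ReferenceSpectra:
    """White/dark reference spectra used for reflectance calibration.

    ``white_raw`` may contain overexposed entries (counts above
    ``sensor_max``); those are reconstructed from a non-overexposed seed
    acquisition by fitting ``a * seed**b + c`` on the valid entries.
    ``fit_params`` stores the fitted (a, b, c) after correction.
    """

    white_raw: np.ndarray
    dark: np.ndarray
    seed_white: np.ndarray | None = None
    sensor_max: float = 4095.0
    fit_params: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.white_raw = np.asarray(self.white_raw, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.seed_white is not None:
            self.seed_white = np.asarray(self.seed_white, dtype=np.float64)
            if self.seed_white.shape != self.white_raw.shape:
                raise ValueError("seed_white must match white_raw in length")
        if self.dark.shape != self.white_raw.shape:
            raise ValueError("dark must match white_raw in length")
        if self.sensor_max <= 0:
            raise ValueError("sensor_max must be positive")


@dataclass
class ReflectanceSpectrum:
    """A single reflectance spectrum with its wavelength axis."""

    values: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.values.shape != self.wavelengths_nm.shape:
            raise ValueError("values and wavelengths_nm must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")
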