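"""Grayscale-image operations.

Interval selection from a hyperspectral cube down to a single grayscale
image (mean / median / Gaussian-weighted band averaging), the filtering
and normalisation function set (Gaussian, derivative of Gaussian, median,
Gabor 7x7 and 9x9, max, min, min-max scaling), and spectral aggregation
(ROI mean) back down to a scalar feature.

All 2-D filters use reflect padding at the image border and are computed
over the full rectangle; features are later read only within the ROI,
which keeps convolution well-defined near mask holes. Filters never
modify the ROI mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cube import HyperspectralCube
from .spectra import ALLOWED_WIDTHS, _window_bounds

__all__ = [
    "GrayscaleImage",
    "image_interval_select",
    "apply_filter",
    "spectral_aggregate",
    "gabor_kernel",
    "ALLOWED_KERNEL_SIZES",
    "GABOR_SIGMA",
    "GABOR_GAMMA",
    "GABOR_PSI",
]

#: Legal spatial filter kernel sizes (pixels).
ALLOWED_KERNEL_SIZES = (3, 5, 7, 9, 11)

# Fixed Gabor envelope parameters; only orientation and frequency evolve.
GABOR_SIGMA = 2.0
GABOR_GAMMA = 0.3
GABOR_PSI = 1.0


@dataclass
class GrayscaleImage:
    """A single-channel image with the ROI mask inherited from its cube."""

    values: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.values.shape != self.roi_mask.shape:
            raise ValueError("mask shape must equal image shape")


def image_interval_select(
    cube: HyperspectralCube,
    center: int,
    width: int,
    mode: str = "mean",
    sigma: float = 1.0,
) -> GrayscaleImage:
    """Collapse a band window of the cube to one grayscale image.

    Per pixel, the bands in the window of nominal ``width`` centred at
    ``center`` are aggregated by ``mode``:

    - ``mean``: plain average;
    - ``median``: per-pixel median;
    - ``gaussian``: weights ``exp(-delta^2 / (2 sigma^2))`` over band
      offsets delta, renormalised to sum to one over the surviving bands.

    Windows are truncated at the spectral edges (no padding). The ROI
    mask is inherited unchanged.
    """
    lo, hi = _window_bounds(center, width, cube.n_bands)
    window = cube.reflectance[:, :, lo:hi]
    if mode == "mean":
        img = window.mean(axis=2)
    elif mode == "median":
        img = np.median(window, axis=2)
    elif mode == "gaussian":
        if not 0 < sigma <= 5:
            raise ValueError("gaussian sigma must be in (0, 5]")
        offsets = np.arange(lo, hi) - center
        weights = np.exp(-(offsets**2) / (2.0 * sigma**2))
        weights /= weights.sum()
        img = np.tensordot(window, weights, axes=([2], [0]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GrayscaleImage(img, cube.roi_mask)


def gabor_kernel(
    ksize: int,
    frequency: float,
    theta: float,
    sigma: float = GABOR_SIGMA,
    gamma: float = GABOR_GAMMA,
    psi: float = GABOR_PSI,
) -> np.ndarray:
    """Real-valued Gabor kernel of an exact ``ksize x ksize`` extent.

    ``g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(f x' + psi)``
    with (x', y') the coordinates rotated by ``theta`` and ``f`` the
    angular frequency in radians per pixel.
    """
    half = ksize // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    x_t = x * np.cos(theta) + y * np.sin(theta)
    y_t = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-(x_t**2 + (gamma * y_t) ** 2) / (2.0 * sigma**2))
    return envelope * np.cos(frequency * x_t + psi)


def apply_filter(image: GrayscaleImage, kind: str, **params) -> GrayscaleImage:
    """Apply one of the filtering/normalisation primitives.

    ``kind`` is one of ``gaussian``, ``dog`` (derivative of Gaussian,
    returned as gradient magnitude at scale sigma), ``median``, ``gabor7``,
    ``gabor9``, ``max``, ``min``, ``minmax``. Min-max scaling maps the ROI
    values onto [0, 1]; a constant ROI maps to all zeros.
    """
    vals = image.values
    if kind == "gaussian":
        k, sigma = _ksize(params), _sigma(params)
        out = ndimage.gaussian_filter(
            vals, sigma, mode="reflect", radius=k // 2
        )
    elif kind == "dog":
        sigma = _sigma(params)
        gx = ndimage.gaussian_filter(vals, sigma, order=(0, 1), mode="reflect")
        gy = ndimage.gaussian_filter(vals, sigma, order=(1, 0), mode="reflect")
        out = np.hypot(gx, gy)
    elif kind == "median":
        out = ndimage.median_filter(vals, size=_ksize(params), mode="reflect")
    elif kind in ("gabor7", "gabor9"):
        ksize = 7 if kind == "gabor7" else 9
        kernel = gabor_kernel(ksize, params["frequency"], params["theta"])
        out = ndimage.convolve(vals, kernel, mode="reflect")
    elif kind == "max":
        out = ndimage.maximum_filter(vals, size=_ksize(params), mode="reflect")
    elif kind == "min":
        out = ndimage.minimum_filter(vals, size=_ksize(params), mode="reflect")
    elif kind == "minmax":
        out = _minmax_scale(vals, image.roi_mask)
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    return GrayscaleImage(out, image.roi_mask)


def _ksize(params: dict) -> int:
    k = params["ksize"]
    if k not in ALLOWED_KERNEL_SIZES:
        raise ValueError(f"kernel size must be one of {ALLOWED_KERNEL_SIZES}, got {k}")
    return int(k)


def _sigma(params: dict) -> float:
    sigma = params["sigma"]
    if not 0 < sigma <= 5:
        raise ValueError("sigma must be in (0, 5]")
    return float(sigma)


def _minmax_scale(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    roi = vals[mask] if mask.any() else vals.ravel()
    lo, hi = roi.min(), roi.max()
    if hi == lo:  # constant ROI: all zeros, avoids division by zero
        return np.zeros_like(vals)
    return (vals - lo) / (hi - lo)


def spectral_aggregate(image: GrayscaleImage) -> float:
    """Mean pixel intensity over the ROI — a grayscale image's one-number
    spectral feature."""
    if not image.roi_mask.any():
        raise ValueError("empty ROI: nothing to aggregate")
    return float(image.values[image.roi_mask].mean())
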