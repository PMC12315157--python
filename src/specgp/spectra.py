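"""Spectrum-level operations.

Mean-spectrum extraction over an ROI, standard normal variate (SNV),
Savitzky-Golay smoothing, and variable-width spectral interval selection
(the aggregation of a contiguous band window into one scalar feature).

All operations accept either a single length-B spectrum or an ``n x B``
matrix of spectra; matrix inputs are processed row-wise (vectorised).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .cube import HyperspectralCube, ReflectanceSpectrum

__all__ = [
    "mean_spectrum",
    "snv",
    "savitzky_golay",
    "spectra_interval_select",
    "ALLOWED_WIDTHS",
]

#: Legal interval window widths (odd, in bands).
ALLOWED_WIDTHS = (1, 3, 5, 7, 9, 11)


def mean_spectrum(cube: HyperspectralCube) -> ReflectanceSpectrum:
    """Per-band arithmetic mean over the cube's ROI pixels."""
    mask = cube.roi_mask
    if not mask.any():
        raise ValueError("empty ROI: no pixels to average")
    values = cube.reflectance[mask].mean(axis=0)
    return ReflectanceSpectrum(values, cube.wavelengths_nm)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre each spectrum, scale to unit sd.

    Uses the sample standard deviation (n-1 denominator). Corrects
    multiplicative illumination and scatter effects: ``snv(a*x+b) == snv(x)``
    for any a > 0.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum")
    return (x - mean) / sd


def savitzky_golay(spectrum: np.ndarray, window: int = 9, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing, length-preserving."""
    x = np.asarray(spectrum, dtype=np.float64)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > x.shape[-1]:
        raise ValueError("window exceeds spectrum length")
    return savgol_filter(x, window, polyorder, axis=-1)


def _window_bounds(center: int, width: int, n_bands: int) -> tuple[int, int]:
    if not 0 <= center <= n_bands - 1:
        raise ValueError(f"center band {center} outside [0, {n_bands - 1}]")
    if width not in ALLOWED_WIDTHS:
        raise ValueError(f"width must be one of {ALLOWED_WIDTHS}, got {width}")
    half = width // 2
    return max(0, center - half), min(n_bands, center + half + 1)


def spectra_interval_select(
    spectrum: np.ndarray, center: int, width: int, mode: str = "mean"
) -> float | np.ndarray:
    """Aggregate a contiguous band window into one spectral feature.

    The window of nominal ``width`` is centred at band ``center`` and
    truncated at the spectrum edges (no padding); the mean is then taken
    over the surviving entries only, i.e. the averaging weights are
    renormalised to sum to one. ``mode`` is ``"mean"`` or ``"median"``
    (median of an even-count truncated window is the midpoint of the two
    central values).

    Returns a scalar for a 1-D input, a length-n vector for an ``n x B``
    matrix of spectra.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    lo, hi = _window_bounds(center, width, x.shape[-1])
    window_vals = x[..., lo:hi]
    if mode == "mean":
        out = window_vals.mean(axis=-1)
    elif mode == "median":
        out = np.median(window_vals, axis=-1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out
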