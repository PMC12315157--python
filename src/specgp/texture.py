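"""Gray-level co-occurrence matrices and texture descriptors.

The GLCM here differs from a stock implementation in two ways demanded by
the pipeline: intensities are quantised by min-max binning over the ROI
(making every descriptor invariant to affine intensity rescaling), and a
pixel pair is only counted when *both* pixels lie inside the ROI.
Accumulation is symmetric, so an offset angle and its opposite produce
identical matrices — the reason only four angles {0, 45, 90, 135} deg are
ever used.

Descriptors: homogeneity, entropy (bits), contrast, correlation, energy
(square root of the angular second moment), plus first-four-moment
histogram statistics over the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .images import GrayscaleImage

__all__ = [
    "GLCMMatrix",
    "glcm",
    "glcm_feature",
    "histogram_feature",
    "GLCM_FEATURE_NAMES",
    "HISTOGRAM_STATS",
    "ALLOWED_DISTANCES",
    "GLCM_ANGLES",
]

GLCM_FEATURE_NAMES = ("homogeneity", "entropy", "contrast", "correlation", "energy")
HISTOGRAM_STATS = ("mean", "sd", "skewness", "kurtosis")
ALLOWED_DISTANCES = (1, 2, 3, 4, 5)
#: Angle grid: multiples of 45 degrees; opposite angles are redundant.
GLCM_ANGLES = tuple(i * np.pi / 4 for i in range(4))


@dataclass
class GLCMMatrix:
    """Symmetric, normalised co-occurrence matrix at one (d, theta) offset."""

    p: np.ndarray
    levels: int
    distance: int
    angle: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (self.levels, self.levels):
            raise ValueError("p must be levels x levels")


def _quantise(image: GrayscaleImage, levels: int) -> np.ndarray:
    """Min-max bin ROI intensities into ``levels`` integer grey levels."""
    vals = image.values
    roi = vals[image.roi_mask]
    lo, hi = roi.min(), roi.max()
    if hi == lo:
        return np.zeros(vals.shape, dtype=np.intp)
    q = np.floor((vals - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def _offset(distance: int, angle: float) -> tuple[int, int]:
    # Row/col displacement for an angle measured counterclockwise from
    # the +col axis (image convention: row axis points down).
    dr = -int(round(distance * np.sin(angle)))
    dc = int(round(distance * np.cos(angle)))
    return dr, dc


def glcm(
    image: GrayscaleImage, distance: int, angle: float, levels: int = 32
) -> GLCMMatrix:
    """Build the symmetric normalised GLCM at offset (distance, angle).

    Both pixels of a counted pair must lie inside the ROI. Raises if the
    ROI admits no valid pair at this offset.
    """
    if distance not in ALLOWED_DISTANCES:
        raise ValueError(f"distance must be in {ALLOWED_DISTANCES}, got {distance}")
    if not image.roi_mask.any():
        raise ValueError("empty ROI")
    q = _quantise(image, levels)
    dr, dc = _offset(distance, angle)
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("offset larger than image: no valid pairs")
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = image.roi_mask[r0:r1, c0:c1] & image.roi_mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        raise ValueError("ROI admits no valid pixel pair at this offset")
    i, j = src[valid], dst[valid]
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    counts += counts.T  # symmetric accumulation
    return GLCMMatrix(counts / counts.sum(), levels, distance, angle)


def glcm_feature(m: GLCMMatrix, name: str) -> float:
    """One of the five co-occurrence descriptors of matrix ``m``."""
    p = m.p
    idx = np.arange(m.levels, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    if name == "homogeneity":
        return float((p / (1.0 + (i - j) ** 2)).sum())
    if name == "entropy":
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())
    if name == "contrast":
        return float((p * (i - j) ** 2).sum())
    if name == "correlation":
        mu_i = float((i * p).sum())
        mu_j = float((j * p).sum())
        var_i = float((p * (i - mu_i) ** 2).sum())
        var_j = float((p * (j - mu_j) ** 2).sum())
        denom = np.sqrt(var_i * var_j)
        if denom == 0:  # flat texture: correlation defined as 0
            return 0.0
        return float(((i - mu_i) * (j - mu_j) * p).sum() / denom)
    if name == "energy":
        return float(np.sqrt((p**2).sum()))
    raise ValueError(f"unknown GLCM feature {name!r}")


def histogram_feature(
    image: GrayscaleImage, stat: str, excess_kurtosis: bool = True
) -> float:
    """First-four-moment statistics of the ROI intensity histogram.

    ``sd`` uses the sample (n-1) convention. ``kurtosis`` is excess by
    default (normal -> 0); pass ``excess_kurtosis=False`` for the raw
    fourth standardised moment.
    """
    vals = image.values[image.roi_mask]
    if stat == "mean":
        if vals.size < 1:
            raise ValueError("empty ROI")
        return float(vals.mean())
    if stat == "sd":
        if vals.size < 2:
            raise ValueError("sd needs at least 2 ROI pixels")
        return float(vals.std(ddof=1))
    if stat in ("skewness", "kurtosis"):
        if vals.size < 3 or np.ptp(vals) == 0:
            raise ValueError(f"{stat} needs >= 3 non-degenerate ROI pixels")
        if stat == "skewness":
            return float(stats.skew(vals))
        return float(stats.kurtosis(vals, fisher=excess_kurtosis))
    raise ValueError(f"unknown histogram statistic {stat!r}")
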