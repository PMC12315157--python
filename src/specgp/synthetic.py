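"""Synthetic hyperspectral scenes with known ground truth.

Generates cubes whose spectra are a smooth sediment-like base curve with
planted Gaussian absorption features whose depths encode the target
attribute, modulated by a spatial texture field, under per-sample
illumination drift, with bright "shell" blobs and per-pixel noise. Every
downstream stage (calibration, segmentation, interval selection, GP
recovery, baseline selectors) is testable against the planted truth
without any field data.

The generator's defaults define the study conditions for the recovery
experiments: two planted absorption bands, an attribute range matching
sediment organic-matter content (percent loss-on-ignition), and a
planted-dip depth at the top of the attribute range equal to five times
the per-pixel noise standard deviation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cube import HyperspectralCube
from .io import write_envi_cube

__all__ = [
    "SyntheticSceneSpec",
    "default_wavelengths",
    "base_spectrum",
    "make_sample",
    "make_dataset",
    "mean_spectra_matrix",
]


def default_wavelengths(n_bands: int = 204) -> np.ndarray:
    """Band-centre grid of a 204-band VNIR camera, 397.32-1003.58 nm."""
    return np.linspace(397.32, 1003.58, n_bands)


def base_spectrum(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Smooth sediment-like reflectance: low in the blue, rising through
    the red edge with gentle curvature (low-order polynomial)."""
    t = (wavelengths_nm - wavelengths_nm[0]) / (
        wavelengths_nm[-1] - wavelengths_nm[0]
    )
    return 0.08 + 0.35 * t - 0.13 * t**2


@dataclass
class SyntheticSceneSpec:
    """Ground-truth recipe for one synthetic scene family.

    ``planted_bands`` is a list of ``(centre_nm, sd_nm, depth_per_unit)``:
    at attribute value y the reflectance dips by
    ``depth_per_unit * y * exp(-(lambda - centre)^2 / (2 sd^2))``.
    """

    n_bands: int = 204
    image_size: tuple[int, int] = (32, 32)
    planted_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(550.0, 6.0, 0.024), (850.0, 6.0, 0.024)]
    )
    attribute_range: tuple[float, float] = (0.5, 2.1)
    baseline_variation: float = 0.02
    texture_correlation_px: float = 3.0
    texture_amplitude: float = 0.05
    texture_attribute_coupling: float = 0.0
    shell_count: int = 0
    shell_brightness: float = 0.9
    shell_radius_px: int = 2
    illumination_drift: float = 0.1
    noise_sd: float = 0.01

    def wavelengths(self) -> np.ndarray:
        return default_wavelengths(self.n_bands)

    def __post_init__(self) -> None:
        wl = self.wavelengths()
        for centre, _, _ in self.planted_bands:
            if not wl[0] <= centre <= wl[-1]:
                raise ValueError(f"planted centre {centre} nm outside wavelength range")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def planted_band_indices(self) -> list[int]:
        wl = self.wavelengths()
        return [int(np.argmin(np.abs(wl - c))) for c, _, _ in self.planted_bands]

    def dip_profile(self, y: float) -> np.ndarray:
        """Absolute reflectance dip at attribute value y, per band."""
        wl = self.wavelengths()
        dip = np.zeros_like(wl)
        for centre, sd, depth in self.planted_bands:
            dip += depth * y * np.exp(-((wl - centre) ** 2) / (2.0 * sd**2))
        return dip


def _texture_field(
    shape: tuple[int, int], correlation_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-sd smoothed white noise (Gaussian-filtered)."""
    white = rng.standard_normal(shape)
    if correlation_px <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, correlation_px, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_sample(
    spec: SyntheticSceneSpec, y: float, rng: np.random.Generator
) -> tuple[HyperspectralCube, float]:
    """Generate one cube whose planted dips encode attribute value ``y``.

    Per pixel and band:
    ``illum * [base(lam) * (1 + amp * T) - dip(lam, y)] + noise``
    with shell blobs overwriting their pixels with flat high reflectance.
    The ROI mask is all-true; shell segmentation is exercised downstream.
    """
    wl = spec.wavelengths()
    h, w = spec.image_size
    base = base_spectrum(wl)
    if spec.baseline_variation > 0:
        # per-sample smooth baseline variability (grain size, moisture,
        # sky conditions): random low-order polynomial modulation. Smooth
        # terms cannot mimic a narrow absorption dip, so the attribute
        # stays decodable only locally at the planted bands.
        t = np.linspace(-1.0, 1.0, spec.n_bands)
        coefs = rng.normal(0.0, spec.baseline_variation, size=3)
        modulation = 1.0 + coefs[0] * t + coefs[1] * (t**2) + coefs[2] * (t**3)
        base = base * modulation
    dip = spec.dip_profile(y)
    illum = 1.0 + spec.illumination_drift * (2.0 * rng.random() - 1.0)
    amp = spec.texture_amplitude * (1.0 + spec.texture_attribute_coupling * y)
    texture = _texture_field((h, w), spec.texture_correlation_px, rng)
    spectral = base[None, None, :] * (1.0 + amp * texture[:, :, None])
    data = illum * (spectral - dip[None, None, :])
    if spec.shell_count > 0:
        rr, cc = np.mgrid[0:h, 0:w]
        for _ in range(spec.shell_count):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            blob = (rr - cy) ** 2 + (cc - cx) ** 2 <= spec.shell_radius_px**2
            data[blob, :] = spec.shell_brightness
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)
    cube = HyperspectralCube(data, wl, meta={"y": float(y)})
    return cube, float(y)


def make_dataset(
    spec: SyntheticSceneSpec,
    n: int,
    rng: np.random.Generator,
    out_dir: str | None = None,
) -> tuple[list[HyperspectralCube], np.ndarray, pd.DataFrame]:
    """Generate ``n`` samples with attribute values uniform over the range.

    Returns (cubes, y, manifest). When ``out_dir`` is given, cubes are
    written as ENVI header+raw pairs and the manifest as
    ``manifest.csv`` in the same column layout the real-data path uses
    (sample_id, cube_path, quadrat, cell_row, cell_col, organic_matter).
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    lo, hi = spec.attribute_range
    ys = lo + (hi - lo) * rng.random(n)
    cubes, rows = [], []
    for i, y in enumerate(ys):
        cube, _ = make_sample(spec, float(y), rng)
        cubes.append(cube)
        path = ""
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            path = os.path.join(out_dir, f"sample_{i:03d}.hdr")
            write_envi_cube(cube, path)
        rows.append(
            {
                "sample_id": f"S{i:03d}",
                "cube_path": path,
                "quadrat": i // 5 + 1,
                "cell_row": (1, 1, 5, 5, 3)[i % 5],
                "cell_col": (1, 5, 1, 5, 3)[i % 5],
                "organic_matter": float(y),
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return cubes, ys, manifest


def mean_spectra_matrix(
    cubes: list[HyperspectralCube],
    snv_first: bool = True,
    savgol_window: int = 9,
    savgol_polyorder: int = 2,
) -> np.ndarray:
    """ROI mean spectra of a cube list as an ``n x B`` matrix.

    Default preprocessing per pixel before averaging: SNV then
    Savitzky-Golay smoothing — the pipeline's standard pretreatment.
    Pass ``snv_first=False`` and ``savgol_window=0`` for raw means.
    """
    from .spectra import savitzky_golay, snv

    rows = []
    for cube in cubes:
        px = cube.reflectance[cube.roi_mask]
        if snv_first:
            px = snv(px)
        if savgol_window:
            px = savitzky_golay(px, savgol_window, savgol_polyorder)
        rows.append(px.mean(axis=0))
    return np.vstack(rows)
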