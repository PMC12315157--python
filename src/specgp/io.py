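"""Cube I/O and radiometric calibration.

Covers the front end of the pipeline: reading/writing ENVI header+raw
pairs (the dialect a SPECIM IQ camera emits), reconstructing overexposed
white-reference entries, converting raw counts to reflectance, gridding a
quadrat into subregions, and removing bright shell/specular pixels from
the ROI mask.
"""

from __future__ import annotations

import os
import re
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.morphology import disk, erosion

from .cube import HyperspectralCube, ReferenceSpectra

__all__ = [
    "FormatError",
    "read_envi_cube",
    "write_envi_cube",
    "read_mask",
    "write_mask",
    "correct_white_reference",
    "calibrate_reflectance",
    "segment_bright_objects",
    "grid_quadrat",
    "reference_sample_cells",
]


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent ENVI files."""


_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_TO_CODE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}

# Axis order of the flat file for each interleave, as (axis of lines,
# axis of samples, axis of bands) in the stored array.
_INTERLEAVE_SHAPE = {
    "bsq": ("bands", "lines", "samples"),
    "bil": ("lines", "bands", "samples"),
    "bip": ("lines", "samples", "bands"),
}


def _parse_envi_header(header_path: str) -> dict:
    with open(header_path, "r") as fh:
        text = fh.read()
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError(f"{header_path}: missing ENVI magic line")
    fields: dict[str, str] = {}
    # Join brace-delimited multi-line values first.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_brace_list(value: str) -> list[float]:
    inner = value.strip()
    if inner.startswith("{"):
        inner = inner[1:]
    if inner.endswith("}"):
        inner = inner[:-1]
    return [float(tok) for tok in inner.replace(",", " ").split()]


def read_envi_cube(header_path: str, mask_path: str | None = None) -> HyperspectralCube:
    """Read an ENVI header+raw pair into a :class:`HyperspectralCube`.

    Accepts BIL/BIP/BSQ interleaves. Wavelengths come from the header's
    ``wavelength`` field. When ``mask_path`` is given it is loaded as the
    ROI mask (NPY boolean array or PNG where nonzero = inside ROI);
    otherwise the mask is all-true.
    """
    fields = _parse_envi_header(header_path)
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"{header_path}: missing required field {exc}") from exc
    if interleave not in _INTERLEAVE_SHAPE:
        raise FormatError(f"{header_path}: unknown interleave {interleave!r}")
    if dtype_code not in _DTYPE_CODES:
        raise FormatError(f"{header_path}: unsupported data type code {dtype_code}")
    if "wavelength" not in fields:
        raise FormatError(f"{header_path}: header lacks a wavelength list")
    wavelengths = np.asarray(_parse_brace_list(fields["wavelength"]), dtype=np.float64)
    if wavelengths.size != bands:
        raise FormatError(
            f"{header_path}: {wavelengths.size} wavelengths for {bands} bands"
        )

    raw_path = _sibling_raw_path(header_path)
    dtype = np.dtype(_DTYPE_CODES[dtype_code])
    byte_order = int(fields.get("byte order", "0"))
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")
    data = np.fromfile(raw_path, dtype=dtype)
    expected = lines * samples * bands
    if data.size != expected:
        raise FormatError(
            f"{raw_path}: raw holds {data.size} values, header implies {expected}"
        )
    axes = _INTERLEAVE_SHAPE[interleave]
    shape = tuple({"lines": lines, "samples": samples, "bands": bands}[a] for a in axes)
    data = data.reshape(shape)
    order = tuple(axes.index(a) for a in ("lines", "samples", "bands"))
    cube_data = np.ascontiguousarray(np.transpose(data, order), dtype=np.float64)

    roi_mask = read_mask(mask_path) if mask_path else None
    meta = {"header_path": header_path}
    for key in ("tint", "acquisition date", "acquisition time", "description"):
        if key in fields:
            meta[key] = fields[key]
    return HyperspectralCube(cube_data, wavelengths, roi_mask, meta)


def _sibling_raw_path(header_path: str) -> str:
    stem, _ = os.path.splitext(header_path)
    for candidate in (stem + ".raw", stem + ".dat", stem + ".img", stem):
        if os.path.isfile(candidate) and candidate != header_path:
            return candidate
    raise FormatError(f"no raw data file found next to {header_path}")


def write_envi_cube(
    cube: HyperspectralCube,
    header_path: str,
    interleave: str = "bil",
    dtype: np.dtype | type = np.float32,
) -> str:
    """Write a cube as an ENVI header+raw pair; returns the raw path."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVE_SHAPE:
        raise FormatError(f"unknown interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_TO_CODE:
        raise FormatError(f"unsupported dtype {dtype}")
    rows, cols = cube.spatial_shape
    axes = _INTERLEAVE_SHAPE[interleave]
    order = tuple(("lines", "samples", "bands").index(a) for a in axes)
    stored = np.ascontiguousarray(
        np.transpose(cube.reflectance, order).astype(dtype)
    )
    raw_path = os.path.splitext(header_path)[0] + ".raw"
    stored.tofile(raw_path)
    wl = ", ".join(f"{w:.12g}" for w in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_CODE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    return raw_path


def read_mask(path: str) -> np.ndarray:
    if path.endswith(".npy"):
        return np.asarray(np.load(path), dtype=bool)
    from imageio.v3 import imread

    img = imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img) > 0


def write_mask(mask: np.ndarray, path: str) -> None:
    if path.endswith(".npy"):
        np.save(path, np.asarray(mask, dtype=bool))
        return
    from imageio.v3 import imwrite

    imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def correct_white_reference(ref: ReferenceSpectra) -> np.ndarray:
    """Reconstruct overexposed white-reference entries from a seed curve.

    Entries of ``white_raw`` at or below ``sensor_max`` pass through
    unchanged. Entries above it (overexposed) are replaced by
    ``a * seed**b + c`` where (a, b, c) minimise the squared difference
    between the transformed seed and the non-overexposed entries. The
    fitted parameters are stored back on ``ref.fit_params``.
    """
    white = ref.white_raw
    if ref.seed_white is None:
        raise ValueError("a seed white spectrum is required for correction")
    over = white > ref.sensor_max
    if not np.any(over):
        ref.fit_params = None
        return white.copy()
    valid = ~over
    if valid.sum() < 3:
        raise ValueError(
            "all (or nearly all) white-reference entries are overexposed; "
            "cannot fit the correction"
        )
    seed = ref.seed_white
    if np.any(seed[valid] <= 0):
        raise ValueError("seed white spectrum must be positive where fitted")

    def model(s: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
        return a * np.power(s, b) + c

    # b bounded to keep seed**b well-behaved; initialised at the identity.
    popt, _ = curve_fit(
        model,
        seed[valid],
        white[valid],
        p0=(1.0, 1.0, 0.0),
        bounds=([-np.inf, 0.05, -np.inf], [np.inf, 20.0, np.inf]),
        maxfev=20000,
    )
    a, b, c = (float(v) for v in popt)
    ref.fit_params = (a, b, c)
    corrected = white.copy()
    corrected[over] = model(seed[over], a, b, c)
    return corrected


def calibrate_reflectance(
    raw: np.ndarray,
    white: np.ndarray,
    dark: np.ndarray,
    wavelengths_nm: np.ndarray | None = None,
    roi_mask: np.ndarray | None = None,
) -> HyperspectralCube:
    """Standard two-point reflectance calibration.

    Per pixel and band, ``R = (raw - dark) / (white - dark)``, with the
    white and dark reference spectra broadcast over the spatial axes.
    """
    raw = np.asarray(raw, dtype=np.float64)
    white = np.asarray(white, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    if raw.ndim != 3:
        raise ValueError("raw must be (rows, cols, bands)")
    denom = white - dark
    if np.any(denom <= 0):
        bad = np.nonzero(denom <= 0)[0]
        raise ValueError(f"degenerate reference bands (white <= dark) at {bad.tolist()}")
    reflectance = (raw - dark[None, None, :]) / denom[None, None, :]
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(raw.shape[2], dtype=np.float64)
    return HyperspectralCube(reflectance, wavelengths_nm, roi_mask)


def segment_bright_objects(
    cube: HyperspectralCube,
    threshold_wavelength_nm: float = 873.0,
    threshold: float | None = None,
    erosion_radius: int = 1,
) -> tuple[np.ndarray, bool]:
    """Remove bright shell/specular pixels from the ROI mask.

    Pixels whose reflectance at the band nearest ``threshold_wavelength_nm``
    exceeds ``threshold`` are dropped; the surviving mask is then eroded by
    a disc of ``erosion_radius`` pixels. When ``threshold`` is None an Otsu
    threshold on that band (within the current ROI) is used.

    Returns ``(new_mask, empty)`` where ``empty`` flags an all-false result.
    """
    wl = cube.wavelengths_nm
    if not (wl[0] <= threshold_wavelength_nm <= wl[-1]):
        raise ValueError(
            f"threshold wavelength {threshold_wavelength_nm} nm outside cube "
            f"range [{wl[0]}, {wl[-1]}]"
        )
    band = cube.reflectance[:, :, cube.band_index(threshold_wavelength_nm)]
    mask = cube.roi_mask.copy()
    if threshold is None:
        vals = band[mask]
        if vals.size == 0 or np.ptp(vals) == 0:
            return mask, not mask.any()
        threshold = float(threshold_otsu(vals))
    mask &= ~(band > threshold)
    if erosion_radius > 0:
        mask = erosion(mask, disk(erosion_radius)).astype(bool)
    return mask, not mask.any()


def grid_quadrat(
    cube: HyperspectralCube, rows: int = 5, cols: int = 5
) -> list[HyperspectralCube]:
    """Divide a quadrat cube into a rows x cols grid of sub-cubes.

    Cells are returned row-major. Remainder pixels go to the last
    row/column so the cells tile the quadrat exactly; each sub-cube
    carries its crop of the ROI mask.
    """
    h, w = cube.spatial_shape
    if h < rows or w < cols:
        raise ValueError(f"quadrat {h}x{w} smaller than the {rows}x{cols} grid")
    r_edges = _cell_edges(h, rows)
    c_edges = _cell_edges(w, cols)
    cells = []
    for ri in range(rows):
        for ci in range(cols):
            r0, r1 = r_edges[ri], r_edges[ri + 1]
            c0, c1 = c_edges[ci], c_edges[ci + 1]
            cells.append(
                HyperspectralCube(
                    cube.reflectance[r0:r1, c0:c1],
                    cube.wavelengths_nm,
                    cube.roi_mask[r0:r1, c0:c1],
                    {**cube.meta, "cell": (ri + 1, ci + 1)},
                )
            )
    return cells


def _cell_edges(extent: int, n: int) -> list[int]:
    size = extent // n
    edges = [i * size for i in range(n)]
    edges.append(extent)  # last cell absorbs the remainder
    return edges


def reference_sample_cells(rows: int = 5, cols: int = 5) -> list[tuple[int, int]]:
    """Grid cells carrying ground-truth reference cores (1-based).

    The field protocol samples the four corners and the direct centre of
    the 5x5 quadrat grid.
    """
    return [(1, 1), (1, cols), (rows, 1), (rows, cols), ((rows + 1) // 2, (cols + 1) // 2)]
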