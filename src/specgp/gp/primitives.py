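"""Typed primitive and terminal sets for the two program structures.

Five data types flow through a tree: HSI (hyperspectral image), GSI
(grayscale image), SPECTRA (reflectance spectrum), SF (scalar spectral
feature) and FV (feature vector). Parameter terminals (band index,
window width, kernel size, Gabor orientation/frequency, GLCM distance/
angle, sigma) are ephemeral constants drawn from fixed ranges and are
re-sampled by leaf mutation.

Evaluation is polymorphic over a *batch* of spectra: in the spectra
structure SPECTRA values are ``n x B`` matrices and SF values length-n
vectors, so one tree evaluation covers the whole calibration set. In the
image structure a tree is evaluated per cube (SF values are scalars).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .. import images as im
from .. import spectra as sp
from .. import texture as tx

__all__ = ["GPType", "Primitive", "TerminalSpec", "PrimitiveSet", "build_primitive_set"]


class GPType(Enum):
    # data types
    HSI = "HSI"
    GSI = "GSI"
    SPECTRA = "SPECTRA"
    SF = "SF"
    FV = "FV"
    # parameter (terminal-only) types
    LAMBDA = "lambda"
    W = "w"
    SIGMA = "sigma"
    K = "k"
    THETA = "theta"
    F = "f"
    THETA_G = "theta_g"
    D = "d"


DATA_TYPES = (GPType.HSI, GPType.GSI, GPType.SPECTRA, GPType.SF, GPType.FV)

#: Protected-division cutoff: |denominator| below this yields 0.
DIV_EPS = 1e-9


@dataclass(frozen=True)
class Primitive:
    name: str
    ret: GPType
    args: tuple[GPType, ...]
    fn: Callable

    @property
    def arity(self) -> int:
        return len(self.args)


@dataclass(frozen=True)
class TerminalSpec:
    """How to draw a value for a parameter terminal type."""

    type: GPType
    sampler: Callable[[np.random.Generator], object]


def _protected_div(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    out = np.where(np.abs(b) < DIV_EPS, 0.0, np.divide(a, np.where(b == 0, 1.0, b)))
    return out if out.ndim else float(out)


def _to_fv(sf):
    arr = np.asarray(sf, dtype=np.float64)
    if arr.ndim == 0:  # single sample: FV is a 1-D vector
        return arr.reshape(1)
    return arr.reshape(-1, 1)  # batch: FV is (n, k)


def _concat(*fvs):
    if fvs[0].ndim == 1:
        return np.concatenate(fvs)
    return np.hstack(fvs)


def _glcm_fv(feature_name: str):
    def fn(gsi, d, theta_g):
        m = tx.glcm(gsi, d, theta_g)
        return np.asarray([tx.glcm_feature(m, feature_name)])

    return fn


def _hist_fv(stat: str):
    def fn(gsi):
        return np.asarray([tx.histogram_feature(gsi, stat)])

    return fn


def _spectra_values(spec_or_matrix):
    # SPECTRA values flow as plain arrays: (B,) per cube or (n, B) batch.
    return np.asarray(spec_or_matrix, dtype=np.float64)


@dataclass
class PrimitiveSet:
    """The typed function/terminal set of one program structure."""

    structure: str  # "spectra" | "image"
    n_bands: int
    primitives: list[Primitive] = field(default_factory=list)
    terminals: dict[GPType, TerminalSpec] = field(default_factory=dict)
    input_type: GPType = GPType.SPECTRA
    root_names: tuple[str, ...] = ("root2", "root3", "root4", "to_fv")
    max_depth: int = 8
    init_depth: tuple[int, int] = (3, 6)
    # reachable subtree heights per type: (min_height, extensible?)
    _heights: dict[GPType, tuple[int, bool]] = field(default_factory=dict)

    def by_ret(self, t: GPType) -> list[Primitive]:
        return [p for p in self.primitives if p.ret == t]

    def roots(self) -> list[Primitive]:
        return [p for p in self.primitives if p.name in self.root_names]

    def get(self, name: str) -> Primitive:
        for p in self.primitives:
            if p.name == name:
                return p
        raise KeyError(name)

    def min_height(self, t: GPType) -> int:
        return self._heights[t][0]

    def extensible(self, t: GPType) -> bool:
        return self._heights[t][1]

    def has_terminal(self, t: GPType) -> bool:
        return t in self.terminals or t == self.input_type

    def compute_heights(self) -> None:
        """Fixed-point computation of minimal subtree height per type,
        plus whether heights above the minimum are also achievable."""
        INF = math.inf
        h: dict[GPType, float] = {t: INF for t in GPType}
        for t in self.terminals:
            h[t] = 0
        h[self.input_type] = 0
        changed = True
        while changed:
            changed = False
            for p in self.primitives:
                if any(h[a] is INF or h[a] == INF for a in p.args):
                    continue
                cand = 1 + max((h[a] for a in p.args), default=0)
                if cand < h[p.ret]:
                    h[p.ret] = cand
                    changed = True
        # a type is extensible if some primitive returning it consumes it
        # (directly or through an extensible chain); conservative direct check
        ext: dict[GPType, bool] = {t: False for t in GPType}
        for p in self.primitives:
            if p.ret in p.args and h[p.ret] != INF:
                ext[p.ret] = True
        # SF extends via arithmetic, FV via roots, GSI via filters,
        # SPECTRA via snv/savgol (image set); additionally a type is
        # extensible if it can be produced from an extensible argument type.
        changed = True
        while changed:
            changed = False
            for p in self.primitives:
                if ext[p.ret] or h[p.ret] == INF:
                    continue
                if any(ext[a] for a in p.args if h[a] != INF):
                    ext[p.ret] = True
                    changed = True
        self._heights = {
            t: (int(h[t]) if h[t] != INF else -1, ext[t]) for t in GPType
        }

    def can_reach(self, t: GPType, height: int) -> bool:
        """Can a subtree of type ``t`` have exactly this height?"""
        mn, ext = self._heights[t]
        if mn < 0:
            return False
        if height == mn:
            return True
        if height == 0:
            return self.has_terminal(t)
        return ext and height > mn

    def can_fit(self, t: GPType, max_height: int) -> bool:
        mn = self._heights[t][0]
        return mn >= 0 and mn <= max_height


def _common_primitives() -> list[Primitive]:
    T = GPType
    return [
        Primitive(
            "sis_mean",
            T.SF,
            (T.SPECTRA, T.LAMBDA, T.W),
            lambda s, lam, w: sp.spectra_interval_select(s, lam, w, "mean"),
        ),
        Primitive(
            "sis_median",
            T.SF,
            (T.SPECTRA, T.LAMBDA, T.W),
            lambda s, lam, w: sp.spectra_interval_select(s, lam, w, "median"),
        ),
        Primitive("add", T.SF, (T.SF, T.SF), lambda a, b: np.asarray(a) + np.asarray(b)),
        Primitive("sub", T.SF, (T.SF, T.SF), lambda a, b: np.asarray(a) - np.asarray(b)),
        Primitive("mul", T.SF, (T.SF, T.SF), lambda a, b: np.asarray(a) * np.asarray(b)),
        Primitive("div", T.SF, (T.SF, T.SF), _protected_div),
        Primitive("to_fv", T.FV, (T.SF,), _to_fv),
        Primitive("root2", T.FV, (T.FV, T.FV), _concat),
        Primitive("root3", T.FV, (T.FV, T.FV, T.FV), _concat),
        Primitive("root4", T.FV, (T.FV, T.FV, T.FV, T.FV), _concat),
    ]


def _image_primitives() -> list[Primitive]:
    T = GPType
    prims = [
        Primitive(
            "iis_mean",
            T.GSI,
            (T.HSI, T.LAMBDA, T.W),
            lambda c, lam, w: im.image_interval_select(c, lam, w, "mean"),
        ),
        Primitive(
            "iis_gaussian",
            T.GSI,
            (T.HSI, T.LAMBDA, T.W, T.SIGMA),
            lambda c, lam, w, s: im.image_interval_select(c, lam, w, "gaussian", s),
        ),
        Primitive(
            "iis_median",
            T.GSI,
            (T.HSI, T.LAMBDA, T.W),
            lambda c, lam, w: im.image_interval_select(c, lam, w, "median"),
        ),
        Primitive(
            "f_gaussian",
            T.GSI,
            (T.GSI, T.K, T.SIGMA),
            lambda g, k, s: im.apply_filter(g, "gaussian", ksize=k, sigma=s),
        ),
        Primitive(
            "f_dog",
            T.GSI,
            (T.GSI, T.SIGMA),
            lambda g, s: im.apply_filter(g, "dog", sigma=s),
        ),
        Primitive(
            "f_median",
            T.GSI,
            (T.GSI, T.K),
            lambda g, k: im.apply_filter(g, "median", ksize=k),
        ),
        Primitive(
            "f_gabor7",
            T.GSI,
            (T.GSI, T.F, T.THETA),
            lambda g, f, t: im.apply_filter(g, "gabor7", frequency=f, theta=t),
        ),
        Primitive(
            "f_gabor9",
            T.GSI,
            (T.GSI, T.F, T.THETA),
            lambda g, f, t: im.apply_filter(g, "gabor9", frequency=f, theta=t),
        ),
        Primitive(
            "f_max",
            T.GSI,
            (T.GSI, T.K),
            lambda g, k: im.apply_filter(g, "max", ksize=k),
        ),
        Primitive(
            "f_min",
            T.GSI,
            (T.GSI, T.K),
            lambda g, k: im.apply_filter(g, "min", ksize=k),
        ),
        Primitive(
            "f_minmax", T.GSI, (T.GSI,), lambda g: im.apply_filter(g, "minmax")
        ),
        Primitive(
            "mean_spectra",
            T.SPECTRA,
            (T.HSI,),
            lambda c: _spectra_values(sp.mean_spectrum(c).values),
        ),
        Primitive("sp_snv", T.SPECTRA, (T.SPECTRA,), lambda s: sp.snv(s)),
        Primitive(
            "sp_savgol",
            T.SPECTRA,
            (T.SPECTRA,),
            lambda s: sp.savitzky_golay(s, 9, 2),
        ),
        Primitive("agg", T.SF, (T.GSI,), lambda g: im.spectral_aggregate(g)),
    ]
    for name in tx.GLCM_FEATURE_NAMES:
        prims.append(
            Primitive(f"glcm_{name}", T.FV, (T.GSI, T.D, T.THETA_G), _glcm_fv(name))
        )
    for stat in tx.HISTOGRAM_STATS:
        prims.append(Primitive(f"hist_{stat}", T.FV, (T.GSI,), _hist_fv(stat)))
    return prims


def _terminal_specs(n_bands: int) -> dict[GPType, TerminalSpec]:
    T = GPType
    return {
        T.LAMBDA: TerminalSpec(T.LAMBDA, lambda rng: int(rng.integers(0, n_bands))),
        T.W: TerminalSpec(T.W, lambda rng: int(rng.choice(sp.ALLOWED_WIDTHS))),
        T.SIGMA: TerminalSpec(
            T.SIGMA, lambda rng: float(5.0 * (1.0 - rng.random()))  # (0, 5]
        ),
        T.K: TerminalSpec(T.K, lambda rng: int(rng.choice(im.ALLOWED_KERNEL_SIZES))),
        T.THETA: TerminalSpec(
            T.THETA, lambda rng: float(int(rng.integers(0, 8)) * np.pi / 4)
        ),
        T.F: TerminalSpec(
            T.F,
            lambda rng: float(np.pi * 2.0 ** -(1.0 + 0.5 * int(rng.integers(0, 4)))),
        ),
        T.THETA_G: TerminalSpec(
            T.THETA_G, lambda rng: float(int(rng.integers(0, 4)) * np.pi / 4)
        ),
        T.D: TerminalSpec(T.D, lambda rng: int(rng.choice(tx.ALLOWED_DISTANCES))),
    }


def build_primitive_set(structure: str, n_bands: int) -> PrimitiveSet:
    """Assemble the typed primitive set for one program structure.

    ``structure`` is ``"spectra"`` (input: mean reflectance spectrum) or
    ``"image"`` (input: hyperspectral cube; the superset with grayscale
    filtering, texture and in-tree spectral preprocessing primitives).
    """
    if structure == "spectra":
        pset = PrimitiveSet(
            structure="spectra",
            n_bands=n_bands,
            primitives=_common_primitives(),
            input_type=GPType.SPECTRA,
            max_depth=8,
            init_depth=(3, 6),
        )
        terms = _terminal_specs(n_bands)
        pset.terminals = {t: terms[t] for t in (GPType.LAMBDA, GPType.W)}
    elif structure == "image":
        pset = PrimitiveSet(
            structure="image",
            n_bands=n_bands,
            primitives=_common_primitives() + _image_primitives(),
            input_type=GPType.HSI,
            max_depth=9,
            init_depth=(4, 7),
        )
        pset.terminals = _terminal_specs(n_bands)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    pset.compute_heights()
    return pset
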