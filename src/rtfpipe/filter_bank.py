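"""The 11-version image filter bank.

Eleven image versions feed feature extraction: the original image, four
point-processing filters (square, squareroot, logarithm, exponential), and
six neighbourhood filters (gradient magnitude, rotation-invariant uniform
local binary patterns, and the four sub-bands of a single-level undecimated
2D wavelet decomposition).

Point-filter conventions follow the widely used reference-tool formulas,
with range-normalizing constants so the output stays on a scale comparable
to the input (M = max |x| over the image):

    square:      f = x^2 / M
    squareroot:  f = sign(x) * sqrt(|x| * M)
    logarithm:   f = sign(x) * M * log(|x| + 1) / log(M + 1)
    exponential: f = exp(x * log(M) / M)

An all-zero image leaves the normalizing constants undefined; the transform
then falls back to the identity with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from skimage.feature import local_binary_pattern

__all__ = [
    "FilterSettings",
    "FILTER_LABELS",
    "apply_point_filter",
    "apply_gradient",
    "apply_lbp2d",
    "apply_wavelet",
    "build_stack",
]

POINT_FILTERS = ("square", "squareroot", "logarithm", "exponential")
WAVELET_LABELS = ("wavelet-LL", "wavelet-LH", "wavelet-HL", "wavelet-HH")
FILTER_LABELS = ("original",) + POINT_FILTERS + ("gradient", "lbp-2D") + WAVELET_LABELS


@dataclass(frozen=True)
class FilterSettings:
    """Settings for the neighbourhood filters (point filters take none)."""

    lbp_radius: int = 1
    lbp_samples: int = 9
    lbp_method: str = "uniform"
    wavelet_basis: str = "coif1"
    point_filter_set: tuple[str, ...] = POINT_FILTERS

    def __post_init__(self):
        if self.lbp_samples < 4 or self.lbp_radius < 1:
            raise ValueError("need lbp_samples >= 4 and lbp_radius >= 1")


def apply_point_filter(image: np.ndarray, kind: str) -> np.ndarray:
    """Element-wise monotone intensity transform with range-preserving scaling."""
    if kind not in POINT_FILTERS:
        raise ValueError(f"unknown point filter {kind!r}")
    x = np.asarray(image, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("image contains non-finite values")
    m = float(np.abs(x).max())
    if m == 0.0:
        warnings.warn(f"all-zero image: {kind} scaling undefined, returning identity",
                      RuntimeWarning, stacklevel=2)
        return x.copy()
    if kind == "square":
        return x ** 2 / m
    if kind == "squareroot":
        return np.sign(x) * np.sqrt(np.abs(x) * m)
    if kind == "logarithm":
        return np.sign(x) * m * np.log1p(np.abs(x)) / np.log1p(m)
    # exponential
    return np.exp(x * np.log(m) / m)


def apply_gradient(image: np.ndarray, spacing=(1.0, 1.0)) -> np.ndarray:
    """Gradient magnitude from central differences in physical units (per mm)."""
    x = np.asarray(image, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    gr, gc = np.gradient(x, spacing[0], spacing[1])
    return np.hypot(gr, gc)


def apply_lbp2d(image: np.ndarray, settings: FilterSettings | None = None) -> np.ndarray:
    """Rotation-invariant uniform local binary pattern codes.

    With P samples the uniform code set is {0, ..., P+1}; the per-ROI maximum
    of these codes saturates at P+1 on essentially any textured image, which
    is why the downstream per-ROI Maximum of this version degenerates.
    """
    settings = settings or FilterSettings()
    x = np.asarray(image, dtype=float)
    if min(x.shape) < 2 * settings.lbp_radius + 1:
        raise ValueError("image smaller than the LBP neighbourhood")
    r = settings.lbp_radius
    with warnings.catch_warnings():
        # parametric maps are inherently float-valued; the integer-dtype
        # recommendation does not apply to this use
        warnings.filterwarnings("ignore", message=".*floating-point images.*",
                                category=UserWarning)
        # edge-replicate so border pixels see a full neighbourhood (a constant
        # image then receives one uniform code everywhere)
        padded = np.pad(x, r, mode="edge")
        codes = local_binary_pattern(padded, P=settings.lbp_samples, R=r,
                                     method=settings.lbp_method)
    return codes[r:-r, r:-r]


def apply_wavelet(image: np.ndarray, basis: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level undecimated 2D wavelet decomposition at input resolution.

    Returns the four sub-bands keyed ``wavelet-LL/LH/HL/HH`` (low/high-pass in
    the horizontal then vertical direction).  The image is padded to even
    dimensions for the stationary transform and cropped back.
    """
    x = np.asarray(image, dtype=float)
    pad_r = x.shape[0] % 2
    pad_c = x.shape[1] % 2
    xp = np.pad(x, ((0, pad_r), (0, pad_c)), mode="symmetric")
    (ca, (ch, cv, cd)), = pywt.swt2(xp, basis, level=1, norm=True)
    out = {"wavelet-LL": ca, "wavelet-LH": ch, "wavelet-HL": cv, "wavelet-HH": cd}
    if pad_r or pad_c:
        out = {k: v[: x.shape[0], : x.shape[1]] for k, v in out.items()}
    return {k: np.ascontiguousarray(v) for k, v in out.items()}


def build_stack(image: np.ndarray, settings: FilterSettings | None = None,
                spacing=(1.0, 1.0)) -> dict[str, np.ndarray]:
    """All 11 image versions, keyed by canonical filter label; deterministic."""
    settings = settings or FilterSettings()
    x = np.asarray(image, dtype=float)
    stack: dict[str, np.ndarray] = {"original": x.copy()}
    for kind in settings.point_filter_set:
        stack[kind] = apply_point_filter(x, kind)
    stack["gradient"] = apply_gradient(x, spacing)
    stack["lbp-2D"] = apply_lbp2d(x, settings)
    stack.update(apply_wavelet(x, settings.wavelet_basis))
    assert set(stack) == set(FILTER_LABELS) and len(stack) == 11
    return {label: stack[label] for label in FILTER_LABELS}
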