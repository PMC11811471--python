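"""93-feature radiomic texture engine.

Features are computed per 2D image version within a binary ROI, after
in-plane resampling to 1 mm.  The 93 features split into six classes:
18 first-order statistics and five gray-level matrix families — GLCM (24),
GLRLM (16), GLSZM (16), GLDM (14) and NGTDM (5) — following the
standardized (IBSI-conform) definitional formulas.  Applied to the 11-image
filter stack this yields 11 x 93 = 1023 named features per (map, mask).

Conventions (documented because the matrices admit several dialects):

* Discretization: fixed bin width, level(x) = floor((x - min_ROI)/W) + 1.
* GLCM/GLRLM: the four in-plane directions at distance 1; features are
  computed per direction and averaged.
* GLSZM zones and GLDM/NGTDM neighbourhoods use 8-connectivity.
* GLDM: a neighbour is dependent if |level difference| <= alpha (default 0);
  the dependence size j counts the centre pixel plus its dependent
  neighbours, so an isolated pixel has j = 1.
* NGTDM: pixels with no in-ROI neighbour are excluded from the counts.
* Degenerate fallbacks: 0*log(0) = 0; correlation-type features on
  zero-variance matrices return 1; Skewness and Kurtosis of a constant ROI
  return 0; NGTDM Coarseness is capped at 1e6 when its denominator vanishes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from importlib import resources

import numpy as np
from scipy import ndimage

from .filter_bank import FILTER_LABELS, FilterSettings, build_stack
from .synthetic_cohort import BinaryMask, ParametricMap

__all__ = [
    "ExtractionSettings",
    "DiscretizedROI",
    "FeatureVector",
    "resample_inplane",
    "discretize_roi",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_gldm",
    "build_ngtdm",
    "firstorder_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "extract_all",
    "feature_manifest",
    "FEATURE_CLASS_COUNTS",
]

FEATURE_CLASS_COUNTS = {
    "firstorder": 18, "glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5,
}

_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))
_NEIGHBOURS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class ExtractionSettings:
    """Settings governing resampling, discretization and matrix construction.

    ``bin_width`` is in map units; ``bin_width_overrides`` lets individual
    filter versions use a different width (LBP code images default to unit
    bins because their values are small integers).
    """

    bin_width: float = 25.0
    bin_width_overrides: dict = dc_field(default_factory=lambda: {"lbp-2D": 1.0})
    target_spacing: tuple[float, float] = (1.0, 1.0)
    glcm_distance: int = 1
    gldm_alpha: float = 0.0
    filter_settings: FilterSettings = dc_field(default_factory=FilterSettings)

    def bin_width_for(self, filter_label: str) -> float:
        return float(self.bin_width_overrides.get(filter_label, self.bin_width))


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer gray levels (1..n_levels) on the ROI; 0 outside."""

    level_image: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float
    original_values: np.ndarray  # ROI pixel values before discretization

    @property
    def roi_pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def levels(self) -> np.ndarray:
        return self.level_image[self.mask]


@dataclass(frozen=True)
class FeatureVector:
    """1023 named feature values with provenance labels."""

    values: dict
    subject: str = ""
    slice_label: str = ""
    field: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# geometry and discretization


def resample_inplane(pmap: ParametricMap, mask: BinaryMask,
                     target_spacing=(1.0, 1.0)) -> tuple[ParametricMap, BinaryMask]:
    """Resample image (bilinear) and mask (nearest-neighbour) to 1x1 mm."""
    spacing = pmap.pixel_spacing
    if tuple(spacing) == tuple(target_spacing):
        return pmap, mask
    zoom = (spacing[0] / target_spacing[0], spacing[1] / target_spacing[1])
    values = ndimage.zoom(pmap.values, zoom, order=1, mode="nearest")
    grid = ndimage.zoom(mask.grid.astype(np.uint8), zoom, order=0, mode="nearest") > 0
    if grid.shape != values.shape:  # pragma: no cover - zoom uses same rounding
        raise RuntimeError("resampled image and mask shapes diverged")
    if not grid.any():
        raise ValueError("mask is empty after resampling")
    out_map = ParametricMap(values, tuple(target_spacing), pmap.subject,
                            pmap.slice_label, pmap.field)
    return out_map, BinaryMask(grid, tuple(target_spacing))


def discretize_roi(values: np.ndarray, mask: np.ndarray, bin_width: float) -> DiscretizedROI:
    """Fixed-bin-width discretization anchored at the ROI minimum."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    v = np.asarray(values, dtype=float)[mask]
    if not np.isfinite(v).all():
        raise ValueError("non-finite values inside the ROI")
    levels = np.floor((v - v.min()) / bin_width).astype(np.int64) + 1
    level_image = np.zeros(mask.shape, dtype=np.int64)
    level_image[mask] = levels
    return DiscretizedROI(level_image=level_image, mask=mask,
                          n_levels=int(levels.max()), bin_width=float(bin_width),
                          original_values=v)


# ---------------------------------------------------------------------------
# matrix builders


def _shift(arr: np.ndarray, dr: int, dc: int, fill=0) -> np.ndarray:
    """Array shifted so out[r, c] = arr[r + dr, c + dc] (fill outside)."""
    out = np.full_like(arr, fill)
    rows, cols = arr.shape
    rs = slice(max(dr, 0), rows + min(dr, 0))
    cs = slice(max(dc, 0), cols + min(dc, 0))
    rd = slice(max(-dr, 0), rows + min(-dr, 0))
    cd = slice(max(-dc, 0), cols + min(-dc, 0))
    out[rd, cd] = arr[rs, cs]
    return out


def build_glcm(d: DiscretizedROI, distance: int = 1) -> list[np.ndarray]:
    """Per-direction symmetric, normalized co-occurrence matrices.

    Directions with no valid in-ROI pixel pair are dropped with a warning.
    """
    ng = d.n_levels
    lv, mask = d.level_image, d.mask
    matrices = []
    for dr, dc in _DIRECTIONS:
        nl = _shift(lv, dr * distance, dc * distance)
        nm = _shift(mask.astype(np.uint8), dr * distance, dc * distance) > 0
        valid = mask & nm
        if not valid.any():
            warnings.warn("GLCM: direction without valid pairs dropped", RuntimeWarning)
            continue
        a = lv[valid] - 1
        b = nl[valid] - 1
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
        counts = counts + counts.T  # symmetrize
        matrices.append(counts / counts.sum())
    if not matrices:
        raise ValueError("no direction produced a co-occurrence pair")
    return matrices


def _lines(level_image: np.ndarray, direction) -> list[np.ndarray]:
    """Scan lines of the level image along a direction (0 = background)."""
    if direction == (0, 1):
        return [level_image[r] for r in range(level_image.shape[0])]
    if direction == (1, 0):
        return [level_image[:, c] for c in range(level_image.shape[1])]
    if direction == (1, 1):
        src = level_image
    elif direction == (1, -1):
        src = np.fliplr(level_image)
    else:
        raise ValueError(f"unsupported direction {direction}")
    rows, cols = src.shape
    return [np.diagonal(src, offset=o) for o in range(-(rows - 1), cols)]


def _run_lengths(line: np.ndarray):
    """(value, length) for each maximal run of equal nonzero values."""
    if line.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [line.size]))
    for s, e in zip(starts, ends):
        if line[s] != 0:
            yield int(line[s]), int(e - s)


def build_glrlm(d: DiscretizedROI) -> list[np.ndarray]:
    """Per-direction run-length matrices R[level, run length]."""
    ng = d.n_levels
    max_len = max(d.level_image.shape)
    matrices = []
    for direction in _DIRECTIONS:
        mat = np.zeros((ng, max_len), dtype=float)
        for line in _lines(d.level_image, direction):
            for value, length in _run_lengths(np.asarray(line)):
                mat[value - 1, length - 1] += 1
        matrices.append(mat)
    return matrices


def build_glszm(d: DiscretizedROI) -> np.ndarray:
    """Zone matrix S[level, zone size] with 8-connected zones."""
    structure = np.ones((3, 3), dtype=int)
    max_size = d.roi_pixel_count
    mat = np.zeros((d.n_levels, max_size), dtype=float)
    for i in range(1, d.n_levels + 1):
        labelled, n_zones = ndimage.label(d.level_image == i, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        for size, count in zip(*np.unique(sizes, return_counts=True)):
            mat[i - 1, size - 1] += count
    return mat


def build_gldm(d: DiscretizedROI, alpha: float = 0.0) -> np.ndarray:
    """Dependence matrix D[level, dependent-neighbour count].

    Column index j0 = number of 8-neighbours inside the ROI whose level
    differs by at most ``alpha``; the dependence size used in the feature
    formulas is j0 + 1 (centre pixel included).
    """
    lv, mask = d.level_image, d.mask
    dep = np.zeros(lv.shape, dtype=np.int64)
    for dr, dc in _NEIGHBOURS8:
        nl = _shift(lv, dr, dc)
        nm = _shift(mask.astype(np.uint8), dr, dc) > 0
        dep += (mask & nm & (np.abs(nl - lv) <= alpha)).astype(np.int64)
    mat = np.zeros((d.n_levels, 9), dtype=float)
    np.add.at(mat, (lv[mask] - 1, dep[mask]), 1.0)
    return mat


def build_ngtdm(d: DiscretizedROI) -> dict:
    """Level occurrence counts n_i, probabilities p_i and sums s_i of
    absolute deviations from the 8-neighbourhood mean.

    Pixels with no in-ROI neighbour do not contribute.
    """
    lv, mask = d.level_image, d.mask
    nbr_sum = np.zeros(lv.shape, dtype=float)
    nbr_cnt = np.zeros(lv.shape, dtype=np.int64)
    for dr, dc in _NEIGHBOURS8:
        nl = _shift(lv, dr, dc)
        nm = _shift(mask.astype(np.uint8), dr, dc) > 0
        nbr_sum += np.where(mask & nm, nl, 0)
        nbr_cnt += (mask & nm).astype(np.int64)
    valid = mask & (nbr_cnt > 0)
    ng = d.n_levels
    n = np.zeros(ng, dtype=float)
    s = np.zeros(ng, dtype=float)
    idx = lv[valid] - 1
    dev = np.abs(lv[valid] - nbr_sum[valid] / nbr_cnt[valid])
    np.add.at(n, idx, 1.0)
    np.add.at(s, idx, dev)
    total = n.sum()
    p = n / total if total > 0 else n
    return {"n": n, "p": p, "s": s, "n_valid": int(total)}


# ---------------------------------------------------------------------------
# feature formulas


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def firstorder_features(values: np.ndarray, d: DiscretizedROI,
                        pixel_area: float = 1.0) -> dict:
    """18 first-order statistics over the original (undiscretized) ROI values.

    Entropy and Uniformity are the only two computed from the discretized
    histogram; Variance uses the population convention.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    mean = v.mean()
    var = v.var()  # population
    centred = v - mean
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    hist = np.bincount(d.levels, minlength=d.n_levels + 1)[1:].astype(float)
    probs = hist / hist.sum()
    if var > 0:
        skew = (centred ** 3).mean() / var ** 1.5
        kurt = (centred ** 4).mean() / var ** 2
    else:
        skew, kurt = 0.0, 0.0  # constant ROI convention
    energy = float((v ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": pixel_area * energy,
        "Entropy": float(-_xlog2x(probs).sum()),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(centred).mean()),
        "RobustMeanAbsoluteDeviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((v ** 2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float((probs ** 2).sum()),
    }


def _glcm_features_single(p: np.ndarray) -> dict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    ux = float((i * px).sum())
    sigx2 = float(((i - ux) ** 2 * px).sum())
    p_sum = np.zeros(2 * ng + 1)       # index k = i + j, 2..2Ng
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    p_diff = np.zeros(ng)              # index k = |i - j|, 0..Ng-1
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2 * ng + 1)
    k_diff = np.arange(ng)

    joint_entropy = float(-_xlog2x(p).sum())
    hx = float(-_xlog2x(px).sum())
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-_xlog2x(pxpy).sum())

    autocorr = float((ii * jj * p).sum())
    if sigx2 > 0:
        correlation = (autocorr - ux * ux) / sigx2
    else:
        correlation = 1.0  # zero-variance fallback
    diff_avg = float((k_diff * p_diff).sum())

    if hx > 0:
        imc1 = (joint_entropy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(imc2_arg)) if imc2_arg > 0 else 0.0

    # MCC: sqrt of the second-largest eigenvalue of
    # Q(i, j) = sum_k p(i,k) p(j,k) / (px_i py_k), over occurring levels.
    present = px > 0
    if present.sum() > 1:
        psub = p[np.ix_(present, present)]
        pxs = px[present]
        q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(max(eig[-2], 0.0)))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autocorr,
        "JointAverage": ux,
        "ClusterProminence": float((((ii + jj) - 2 * ux) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - 2 * ux) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - 2 * ux) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-_xlog2x(p_diff).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff ** 2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p_diff[1:] / k_diff[1:] ** 2).sum()) if ng > 1 else 0.0,
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-_xlog2x(p_sum).sum()),
        "SumSquares": sigx2,
    }


def _average_dicts(dicts: list[dict]) -> dict:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def glcm_features(matrices: list[np.ndarray]) -> dict:
    """24 co-occurrence features, averaged over the per-direction matrices."""
    return _average_dicts([_glcm_features_single(p) for p in matrices])


def _sized_matrix_features(mat: np.ndarray, n_pixels: int, prefix: str) -> dict:
    """Shared formula core for GLRLM-like matrices M[level, size].

    ``prefix`` selects the family-specific feature names: runs (GLRLM) or
    zones (GLSZM).  ``n_pixels`` is the ROI pixel count for the percentage
    feature.
    """
    total = mat.sum()
    if total == 0:
        raise ValueError("degenerate matrix: no runs/zones")
    p = mat / total
    ng, nl = mat.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nl + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = p.sum(axis=1)   # marginal over sizes
    ps = p.sum(axis=0)   # marginal over levels
    mu_i = float((i * pg).sum())
    mu_j = float((j * ps).sum())
    gln = float((mat.sum(axis=1) ** 2).sum() / total)
    sln = float((mat.sum(axis=0) ** 2).sum() / total)
    base = {
        "GrayLevelNonUniformity": gln,
        "GrayLevelNonUniformityNormalized": gln / total,
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "LowGrayLevel": float((p / ii ** 2).sum()),
        "HighGrayLevel": float((p * ii ** 2).sum()),
        "Small": float((p / jj ** 2).sum()),
        "Large": float((p * jj ** 2).sum()),
        "SmallLow": float((p / (ii ** 2 * jj ** 2)).sum()),
        "SmallHigh": float((p * ii ** 2 / jj ** 2).sum()),
        "LargeLow": float((p * jj ** 2 / ii ** 2).sum()),
        "LargeHigh": float((p * ii ** 2 * jj ** 2).sum()),
        "SizeNonUniformity": sln,
        "SizeNonUniformityNormalized": sln / total,
        "SizeVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "Entropy": float(-_xlog2x(p).sum()),
        "Percentage": float(total / n_pixels),
    }
    if prefix == "glrlm":
        names = {
            "GrayLevelNonUniformity": "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
            "GrayLevelVariance": "GrayLevelVariance",
            "LowGrayLevel": "LowGrayLevelRunEmphasis",
            "HighGrayLevel": "HighGrayLevelRunEmphasis",
            "Small": "ShortRunEmphasis",
            "Large": "LongRunEmphasis",
            "SmallLow": "ShortRunLowGrayLevelEmphasis",
            "SmallHigh": "ShortRunHighGrayLevelEmphasis",
            "LargeLow": "LongRunLowGrayLevelEmphasis",
            "LargeHigh": "LongRunHighGrayLevelEmphasis",
            "SizeNonUniformity": "RunLengthNonUniformity",
            "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
            "SizeVariance": "RunVariance",
            "Entropy": "RunEntropy",
            "Percentage": "RunPercentage",
        }
    else:  # glszm
        names = {
            "GrayLevelNonUniformity": "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
            "GrayLevelVariance": "GrayLevelVariance",
            "LowGrayLevel": "LowGrayLevelZoneEmphasis",
            "HighGrayLevel": "HighGrayLevelZoneEmphasis",
            "Small": "SmallAreaEmphasis",
            "Large": "LargeAreaEmphasis",
            "SmallLow": "SmallAreaLowGrayLevelEmphasis",
            "SmallHigh": "SmallAreaHighGrayLevelEmphasis",
            "LargeLow": "LargeAreaLowGrayLevelEmphasis",
            "LargeHigh": "LargeAreaHighGrayLevelEmphasis",
            "SizeNonUniformity": "SizeZoneNonUniformity",
            "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
            "SizeVariance": "ZoneVariance",
            "Entropy": "ZoneEntropy",
            "Percentage": "ZonePercentage",
        }
    return {names[k]: v for k, v in base.items()}


def glrlm_features(matrices: list[np.ndarray], n_pixels: int) -> dict:
    """16 run-length features, averaged over the four directions."""
    return _average_dicts(
        [_sized_matrix_features(m, n_pixels, "glrlm") for m in matrices])


def glszm_features(matrix: np.ndarray, n_pixels: int) -> dict:
    """16 size-zone features (single 8-connected zone matrix)."""
    return _sized_matrix_features(matrix, n_pixels, "glszm")


def gldm_features(matrix: np.ndarray) -> dict:
    """14 dependence features; dependence size j = dependent neighbours + 1."""
    total = matrix.sum()
    if total == 0:
        raise ValueError("degenerate dependence matrix")
    p = matrix / total
    ng, nd = matrix.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nd + 1)  # column 0 holds pixels with no dependent neighbour
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = p.sum(axis=1)
    pd_ = p.sum(axis=0)
    mu_i = float((i * pg).sum())
    mu_j = float((j * pd_).sum())
    gln = float((matrix.sum(axis=1) ** 2).sum() / total)
    dn = float((matrix.sum(axis=0) ** 2).sum() / total)
    return {
        "SmallDependenceEmphasis": float((p / jj ** 2).sum()),
        "LargeDependenceEmphasis": float((p * jj ** 2).sum()),
        "GrayLevelNonUniformity": gln,
        "DependenceNonUniformity": dn,
        "DependenceNonUniformityNormalized": dn / total,
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "DependenceVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-_xlog2x(p).sum()),
        "LowGrayLevelEmphasis": float((p / ii ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * ii ** 2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (ii ** 2 * jj ** 2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * ii ** 2 / jj ** 2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * jj ** 2 / ii ** 2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * ii ** 2 * jj ** 2).sum()),
    }


def ngtdm_features(stats: dict) -> dict:
    """5 neighbourhood gray-tone-difference features."""
    n, p, s = stats["n"], stats["p"], stats["s"]
    n_valid = stats["n_valid"]
    if n_valid == 0:
        raise ValueError("NGTDM: no pixel with a valid neighbour")
    ng = len(p)
    i = np.arange(1, ng + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s[present]

    denom_coarse = float((pp * sp).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = (pij * di ** 2).sum() / (ngp * (ngp - 1)) * (s.sum() / n_valid)
        busy_denom = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum()
        busyness = denom_coarse / busy_denom if busy_denom > 0 else 0.0
        psi = pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        complexity = (np.abs(di) * psi / (pp[:, None] + pp[None, :])).sum() / n_valid
        strength = float(((pp[:, None] + pp[None, :]) * di ** 2).sum())
        s_total = s.sum()
        strength = strength / s_total if s_total > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# full extraction


def features_for_image(values: np.ndarray, mask: np.ndarray,
                       settings: ExtractionSettings, bin_width: float,
                       pixel_area: float = 1.0) -> dict:
    """The 93 features of one image version within the ROI."""
    d = discretize_roi(values, mask, bin_width)
    out = {}
    for name, val in firstorder_features(d.original_values, d, pixel_area).items():
        out[f"firstorder_{name}"] = val
    for name, val in glcm_features(build_glcm(d, settings.glcm_distance)).items():
        out[f"glcm_{name}"] = val
    for name, val in glrlm_features(build_glrlm(d), d.roi_pixel_count).items():
        out[f"glrlm_{name}"] = val
    for name, val in glszm_features(build_glszm(d), d.roi_pixel_count).items():
        out[f"glszm_{name}"] = val
    for name, val in gldm_features(build_gldm(d, settings.gldm_alpha)).items():
        out[f"gldm_{name}"] = val
    for name, val in ngtdm_features(build_ngtdm(d)).items():
        out[f"ngtdm_{name}"] = val
    assert len(out) == 93
    return out


def extract_all(pmap: ParametricMap, mask: BinaryMask,
                settings: ExtractionSettings | None = None) -> FeatureVector:
    """Resample, filter, discretize and compute all 1023 named features."""
    settings = settings or ExtractionSettings()
    pmap, mask = resample_inplane(pmap, mask, settings.target_spacing)
    pixel_area = settings.target_spacing[0] * settings.target_spacing[1]
    stack = build_stack(pmap.values, settings.filter_settings, pmap.pixel_spacing)
    values: dict[str, float] = {}
    for label, image in stack.items():
        feats = features_for_image(image, mask.grid, settings,
                                   settings.bin_width_for(label), pixel_area)
        for name, val in feats.items():
            values[f"{label}_{name}"] = val
    assert len(values) == 1023
    return FeatureVector(values=values, subject=pmap.subject,
                         slice_label=pmap.slice_label, field=pmap.field)


def feature_manifest() -> dict:
    """Canonical feature names per class and the 1023 full names."""
    with resources.files("rtfpipe").joinpath("feature_manifest.json").open() as fh:
        return json.load(fh)
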