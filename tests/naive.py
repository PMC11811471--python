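"""Definition-literal brute-force oracles for the texture engine.

Everything here is written as explicit per-pixel / per-entry loops straight
from the definitional formulas, deliberately ignoring vectorization, so it
can serve as an independent check of the production implementations.  The
conventions mirror the ones documented in rtfpipe.texture_features:
floor discretization anchored at the ROI minimum, 4 in-plane directions,
8-connectivity, dependence size = dependent neighbours + 1, NGTDM pixels
without valid neighbours excluded, 0*log(0) = 0.
"""

import math

import numpy as np

DIRECTIONS = [(0, 1), (1, 0), (1, 1), (1, -1)]
NEIGHBOURS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _inside(shape, r, c):
    return 0 <= r < shape[0] and 0 <= c < shape[1]


# ---------------------------------------------------------------------------
# matrices


def naive_glcm(level_img, mask, ng, direction):
    """Symmetric normalized co-occurrence counts for one direction, or None."""
    dr, dc = direction
    counts = np.zeros((ng, ng))
    rows, cols = level_img.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            r2, c2 = r + dr, c + dc
            if _inside(level_img.shape, r2, c2) and mask[r2, c2]:
                counts[level_img[r, c] - 1, level_img[r2, c2] - 1] += 1
                counts[level_img[r2, c2] - 1, level_img[r, c] - 1] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def naive_glrlm(level_img, mask, ng, direction):
    """Run-length counts for one direction by walking each maximal run."""
    dr, dc = direction
    rows, cols = level_img.shape
    max_len = max(rows, cols)
    mat = np.zeros((ng, max_len))
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            pr, pc = r - dr, c - dc
            if (_inside(level_img.shape, pr, pc) and mask[pr, pc]
                    and level_img[pr, pc] == level_img[r, c]):
                continue  # not the start of a run
            length = 1
            nr, nc = r + dr, c + dc
            while (_inside(level_img.shape, nr, nc) and mask[nr, nc]
                   and level_img[nr, nc] == level_img[r, c]):
                length += 1
                nr, nc = nr + dr, nc + dc
            mat[level_img[r, c] - 1, length - 1] += 1
    return mat


def naive_glszm(level_img, mask, ng):
    """Zone counts via explicit 8-connected flood fill."""
    rows, cols = level_img.shape
    visited = np.zeros_like(mask, dtype=bool)
    mat = np.zeros((ng, int(mask.sum())))
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or visited[r, c]:
                continue
            level = level_img[r, c]
            stack = [(r, c)]
            visited[r, c] = True
            size = 0
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGHBOURS8:
                    nr, nc = cr + dr, cc + dc
                    if (_inside(level_img.shape, nr, nc) and mask[nr, nc]
                            and not visited[nr, nc] and level_img[nr, nc] == level):
                        visited[nr, nc] = True
                        stack.append((nr, nc))
            mat[level - 1, size - 1] += 1
    return mat


def naive_gldm(level_img, mask, ng, alpha=0.0):
    """Dependence counts: column index = number of dependent 8-neighbours."""
    mat = np.zeros((ng, 9))
    rows, cols = level_img.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            dep = 0
            for dr, dc in NEIGHBOURS8:
                nr, nc = r + dr, c + dc
                if (_inside(level_img.shape, nr, nc) and mask[nr, nc]
                        and abs(int(level_img[nr, nc]) - int(level_img[r, c])) <= alpha):
                    dep += 1
            mat[level_img[r, c] - 1, dep] += 1
    return mat


def naive_ngtdm(level_img, mask, ng):
    """Occurrence counts, probabilities and neighbourhood-deviation sums."""
    n = np.zeros(ng)
    s = np.zeros(ng)
    rows, cols = level_img.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            nb = [level_img[r + dr, c + dc] for dr, dc in NEIGHBOURS8
                  if _inside(level_img.shape, r + dr, c + dc) and mask[r + dr, c + dc]]
            if not nb:
                continue
            i = level_img[r, c] - 1
            n[i] += 1
            s[i] += abs(level_img[r, c] - sum(nb) / len(nb))
    total = n.sum()
    p = n / total if total > 0 else n
    return {"n": n, "p": p, "s": s, "n_valid": int(total)}


# ---------------------------------------------------------------------------
# first-order statistics


def naive_firstorder(values, levels, n_levels, pixel_area=1.0):
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    energy = sum(x * x for x in v)

    def percentile(q):
        return float(np.percentile(np.array(v), q))

    p10, p25, p75, p90 = (percentile(q) for q in (10, 25, 75, 90))
    robust = [x for x in v if p10 <= x <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    counts = [0] * n_levels
    for lv in levels:
        counts[lv - 1] += 1
    probs = [cnt / n for cnt in counts]
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    if var > 0:
        skew = (sum((x - mean) ** 3 for x in v) / n) / var ** 1.5
        kurt = (sum((x - mean) ** 4 for x in v) / n) / var ** 2
    else:
        skew = kurt = 0.0
    return {
        "Energy": energy,
        "TotalEnergy": pixel_area * energy,
        "Entropy": entropy,
        "Minimum": v[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": v[-1],
        "Mean": mean,
        "Median": percentile(50),
        "InterquartileRange": p75 - p25,
        "Range": v[-1] - v[0],
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
        "RobustMeanAbsoluteDeviation":
            sum(abs(x - rmean) for x in robust) / len(robust) if robust else 0.0,
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }


# ---------------------------------------------------------------------------
# matrix-family features


def naive_glcm_features(p):
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    sigx2 = sum((i + 1 - ux) ** 2 * px[i] for i in range(ng))
    p_sum = [0.0] * (2 * ng + 1)
    p_diff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            p_sum[(i + 1) + (j + 1)] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]
    autocorr = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    joint_entropy = -sum(p[i][j] * math.log2(p[i][j])
                         for i in range(ng) for j in range(ng) if p[i][j] > 0)
    hx = -sum(q * math.log2(q) for q in px if q > 0)
    hxy1 = -sum(p[i][j] * math.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng)
                if p[i][j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng) if px[i] * px[j] > 0)
    diff_avg = sum(k * p_diff[k] for k in range(ng))

    if sigx2 > 0:
        correlation = (autocorr - ux * ux) / sigx2
    else:
        correlation = 1.0
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0
    imc2_arg = 1.0 - math.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = math.sqrt(imc2_arg) if imc2_arg > 0 else 0.0

    present = [i for i in range(ng) if px[i] > 0]
    if len(present) > 1:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(p[i][k] * p[j][k] / (px[i] * px[k])
                              for k in present)
        eig = sorted(np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(eig[-2], 0.0))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autocorr,
        "JointAverage": ux,
        "ClusterProminence": sum(((i + 1) + (j + 1) - 2 * ux) ** 4 * p[i][j]
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum(((i + 1) + (j + 1) - 2 * ux) ** 3 * p[i][j]
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum(((i + 1) + (j + 1) - 2 * ux) ** 2 * p[i][j]
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": -sum(q * math.log2(q) for q in p_diff if q > 0),
        "DifferenceVariance": sum((k - diff_avg) ** 2 * p_diff[k] for k in range(ng)),
        "Id": sum(p_diff[k] / (1.0 + k) for k in range(ng)),
        "Idm": sum(p_diff[k] / (1.0 + k * k) for k in range(ng)),
        "Idmn": sum(p_diff[k] / (1.0 + (k / ng) ** 2) for k in range(ng)),
        "Idn": sum(p_diff[k] / (1.0 + k / ng) for k in range(ng)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(p_diff[k] / k ** 2 for k in range(1, ng)),
        "JointEnergy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": max(p[i][j] for i in range(ng) for j in range(ng)),
        "SumAverage": sum(k * p_sum[k] for k in range(2 * ng + 1)),
        "SumEntropy": -sum(q * math.log2(q) for q in p_sum if q > 0),
        "SumSquares": sigx2,
    }


def _naive_sized_features(mat, n_pixels, names):
    total = mat.sum()
    ng, nl = mat.shape
    p = mat / total
    mu_i = sum((i + 1) * p[i][j] for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * p[i][j] for i in range(ng) for j in range(nl))
    gln = sum(sum(mat[i]) ** 2 for i in range(ng)) / total
    sln = sum(sum(mat[i][j] for i in range(ng)) ** 2 for j in range(nl)) / total
    vals = {
        "GrayLevelNonUniformity": gln,
        "GrayLevelNonUniformityNormalized": gln / total,
        "GrayLevelVariance": sum((i + 1 - mu_i) ** 2 * p[i][j]
                                 for i in range(ng) for j in range(nl)),
        "LowGrayLevel": sum(p[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nl)),
        "HighGrayLevel": sum(p[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nl)),
        "Small": sum(p[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nl)),
        "Large": sum(p[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nl)),
        "SmallLow": sum(p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
                        for i in range(ng) for j in range(nl)),
        "SmallHigh": sum(p[i][j] * (i + 1) ** 2 / (j + 1) ** 2
                         for i in range(ng) for j in range(nl)),
        "LargeLow": sum(p[i][j] * (j + 1) ** 2 / (i + 1) ** 2
                        for i in range(ng) for j in range(nl)),
        "LargeHigh": sum(p[i][j] * (i + 1) ** 2 * (j + 1) ** 2
                         for i in range(ng) for j in range(nl)),
        "SizeNonUniformity": sln,
        "SizeNonUniformityNormalized": sln / total,
        "SizeVariance": sum((j + 1 - mu_j) ** 2 * p[i][j]
                            for i in range(ng) for j in range(nl)),
        "Entropy": -sum(p[i][j] * math.log2(p[i][j])
                        for i in range(ng) for j in range(nl) if p[i][j] > 0),
        "Percentage": total / n_pixels,
    }
    return {names[k]: v for k, v in vals.items()}


GLRLM_NAMES = {
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

GLSZM_NAMES = {
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


def naive_glrlm_features(mat, n_pixels):
    return _naive_sized_features(mat, n_pixels, GLRLM_NAMES)


def naive_glszm_features(mat, n_pixels):
    return _naive_sized_features(mat, n_pixels, GLSZM_NAMES)


def naive_gldm_features(mat):
    total = mat.sum()
    ng, nd = mat.shape
    p = mat / total
    mu_i = sum((i + 1) * p[i][j] for i in range(ng) for j in range(nd))
    mu_j = sum((j + 1) * p[i][j] for i in range(ng) for j in range(nd))
    gln = sum(sum(mat[i]) ** 2 for i in range(ng)) / total
    dn = sum(sum(mat[i][j] for i in range(ng)) ** 2 for j in range(nd)) / total
    return {
        "SmallDependenceEmphasis": sum(p[i][j] / (j + 1) ** 2
                                       for i in range(ng) for j in range(nd)),
        "LargeDependenceEmphasis": sum(p[i][j] * (j + 1) ** 2
                                       for i in range(ng) for j in range(nd)),
        "GrayLevelNonUniformity": gln,
        "DependenceNonUniformity": dn,
        "DependenceNonUniformityNormalized": dn / total,
        "GrayLevelVariance": sum((i + 1 - mu_i) ** 2 * p[i][j]
                                 for i in range(ng) for j in range(nd)),
        "DependenceVariance": sum((j + 1 - mu_j) ** 2 * p[i][j]
                                  for i in range(ng) for j in range(nd)),
        "DependenceEntropy": -sum(p[i][j] * math.log2(p[i][j])
                                  for i in range(ng) for j in range(nd) if p[i][j] > 0),
        "LowGrayLevelEmphasis": sum(p[i][j] / (i + 1) ** 2
                                    for i in range(ng) for j in range(nd)),
        "HighGrayLevelEmphasis": sum(p[i][j] * (i + 1) ** 2
                                     for i in range(ng) for j in range(nd)),
        "SmallDependenceLowGrayLevelEmphasis":
            sum(p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
                for i in range(ng) for j in range(nd)),
        "SmallDependenceHighGrayLevelEmphasis":
            sum(p[i][j] * (i + 1) ** 2 / (j + 1) ** 2
                for i in range(ng) for j in range(nd)),
        "LargeDependenceLowGrayLevelEmphasis":
            sum(p[i][j] * (j + 1) ** 2 / (i + 1) ** 2
                for i in range(ng) for j in range(nd)),
        "LargeDependenceHighGrayLevelEmphasis":
            sum(p[i][j] * (i + 1) ** 2 * (j + 1) ** 2
                for i in range(ng) for j in range(nd)),
    }


def naive_ngtdm_features(stats):
    n, p, s = stats["n"], stats["p"], stats["s"]
    n_valid = stats["n_valid"]
    present = [i for i in range(len(p)) if p[i] > 0]
    ngp = len(present)
    denom_coarse = sum(p[i] * s[i] for i in present)
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6
    if ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2
                        for i in present for j in present)
                    / (ngp * (ngp - 1))) * (sum(s) / n_valid)
        busy_denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                         for i in present for j in present)
        busyness = denom_coarse / busy_denom if busy_denom > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                         for i in present for j in present) / n_valid
        s_total = sum(s)
        strength = (sum((p[i] + p[j]) * (i - j) ** 2
                        for i in present for j in present) / s_total
                    if s_total > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# two-way ANOVA


def naive_mean_squares(table):
    """Sums of squares by definition-literal double loops."""
    arr = np.asarray(table, dtype=float)
    n, k = arr.shape
    grand = sum(arr[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(arr[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(arr[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = sum((arr[i][j] - row_means[i] - col_means[j] + grand) ** 2
                 for i in range(n) for j in range(k))
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))
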