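"""Two-way ANOVA intraclass correlation estimation and categorization.

The reliability index is the proportion of total measurement variance
attributable to true between-target differences.  Four two-way models are
supported, in Shrout–Fleiss / McGraw–Wong notation:

* ICC(2,1) — two-way random effects, absolute agreement, single rater
  (repeatability across segmentation runs),
* ICC(3,1) — two-way mixed effects, consistency, single rater
  (reproducibility across field strengths),
* ICC(2,k) / ICC(3,k) — the corresponding reliabilities of k-averaged
  measurements.

Point estimates and 95% confidence intervals use the standard F-based
constructions from the two-way mean squares (targets MSR, raters MSC,
residual MSE).  Estimates are categorized as excellent (ICC >= 0.95), good
(0.95 > ICC >= 0.75), moderate (0.75 > ICC >= 0.5) or poor (ICC < 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = [
    "ICCEstimate",
    "DegenerateTableError",
    "two_way_mean_squares",
    "icc",
    "categorize",
    "icc_per_feature",
    "screen_degenerate",
    "breakdown",
    "MODELS",
    "CATEGORIES",
]

MODELS = ("ICC(2,1)", "ICC(3,1)", "ICC(2,k)", "ICC(3,k)")
CATEGORIES = ("excellent", "good", "moderate", "poor")


class DegenerateTableError(ValueError):
    """All-constant (or otherwise degenerate) table: ICC undefined."""


@dataclass(frozen=True)
class ICCEstimate:
    model: str
    value: float
    ci95: tuple[float, float]
    category: str
    n: int
    k: int


def _as_table(table) -> np.ndarray:
    """Coerce a wide n x k layout (targets x raters) to a float array."""
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("measurement table must be 2-D (targets x raters)")
    if np.isnan(arr).any():
        raise ValueError("incomplete table: missing values")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    return arr


def two_way_mean_squares(table) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way crossed layout without replication.

    Satisfies the decomposition total SS = row SS + column SS + error SS.
    """
    arr = _as_table(table)
    n, k = arr.shape
    if np.ptp(arr, axis=1).max() == 0:
        # exact agreement between raters: rater and error SS vanish identically
        row = arr[:, 0]
        msr = k * ((row - row.mean()) ** 2).sum() / (n - 1)
        return float(msr), 0.0, 0.0
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    # residual form avoids the catastrophic cancellation of total-minus-parts
    resid = arr - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def categorize(value: float) -> str:
    """Four-tier reliability category (negative estimates are poor)."""
    if value >= 0.95:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.5:
        return "moderate"
    return "poor"


def icc(table, model: str = "ICC(2,1)", alpha: float = 0.05) -> ICCEstimate:
    """ICC point estimate with F-based 95% CI for one two-way model.

    Negative point estimates are reported as computed (categorized poor);
    CI upper bounds are truncated to <= 1.  An all-constant table raises
    :class:`DegenerateTableError` so callers exclude the feature rather than
    propagate an undefined number.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    arr = _as_table(table)
    n, k = arr.shape
    msr, msc, mse = two_way_mean_squares(arr)
    if msr <= 0 and mse <= 0:
        raise DegenerateTableError("constant table: ICC undefined")
    with np.errstate(all="ignore"):
        return _icc_from_mean_squares(model, msr, msc, mse, n, k, alpha)


def _icc_from_mean_squares(model, msr, msc, mse, n, k, alpha):

    df_err = (n - 1) * (k - 1)
    q = f_dist.ppf(1 - alpha / 2, n - 1, df_err)
    q_rev = f_dist.ppf(1 - alpha / 2, df_err, n - 1)

    if model in ("ICC(3,1)", "ICC(3,k)"):
        denom = msr + (k - 1) * mse
        if denom <= 0 or msr <= 0:
            raise DegenerateTableError("zero denominator in consistency model")
        value31 = (msr - mse) / denom
        if mse == 0:
            lo31, hi31 = 1.0, 1.0
        else:
            fstat = msr / mse
            fl = fstat / q
            fu = fstat * q_rev
            lo31 = (fl - 1) / (fl + (k - 1))
            hi31 = (fu - 1) / (fu + (k - 1))
        if model == "ICC(3,1)":
            value, lo, hi = value31, lo31, hi31
        else:
            value = (msr - mse) / msr
            lo = 1 - 1 / (msr / mse / q) if mse > 0 else 1.0
            hi = 1 - 1 / (msr / mse * q_rev) if mse > 0 else 1.0
    else:
        denom21 = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom21 <= 0:
            raise DegenerateTableError("zero denominator in agreement model")
        icc21 = (msr - mse) / denom21
        if mse == 0 and msc == 0:
            lo21, hi21 = 1.0, 1.0
        else:
            # Satterthwaite df for the agreement-model interval
            fj = msc / mse if mse > 0 else np.inf
            a = k * icc21 * fj + n * (1 + (k - 1) * icc21) - k * icc21
            if np.isfinite(a):
                v = df_err * a ** 2 / (
                    (n - 1) * k ** 2 * icc21 ** 2 * fj ** 2
                    + (n * (1 + (k - 1) * icc21) - k * icc21) ** 2)
            else:
                v = n - 1
            f2u = f_dist.ppf(1 - alpha / 2, n - 1, v)
            f2l = f_dist.ppf(1 - alpha / 2, v, n - 1)
            lo21 = n * (msr - f2u * mse) / (
                f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi21 = n * (f2l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2l * msr)
        if model == "ICC(2,1)":
            value, lo, hi = icc21, lo21, hi21
        else:  # ICC(2,k): Spearman-Brown step-up of the single-rater bounds
            denom2k = msr + (msc - mse) / n
            if denom2k <= 0:
                raise DegenerateTableError("zero denominator in agreement model")
            value = (msr - mse) / denom2k
            lo = lo21 * k / (1 + lo21 * (k - 1))
            hi = hi21 * k / (1 + hi21 * (k - 1))

    # The Satterthwaite df can degenerate for strongly negative estimates
    # (msr << mse): fall back to the widest admissible bounds there.
    value = float(value)
    lo = float(lo) if np.isfinite(lo) else -1.0
    hi = float(hi) if np.isfinite(hi) else 1.0
    hi = min(max(hi, value), 1.0)
    lo = min(lo, value)
    return ICCEstimate(model=model, value=value, ci95=(lo, hi),
                       category=categorize(value), n=n, k=k)


# ---------------------------------------------------------------------------
# feature-table level operations


def screen_degenerate(long_table: pd.DataFrame, value_col: str = "value",
                      feature_col: str = "feature") -> tuple[list, pd.DataFrame]:
    """Exclude features that are constant or non-finite across *all* observations.

    Returns (kept feature names, exclusion log with columns feature/reason).
    Screening is global — applied once across every run, field and target —
    so a single exclusion governs all downstream analyses.
    """
    exclusions = []
    kept = []
    for feat, grp in long_table.groupby(feature_col, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            exclusions.append((feat, "non-finite values"))
        elif np.ptp(vals) == 0:
            exclusions.append((feat, "zero variance"))
        else:
            kept.append(feat)
    log = pd.DataFrame(exclusions, columns=["feature", "reason"])
    return kept, log


def icc_per_feature(long_table: pd.DataFrame, model: str,
                    target_col: str = "target", rater_col: str = "rater",
                    value_col: str = "value",
                    feature_col: str = "feature") -> pd.DataFrame:
    """Per-feature ICC estimates from a long (target, rater, feature, value) table.

    Features whose table is degenerate are reported with NaN estimate and
    category ``degenerate`` (callers normally screen these out beforehand).
    """
    rows = []
    for feat, grp in long_table.groupby(feature_col, sort=True):
        wide = grp.pivot(index=target_col, columns=rater_col, values=value_col)
        try:
            est = icc(wide, model)
            rows.append((feat, model, est.value, est.ci95[0], est.ci95[1],
                         est.category, est.n, est.k))
        except DegenerateTableError:
            rows.append((feat, model, np.nan, np.nan, np.nan, "degenerate",
                         wide.shape[0], wide.shape[1]))
    return pd.DataFrame(rows, columns=["feature", "model", "icc", "ci_lo",
                                       "ci_hi", "category", "n", "k"])


def _filter_class(feature_name: str) -> str:
    return feature_name.split("_")[0]


def _feature_class(feature_name: str) -> str:
    return feature_name.split("_")[1]


def breakdown(estimates: pd.DataFrame, group_axis: str = "overall") -> pd.DataFrame:
    """Count/proportion of features per category, grouped by filter class,
    feature class, or overall.  Proportions sum to 1 within each group."""
    est = estimates[estimates["category"].isin(CATEGORIES)].copy()
    if group_axis == "filter class":
        est["group"] = est["feature"].map(_filter_class)
    elif group_axis == "feature class":
        est["group"] = est["feature"].map(_feature_class)
    elif group_axis == "overall":
        est["group"] = "overall"
    else:
        raise ValueError("group_axis must be 'filter class', 'feature class' "
                         "or 'overall'")
    rows = []
    for group, grp in est.groupby("group", sort=True):
        total = len(grp)
        for cat in CATEGORIES:
            count = int((grp["category"] == cat).sum())
            rows.append((group, cat, count, count / total))
    return pd.DataFrame(rows, columns=["group", "category", "count", "proportion"])


def top_feature_per_filter(estimates: pd.DataFrame) -> pd.DataFrame:
    """Most reliable feature in each filter class (highest point estimate)."""
    est = estimates.dropna(subset=["icc"]).copy()
    est["filter"] = est["feature"].map(_filter_class)
    idx = est.groupby("filter")["icc"].idxmax()
    out = est.loc[idx, ["filter", "feature", "icc", "ci_lo", "ci_hi", "category"]]
    return out.sort_values("icc", ascending=False).reset_index(drop=True)
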