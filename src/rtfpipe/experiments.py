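"""Study orchestration: repeatability, reproducibility and the level sweep.

Three analyses mirror the study design:

* repeatability — per field strength, three segmentation masks per map
  (perturbed at a given level, or the reference replicated at level 0),
  per-feature ICC(2,1) over the (subject-slice) x (run) tables;
* reproducibility — per-feature ICC(3,1) over the (subject-slice) x (field)
  tables, using one segmentation per map;
* perturbation sweep — both of the above ingredients per perturbation level
  on the grid 0..0.3 step 0.02: the dataset-mean IoU decomposition of the
  mask triplets and the per-category proportions of kept features.

Seeds for mask perturbation derive from (master_seed, map index, run index)
only — not the level — so levels share common random numbers and level
comparisons are not washed out by Monte Carlo noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import IoUDecomposition, decompose_triplet, mean_decomposition
from .reliability import breakdown, icc_per_feature, screen_degenerate, top_feature_per_filter
from .synthetic_cohort import (Cohort, CohortRecord, perturb_triplet)
from .texture_features import ExtractionSettings, extract_all

__all__ = [
    "DEFAULT_LEVEL_GRID",
    "RepeatabilityResult",
    "ReproducibilityResult",
    "run_repeatability",
    "run_reproducibility",
    "run_dp_sweep",
    "write_report",
]

DEFAULT_LEVEL_GRID = tuple(np.round(np.arange(0, 0.301, 0.02), 2))


def _triplet_seeds(master_seed: int, map_index: int) -> list[int]:
    ss = np.random.SeedSequence((master_seed, map_index, 7))
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]


def _target_id(rec: CohortRecord) -> str:
    return f"{rec.subject}:{rec.slice_label}"


def _long_table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["target", "rater", "feature", "value"])


@dataclass(frozen=True)
class RepeatabilityResult:
    field: str
    level: float
    estimates: pd.DataFrame
    exclusions: pd.DataFrame
    mean_iou: IoUDecomposition
    filter_breakdown: pd.DataFrame
    feature_breakdown: pd.DataFrame
    overall_breakdown: pd.DataFrame


@dataclass(frozen=True)
class ReproducibilityResult:
    estimates: pd.DataFrame
    exclusions: pd.DataFrame
    filter_breakdown: pd.DataFrame
    feature_breakdown: pd.DataFrame
    overall_breakdown: pd.DataFrame
    top_features: pd.DataFrame


def _extract_run_table(records, level: float, settings: ExtractionSettings,
                       master_seed: int, n_runs: int = 3):
    """Per-run feature extraction for every map; returns (long rows, IoU decs)."""
    rows, decs = [], []
    for mi, rec in enumerate(records):
        if level == 0.0:
            masks = [rec.reference_mask] * n_runs
        else:
            masks = perturb_triplet(rec.reference_mask, level,
                                    _triplet_seeds(master_seed, mi))
        decs.append(decompose_triplet(masks))
        target = _target_id(rec)
        for ri, mask in enumerate(masks):
            fv = extract_all(rec.map, mask, settings)
            rows.extend((target, f"run{ri + 1}", name, val)
                        for name, val in fv.values.items())
    return rows, decs


def run_repeatability(cohort: Cohort, level: float = 0.0, field: str | None = None,
                      n_runs: int = 3,
                      settings: ExtractionSettings | None = None,
                      master_seed: int | None = None) -> RepeatabilityResult:
    """Segmentation-run repeatability: per-feature ICC(2,1) at one level.

    At level 0 the three runs are the reference mask itself, so every kept
    feature has zero within-target variance and ICC exactly 1.
    """
    settings = settings or ExtractionSettings()
    if master_seed is None:
        master_seed = cohort.config.master_seed
    records = cohort.select(field=field)
    if field is None:
        field = "all"
    if len({_target_id(r) for r in records}) < 2:
        raise ValueError("repeatability needs at least 2 targets")
    rows, decs = _extract_run_table(records, level, settings, master_seed, n_runs)
    table = _long_table(rows)
    kept, exclusions = screen_degenerate(table)
    table = table[table["feature"].isin(kept)]
    estimates = icc_per_feature(table, "ICC(2,1)")
    return RepeatabilityResult(
        field=field, level=level, estimates=estimates, exclusions=exclusions,
        mean_iou=mean_decomposition(decs),
        filter_breakdown=breakdown(estimates, "filter class"),
        feature_breakdown=breakdown(estimates, "feature class"),
        overall_breakdown=breakdown(estimates, "overall"),
    )


def run_reproducibility(cohort: Cohort,
                        settings: ExtractionSettings | None = None) -> ReproducibilityResult:
    """Field-strength reproducibility: per-feature ICC(3,1) on paired fields.

    Uses the reference segmentation of each map (the single-expert mask)."""
    settings = settings or ExtractionSettings()
    fields = cohort.config.field_labels
    rows = []
    for rec in cohort.records:
        fv = extract_all(rec.map, rec.reference_mask, settings)
        rows.extend((_target_id(rec), rec.field, name, val)
                    for name, val in fv.values.items())
    table = _long_table(rows)
    if table["rater"].nunique() != 2:
        raise ValueError(f"expected two field labels, got {sorted(set(table['rater']))}")
    kept, exclusions = screen_degenerate(table)
    table = table[table["feature"].isin(kept)]
    estimates = icc_per_feature(table, "ICC(3,1)")
    return ReproducibilityResult(
        estimates=estimates, exclusions=exclusions,
        filter_breakdown=breakdown(estimates, "filter class"),
        feature_breakdown=breakdown(estimates, "feature class"),
        overall_breakdown=breakdown(estimates, "overall"),
        top_features=top_feature_per_filter(estimates),
    )


def run_dp_sweep(cohort: Cohort, grid=DEFAULT_LEVEL_GRID, field: str | None = None,
                 settings: ExtractionSettings | None = None,
                 master_seed: int | None = None) -> pd.DataFrame:
    """Mean IoU decomposition and feature-category proportions per level.

    Tidy output: one row per level with columns iou3/iou2/iou1 and
    prop_excellent/good/moderate/poor over kept features.
    """
    if any(not (0.0 <= g <= 0.3) for g in grid):
        raise ValueError("levels must lie in [0, 0.3]")
    rows = []
    for level in grid:
        res = run_repeatability(cohort, level=float(level), field=field,
                                settings=settings, master_seed=master_seed)
        props = {f"prop_{r.category}": r.proportion
                 for r in res.overall_breakdown.itertuples()}
        rows.append({"level": float(level), "iou3": res.mean_iou.iou3,
                     "iou2": res.mean_iou.iou2, "iou1": res.mean_iou.iou1,
                     "n_kept": len(res.estimates), **props})
    return pd.DataFrame(rows)


def write_report(results: dict, out_dir: str | Path, metadata: dict | None = None,
                 figures: bool = False) -> list[Path]:
    """Serialize a results bundle: CSV per table, JSON run metadata.

    ``results`` maps names to DataFrames, RepeatabilityResult or
    ReproducibilityResult objects.  Raises on an empty bundle — a partial
    report is never written.
    """
    if not results:
        raise ValueError("empty results: nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(name: str, df: pd.DataFrame):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)

    for name, res in results.items():
        if isinstance(res, pd.DataFrame):
            _write_df(name, res)
        elif isinstance(res, RepeatabilityResult):
            _write_df(f"{name}_estimates", res.estimates)
            _write_df(f"{name}_exclusions", res.exclusions)
            _write_df(f"{name}_filter_breakdown", res.filter_breakdown)
            _write_df(f"{name}_feature_breakdown", res.feature_breakdown)
            iou = pd.DataFrame([res.mean_iou.as_tuple()], columns=["iou3", "iou2", "iou1"])
            _write_df(f"{name}_mean_iou", iou)
        elif isinstance(res, ReproducibilityResult):
            _write_df(f"{name}_estimates", res.estimates)
            _write_df(f"{name}_exclusions", res.exclusions)
            _write_df(f"{name}_filter_breakdown", res.filter_breakdown)
            _write_df(f"{name}_feature_breakdown", res.feature_breakdown)
            _write_df(f"{name}_top_features", res.top_features)
        else:
            raise TypeError(f"cannot serialize result {name!r} of type {type(res)}")
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata or {}, indent=2, sort_keys=True))
    written.append(meta_path)
    if figures:
        written.extend(_write_figures(results, out))
    return written


def _write_figures(results: dict, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for name, res in results.items():
        if isinstance(res, pd.DataFrame) and {"level", "iou3"} <= set(res.columns):
            fig, ax = plt.subplots(figsize=(7, 4))
            bottom = np.zeros(len(res))
            for comp, color in (("iou3", "#2c7fb8"), ("iou2", "#7fcdbb"), ("iou1", "#edf8b1")):
                ax.bar(res["level"], res[comp], width=0.015, bottom=bottom,
                       color=color, label=comp)
                bottom += res[comp].to_numpy()
            if "prop_excellent" in res.columns:
                ax.plot(res["level"], res["prop_excellent"], "k.-", label="excellent")
            ax.set_xlabel("perturbation level")
            ax.set_ylabel("proportion")
            ax.legend(loc="upper right", fontsize=8)
            path = out / f"{name}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
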