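"""Sweep driver, retention tables and improvement arithmetic.

Reported percentages are rounded half-away-from-zero to one decimal, the
printed precision used throughout the result tables this module emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .core_data import Corpus
from .curation import AugmentSpec, clean_by_score
from .evaluation import PipelineConfig, run_cv
from .labels import get_scheme

__all__ = ["improvement", "retention_table", "SweepGrid", "sweep", "round1"]

DEFAULT_RATIOS: tuple[float | None, ...] = (None, 0.0, 0.2, 0.4, 0.6, 0.8, 0.95)


def round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (38.849... -> 38.8; 0.25 -> 0.3)."""
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


def improvement(best: float, baseline: float, mode: str = "points") -> float:
    """Gain of *best* over *baseline*: percentage points or relative percent."""
    if mode == "points":
        return round1(best - baseline)
    if mode == "relative":
        if baseline == 0:
            raise ValueError("relative improvement undefined for a zero baseline")
        return round1(100.0 * (best - baseline) / baseline)
    raise ValueError(f"unknown mode {mode!r}; expected 'points' or 'relative'")


def retention_table(corpus: Corpus, thresholds=DEFAULT_RATIOS) -> pd.DataFrame:
    """Per-threshold retained-sample counts and binary class breakdown.

    Columns: cleaning_ratio, retained, class 0 (low arousal) and class 1
    (high arousal) counts, percent of the full corpus.
    """
    scheme = get_scheme("binary")
    total = len(corpus.trials)
    rows = []
    for tau in thresholds:
        kept = clean_by_score(list(corpus.trials), tau)
        n_ha = sum(1 for t in kept if scheme.map[t.emotion] == "HA")
        n_la = len(kept) - n_ha
        rows.append(
            {
                "cleaning_ratio": "none" if tau is None else tau,
                "retained": len(kept),
                "class0_la": n_la,
                "class1_ha": n_ha,
                "percent_of_total": round1(100.0 * len(kept) / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepGrid:
    """The experimental grid: cleaning ratios x augmentations x PCA x tasks."""

    cleaning_ratios: tuple[float | None, ...] = DEFAULT_RATIOS
    augmentations: tuple[str, ...] = ("none", "average", "gaussian", "time")
    pca: tuple[bool, ...] = (False, True)
    tasks: tuple[str, ...] = ("binary", "quadrant", "seven")


@dataclass
class SweepResult:
    table: pd.DataFrame
    best_cells: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def sweep(corpus: Corpus, grid: SweepGrid, base_config: PipelineConfig) -> SweepResult:
    """One ``run_cv`` per grid cell; long-format results plus best-cell summary.

    A failing cell is recorded (task, ratio, augment, pca, error) and the
    sweep continues; callers should treat a non-empty failure list as a
    nonzero exit status.
    """
    rows = []
    failures: list[dict] = []
    for task in grid.tasks:
        for aug_kind in grid.augmentations:
            for use_pca in grid.pca:
                for tau in grid.cleaning_ratios:
                    config = replace(
                        base_config,
                        task=task,
                        augment=replace(base_config.augment, kind=aug_kind),
                        cleaning_ratio=tau,
                        pca=use_pca,
                    )
                    cell = {
                        "task": task,
                        "cleaning_ratio": "none" if tau is None else tau,
                        "augment": aug_kind,
                        "pca": use_pca,
                    }
                    try:
                        result = run_cv(corpus, config)
                    except Exception as exc:  # cell failure: record, continue
                        failures.append({**cell, "error": f"{type(exc).__name__}: {exc}"})
                        continue
                    rows.append(
                        {
                            **cell,
                            "mean_acc": 100.0 * result.mean_acc,
                            "sd_acc": 100.0 * result.sd_acc,
                            "mean_f1": 100.0 * result.mean_f1,
                            "sd_f1": 100.0 * result.sd_f1,
                            "ci95_acc": 100.0 * result.ci95_acc,
                            "ci95_f1": 100.0 * result.ci95_f1,
                        }
                    )
    table = pd.DataFrame(rows)

    best_rows = []
    if not table.empty:
        for task, sub in table.groupby("task"):
            baseline_rows = sub[(sub["augment"] == "none") & (~sub["pca"].astype(bool))]
            baseline_rows = baseline_rows[baseline_rows["cleaning_ratio"] == "none"]
            if baseline_rows.empty:  # fall back to the weakest-curation cell present
                baseline_rows = sub.iloc[[0]]
            baseline_f1 = float(baseline_rows["mean_f1"].iloc[0])
            best = sub.loc[sub["mean_f1"].idxmax()]
            best_rows.append(
                {
                    "task": task,
                    "best_f1": round1(float(best["mean_f1"])),
                    "best_cleaning_ratio": best["cleaning_ratio"],
                    "best_augment": best["augment"],
                    "best_pca": bool(best["pca"]),
                    "baseline_f1": round1(baseline_f1),
                    "relative_improvement": improvement(
                        float(best["mean_f1"]), baseline_f1, "relative"
                    ),
                }
            )
    return SweepResult(table=table, best_cells=pd.DataFrame(best_rows), failures=failures)
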