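"""Correlation assessment of predicted vs reference BMD.

Reports the sample Pearson correlation between model predictions and the
DXA reference, pooled over all (case, vertebral level) samples and
stratified by level (T12..S1).  The "excluding L1" target variants drop
L1-level rows from the pooled estimate while still reporting the L1 stratum
itself, so both the per-level and the excl-L1 readings are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .roi import DegenerateInputError

__all__ = [
    "VERTEBRA_LEVELS",
    "TARGET_COLUMNS",
    "TargetResult",
    "EvaluationReport",
    "pearson_r",
    "spearman_r",
    "evaluate_predictions",
]

VERTEBRA_LEVELS = ("T12", "L1", "L2", "L3", "L4", "L5", "S1")

# target name -> (reference column, drop L1 rows from the pooled estimate?)
TARGET_COLUMNS = {
    "lumbar_total": ("lumbar_total", False),
    "lumbar_total_excl_L1": ("lumbar_total", True),
    "hip_total": ("hip_total", False),
}

_MIN_N = 3


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson product-moment correlation.

    Requires n >= 3 and non-constant inputs; a constant vector raises
    :class:`DegenerateInputError` rather than silently returning 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D vectors of equal length")
    if a.size < _MIN_N:
        raise DegenerateInputError(f"need >= {_MIN_N} points, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant input vector has undefined correlation")
    return float(_sps.pearsonr(a, b).statistic)


def spearman_r(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation (offered for robustness studies)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < _MIN_N:
        raise DegenerateInputError(f"need >= {_MIN_N} points, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant input vector has undefined correlation")
    return float(_sps.spearmanr(a, b).statistic)


@dataclass
class TargetResult:
    """Correlation summary for one (model, target, stratum) cell."""

    target: str
    model: str
    stratum: str  # "pooled" or a vertebral level
    n: int
    pearson_r: float
    slope: float
    intercept: float


@dataclass
class EvaluationReport:
    results: list[TargetResult]
    n_input_rows: int
    # per-target count of rows dropped for a missing reference; for every
    # target, usable + dropped = n_input_rows
    n_dropped_rows: dict[str, int]
    scatter: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])

    def pooled_r(self, model: str, target: str) -> float:
        for r in self.results:
            if r.model == model and r.target == target and r.stratum == "pooled":
                return r.pearson_r
        raise KeyError(f"no pooled result for model={model!r}, target={target!r}")

    def to_dict(self) -> dict:
        return {
            "n_input_rows": self.n_input_rows,
            "n_dropped_rows": self.n_dropped_rows,
            "results": [vars(r) for r in self.results],
        }


def _fit_line(reference: np.ndarray, prediction: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(reference, prediction, 1)
    return float(slope), float(intercept)


def evaluate_predictions(
    cohort: pd.DataFrame,
    predictions: dict[str, np.ndarray],
    targets: list[str],
) -> EvaluationReport:
    """Correlate each model's predictions with each reference target.

    ``cohort`` needs columns ``case_id``, ``vertebra_level`` and the
    reference columns; ``predictions`` maps model name -> per-row predicted
    BMD aligned with ``cohort``.  Rows with a missing reference are dropped
    and counted.  Each (model, target) yields a pooled estimate plus one
    stratum per vertebral level with >= 3 usable rows.
    """
    unknown = [t for t in targets if t not in TARGET_COLUMNS]
    if unknown:
        raise KeyError(f"unknown evaluation target(s) {unknown}; choose from {list(TARGET_COLUMNS)}")
    results: list[TargetResult] = []
    scatter_rows: list[pd.DataFrame] = []
    n_input = len(cohort)
    n_dropped: dict[str, int] = {}

    for target in targets:
        ref_col, excl_l1 = TARGET_COLUMNS[target]
        if ref_col not in cohort.columns:
            raise KeyError(f"reference column {ref_col!r} missing from cohort table")
        usable = cohort[ref_col].notna()
        if not usable.any():
            raise ValueError(f"all rows missing reference {ref_col!r}")
        n_dropped[target] = int((~usable).sum())

        for model_name, pred in predictions.items():
            pred = np.asarray(pred, dtype=float)
            if len(pred) != n_input:
                raise ValueError(
                    f"predictions for {model_name!r} have {len(pred)} rows, cohort has {n_input}"
                )
            ref = cohort[ref_col].to_numpy(dtype=float)
            levels = cohort["vertebra_level"].to_numpy()

            pooled_sel = usable.to_numpy() & ((levels != "L1") if excl_l1 else True)
            if pooled_sel.sum() < _MIN_N:
                raise ValueError(
                    f"fewer than {_MIN_N} usable rows for target {target!r}"
                )
            r = pearson_r(ref[pooled_sel], pred[pooled_sel])
            slope, intercept = _fit_line(ref[pooled_sel], pred[pooled_sel])
            results.append(
                TargetResult(target, model_name, "pooled", int(pooled_sel.sum()), r, slope, intercept)
            )
            for level in VERTEBRA_LEVELS:
                sel = usable.to_numpy() & (levels == level)
                if sel.sum() < _MIN_N:
                    continue
                r_lv = pearson_r(ref[sel], pred[sel])
                slope_lv, intercept_lv = _fit_line(ref[sel], pred[sel])
                results.append(
                    TargetResult(target, model_name, level, int(sel.sum()), r_lv, slope_lv, intercept_lv)
                )
            scatter_rows.append(
                pd.DataFrame(
                    {
                        "case_id": cohort["case_id"].to_numpy()[usable],
                        "level": levels[usable],
                        "target": target,
                        "model": model_name,
                        "reference": ref[usable],
                        "prediction": pred[usable],
                    }
                )
            )

    scatter = pd.concat(scatter_rows, ignore_index=True) if scatter_rows else pd.DataFrame()
    return EvaluationReport(
        results=results,
        n_input_rows=n_input,
        n_dropped_rows=n_dropped,
        scatter=scatter,
    )
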