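"""End-to-end cohort orchestration.

Stages: simulate (optional, synthetic cohorts) -> extract (slice -> ROI ->
45 features per row) -> fit + evaluate (normalize, fit the configured
models per target on the full sample, correlate predictions with the
reference).  Per-case failures during extraction are logged and collected
rather than aborting the run, unless strict mode is on; every stage
conserves rows (processed + failed = input) and is deterministic given the
config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, models
from .config import PipelineConfig
from .features import extract_features, feature_names
from .imaging import read_dicom_slice, read_matrix_fixture
from .phantom import PhantomSpec, SyntheticCohortSpec, generate_cohort
from .roi import extract_roi, find_trabecular_roi

__all__ = [
    "ExtractionResult",
    "load_cohort",
    "run_extract",
    "run_fit_evaluate",
    "run_simulate",
    "run_all",
]

logger = logging.getLogger(__name__)

KEY_COLUMNS = ("case_id", "vertebra_level")


@dataclass
class ExtractionResult:
    features: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    @property
    def n_processed(self) -> int:
        return len(self.features)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def load_cohort(cohort_csv: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Requires the key columns and image paths; enforces uniqueness of
    (case_id, vertebra_level) and the BMD sanity bound 0 < bmd < 3 g/cm^2.
    """
    cohort = pd.read_csv(cohort_csv, dtype={"case_id": str, "patient_id": str})
    missing = [c for c in (*KEY_COLUMNS, "image_path") if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s) {missing}")
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    dupes = cohort.duplicated(subset=list(KEY_COLUMNS))
    if dupes.any():
        bad = cohort.loc[dupes, list(KEY_COLUMNS)].to_records(index=False).tolist()
        raise ValueError(f"duplicate (case_id, vertebra_level) rows: {bad[:5]}")
    for col in ("lumbar_total", "lumbar_total_excl_L1", "hip_total"):
        if col in cohort.columns:
            vals = cohort[col].dropna()
            if ((vals <= 0) | (vals >= 3.0)).any():
                raise ValueError(f"{col} outside the sanity bound (0, 3) g/cm^2")
    return cohort


def _read_slice(path: str | Path):
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return read_dicom_slice(path)
    return read_matrix_fixture(path)


def run_extract(
    cohort_csv: str | Path, config: PipelineConfig | None = None
) -> ExtractionResult:
    """One feature row per (case, vertebral level).

    Each slice is read, the trabecular ROI is located and cropped, and the
    45-feature vector is computed.  A failing case is recorded with its
    error and skipped (or re-raised in strict mode).
    """
    config = config or PipelineConfig()
    cohort = load_cohort(cohort_csv)
    base_dir = Path(cohort_csv).parent
    names = feature_names(config.features)
    rows: list[dict] = []
    failures: list[dict] = []
    for rec in cohort.itertuples(index=False):
        try:
            img_path = Path(rec.image_path)
            if not img_path.is_absolute():
                img_path = base_dir / img_path
            img = _read_slice(img_path)
            region = find_trabecular_roi(
                img,
                hu_low=config.roi.hu_low,
                hu_high=config.roi.hu_high,
                closing=config.roi.closing,
                min_roi_area=config.roi.min_roi_area,
            )
            roi = extract_roi(img, region)
            fv = extract_features(roi, config.features)
            row = {
                "case_id": rec.case_id,
                "vertebra_level": rec.vertebra_level,
                "source_id": img.source_id,
                "roi_row_start": region.row_start,
                "roi_row_end": region.row_end,
                "roi_col_start": region.col_start,
                "roi_col_end": region.col_end,
            }
            row.update(dict(zip(names, fv.values)))
            rows.append(row)
        except Exception as exc:
            if config.strict:
                raise
            logger.warning(
                "extraction failed for (%s, %s): %s", rec.case_id, rec.vertebra_level, exc
            )
            failures.append(
                {
                    "case_id": rec.case_id,
                    "vertebra_level": rec.vertebra_level,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    logger.info("extracted %d rows, %d failures", len(rows), len(failures))
    columns = [
        "case_id",
        "vertebra_level",
        "source_id",
        "roi_row_start",
        "roi_row_end",
        "roi_col_start",
        "roi_col_end",
        *names,
    ]
    features = pd.DataFrame(rows, columns=columns)
    return ExtractionResult(features=features, failures=failures)


def write_features(result: ExtractionResult, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "features.csv"
    result.features.to_csv(path, index=False, float_format="%.10g")
    if result.failures:
        pd.DataFrame(result.failures).to_csv(out_dir / "failures.csv", index=False)
    return path


def run_fit_evaluate(
    features: pd.DataFrame | str | Path,
    cohort_csv: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict, evaluation.EvaluationReport]:
    """Fit the configured models per target on the full sample and
    correlate their predictions with the reference BMD.

    Returns (fitted models keyed by (model, target), report).  With
    ``out_dir`` set, also writes model JSON files, the report (JSON + CSV)
    and the scatter table.
    """
    config = config or PipelineConfig()
    if not isinstance(features, pd.DataFrame):
        features = pd.read_csv(features, dtype={"case_id": str})
    cohort = load_cohort(cohort_csv)
    names = list(feature_names(config.features))
    merged = features.merge(cohort, on=list(KEY_COLUMNS), how="inner", validate="1:1")
    if len(merged) < 10:
        raise models.InsufficientDataError(
            f"only {len(merged)} joined rows; need >= 10 to fit"
        )
    X = merged[names].to_numpy(dtype=float)

    # One model per (kind, target): each reference target gets its own fit,
    # and its correlations are computed from that fit's predictions.
    fitted: dict[tuple[str, str], object] = {}
    all_results: list[evaluation.TargetResult] = []
    dropped: dict[str, int] = {}
    scatter_parts: list[pd.DataFrame] = []
    for target in config.targets:
        ref_col = evaluation.TARGET_COLUMNS[target][0]
        ok = merged[ref_col].notna().to_numpy()
        y = merged.loc[ok, ref_col].to_numpy(dtype=float)
        predictions: dict[str, np.ndarray] = {}
        for model_name in config.models:
            if model_name == "linear":
                model = models.fit_linear(X[ok], y, target_name=target)
                predictions[model_name] = models.predict_linear(model, X)
            else:
                model = models.fit_ann(X[ok], y, config.ann, target_name=target)
                predictions[model_name] = models.predict_ann(model, X)
            fitted[(model_name, target)] = model
        part = evaluation.evaluate_predictions(merged, predictions, [target])
        all_results.extend(part.results)
        dropped.update(part.n_dropped_rows)
        scatter_parts.append(part.scatter)

    report = evaluation.EvaluationReport(
        results=all_results,
        n_input_rows=len(merged),
        n_dropped_rows=dropped,
        scatter=pd.concat(scatter_parts, ignore_index=True),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (model_name, target), model in fitted.items():
            models.save_model(model, out_dir / f"model_{model_name}_{target}.json")
        report.to_frame().to_csv(out_dir / "report.csv", index=False, float_format="%.10g")
        (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        report.scatter.to_csv(out_dir / "scatter.csv", index=False, float_format="%.10g")
        config.write_yaml(out_dir / "resolved_config.yaml")
    return fitted, report


def run_simulate(
    out_dir: str | Path,
    cohort_spec: SyntheticCohortSpec | None = None,
    phantom_template: PhantomSpec | None = None,
    spec_file: str | Path | None = None,
) -> Path:
    """Generate a synthetic cohort on disk; returns the cohort CSV path.

    ``spec_file`` is a YAML file with optional ``cohort:`` and ``phantom:``
    mappings overriding the dataclass defaults.
    """
    if spec_file is not None:
        import yaml

        raw = yaml.safe_load(Path(spec_file).read_text()) or {}
        try:
            cohort_kwargs = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in (raw.get("cohort") or {}).items()
            }
            phantom_kwargs = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in (raw.get("phantom") or {}).items()
            }
            cohort_spec = SyntheticCohortSpec(**cohort_kwargs)
            phantom_template = PhantomSpec(**phantom_kwargs)
        except TypeError as exc:
            raise ValueError(f"invalid simulation spec {spec_file}: {exc}") from exc
    cohort_spec = cohort_spec or SyntheticCohortSpec()
    csv_path, _ = generate_cohort(cohort_spec, out_dir, phantom_template)
    logger.info("synthetic cohort written to %s", csv_path)
    return csv_path


def run_all(
    cohort_csv: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> tuple[Path, evaluation.EvaluationReport]:
    """extract -> fit -> evaluate; writes all artifacts plus a run summary.

    Returns (feature CSV path, evaluation report).
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    extraction = run_extract(cohort_csv, config)
    feature_path = write_features(extraction, out_dir)
    _, report = run_fit_evaluate(extraction.features, cohort_csv, config, out_dir=out_dir)
    summary = {
        "n_input_rows": extraction.n_processed + extraction.n_failed,
        "n_processed": extraction.n_processed,
        "n_failed": extraction.n_failed,
        "targets": list(config.targets),
        "models": list(config.models),
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return feature_path, report
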