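"""End-to-end orchestration: generate → preprocess → metrics → CV → ROC → report.

Each stage is a file-in/file-out function under one run directory, so any
stage can be rerun independently; ``run_pipeline`` chains them and serializes
the full configuration alongside the outputs as a provenance record.  All
randomness flows from the named seeds in :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .classifier import ClassifierConfig, cross_validate
from .diagnostics import roc_curve
from .errors import ConfigurationError, SegmentationError
from .preprocess import build_dataset, deskew, segment_rows
from .report import build_report
from .synth import GeneratorConfig, sample_subject_profiles, write_dataset

log = logging.getLogger("penstroke")

#: task used for the objective micrographia metrics (the sentence task).
METRICS_TASK = "sentence"


@dataclass
class RunConfig:
    """One reproducible run: cohorts, generator, classifier, comparison, seeds."""

    out_dir: str | Path
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"HS": 25, "PD_OFF": 57}
    )
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    comparison: str = "HS_vs_PD"
    seed_generation: int = 0
    seed_folds: int = 1
    seed_training: int = 2
    expected_rows: int | None = None  # defaults to generator.rows_per_sheet

    def validate(self) -> None:
        """Fail fast before any stage runs."""
        rows = self.expected_rows or self.generator.rows_per_sheet
        if rows < 2:
            raise ConfigurationError("expected_rows must be >= 2")
        counts = {}
        for label, n in self.n_per_group.items():
            if label not in self.generator.group_area_params:
                raise ConfigurationError(f"no generator params for group {label!r}")
            cls = 0 if label == "HS" else 1
            counts[cls] = counts.get(cls, 0) + n
        if self.comparison == "HS_vs_PD":
            for cls in (0, 1):
                if counts.get(cls, 0) < self.classifier.folds:
                    raise ConfigurationError(
                        f"class {cls} has {counts.get(cls, 0)} subjects, "
                        f"fewer than {self.classifier.folds} folds"
                    )


def _serialize_config(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if callable(obj):
            return getattr(obj, "__name__", "callable")
        return obj

    return enc(config)


def measure_synthetic_cohort(
    group_label: str,
    n_subjects: int,
    seed: int,
    generator: GeneratorConfig | None = None,
    task_id: str = METRICS_TASK,
) -> pd.DataFrame:
    """Generate one cohort, render clean sheets, and run the metrics pipeline.

    Per subject: draw generator parameters from the group's distribution,
    render the sentence-task sheet, segment it, and measure per-row ink areas;
    returns one row per subject with the measured first-row (consistent) area,
    the measured sequence effect, and the generating parameters.  Used for
    parameter-recovery checks of the whole synth → segment → binarize →
    ink-area chain.
    """
    generator = generator or GeneratorConfig()
    profiles = sample_subject_profiles(generator, {group_label: n_subjects}, seed)
    records = []
    for i, profile in enumerate(profiles):
        sheet_seed = int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        )
        from .synth import render_sheet

        page, gt = render_sheet(profile, task_id, generator, sheet_seed)
        rows = measure_page(
            page, generator.calibration, generator.rows_per_sheet,
            subject_id=profile.subject_id, task_id=task_id,
        )
        summary = metrics_mod.summarize_subject(rows)
        records.append(
            {
                "subject_id": profile.subject_id,
                "true_base_area_mm2": profile.base_area_mm2,
                "true_seq_effect": profile.seq_effect,
                "consistent_area_mm2": summary.consistent_area_mm2,
                "sequence_effect": summary.sequence_effect,
            }
        )
    return pd.DataFrame(records)


def stage_generate(config: RunConfig) -> Path:
    """Sample cohorts and write all page images plus the manifest."""
    out = Path(config.out_dir) / "pages"
    profiles = sample_subject_profiles(
        config.generator, config.n_per_group, config.seed_generation
    )
    write_dataset(profiles, config.generator, out, overwrite=True)
    log.info("generate: %d subjects -> %s", len(profiles), out)
    return out / "manifest.csv"


def measure_page(
    page: np.ndarray,
    calibration: float,
    expected_rows: int,
    subject_id: str = "",
    task_id: str = "",
    apply_deskew: bool = False,
) -> list[metrics_mod.StrokeMetrics]:
    """Segment one page and measure each row at native resolution.

    With ``apply_deskew`` the page is illumination-flattened, rows are located
    on a deskewed copy, and each row's band is mapped back (nearest-neighbor)
    onto the flattened original so ink areas are counted on a page that has
    been resampled only once — re-rotating the intensities a second time
    softens thin strokes enough to bias the counted area.  Row geometry is
    taken from the deskewed frame, where rows are horizontal.
    """
    from scipy import ndimage as ndi

    if not apply_deskew:
        boxes = segment_rows(page, expected_rows, calibration)
        return [
            metrics_mod.measure_row(
                page[y0:y1, x0:x1], calibration,
                subject_id=subject_id, task_id=task_id, row_index=i + 1,
            )
            for i, (x0, y0, x1, y1) in enumerate(boxes)
        ]

    from .preprocess import estimate_skew, flatten_illumination

    flat = flatten_illumination(page, calibration)
    angle = estimate_skew(flat, calibration)
    desk = np.clip(
        np.round(ndi.rotate(flat.astype(float), angle, reshape=False, order=1,
                            mode="constant", cval=255.0)),
        0, 255,
    ).astype(np.uint8)
    boxes = segment_rows(desk, expected_rows, calibration)
    labels = np.zeros(desk.shape, dtype=np.int32)
    for i, (x0, y0, x1, y1) in enumerate(boxes):
        labels[y0:y1, x0:x1] = i + 1
    bands = ndi.rotate(labels, -angle, reshape=False, order=0, mode="constant", cval=0)
    mask = metrics_mod.binarize(flat, calibration)
    rows = []
    for i, (x0, y0, x1, y1) in enumerate(boxes):
        area = metrics_mod.ink_area(mask & (bands == i + 1), calibration)
        crop_mask = metrics_mod.binarize(desk[y0:y1, x0:x1], calibration)
        if crop_mask.any():
            height, length = metrics_mod.row_geometry(crop_mask, calibration)
        else:
            height = length = 0.0
        rows.append(
            metrics_mod.StrokeMetrics(
                subject_id, task_id, i + 1, area, height, length
            )
        )
    return rows


def stage_metrics(config: RunConfig, manifest_path: Path) -> tuple[Path, Path]:
    """Per-row and per-subject micrographia metrics for the sentence task."""
    from .preprocess import load_page

    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    root = manifest_path.parent
    apply_deskew = config.generator.artifact_params is not None
    all_rows, summaries, skipped = [], [], 0
    for rec in manifest.itertuples(index=False):
        if rec.task_id != METRICS_TASK:
            continue
        page = load_page(root / rec.path)
        try:
            rows = measure_page(
                page, float(rec.calibration_mm_per_px),
                config.expected_rows or config.generator.rows_per_sheet,
                subject_id=rec.subject_id, task_id=rec.task_id,
                apply_deskew=apply_deskew,
            )
        except SegmentationError as exc:
            log.warning("metrics: skipping %s (%s)", rec.path, exc)
            skipped += 1
            continue
        all_rows.extend(rows)
        summaries.append(metrics_mod.summarize_subject(rows))
    out_dir = Path(config.out_dir)
    rows_path = out_dir / "row_metrics.csv"
    summary_path = out_dir / "subject_metrics.csv"
    metrics_mod.metrics_table(all_rows).to_csv(rows_path, index=False)
    metrics_mod.summary_table(summaries).to_csv(summary_path, index=False)
    log.info("metrics: %d subjects measured, %d pages skipped", len(summaries), skipped)
    return rows_path, summary_path


def stage_classify(config: RunConfig, manifest_path: Path) -> Path:
    """Patient-disjoint cross-validation; writes per-patient LR scores."""
    dataset = build_dataset(
        manifest_path,
        config.comparison,
        expected_rows=config.expected_rows or config.generator.rows_per_sheet,
        target_size=config.classifier.input_size,
        apply_deskew=config.generator.artifact_params is not None,
    )
    cfg = dataclasses.replace(config.classifier, seed=config.seed_training)
    result = cross_validate(dataset, cfg)
    out_dir = Path(config.out_dir)
    scores_path = out_dir / "patient_lr.csv"
    table = result.scores_table()
    table["label"] = [dataset.subject_to_class[s] for s in table["subject_id"]]
    table.to_csv(scores_path, index=False)
    result.fold_metrics.to_csv(out_dir / "fold_metrics.csv", index=False)
    oof = pd.DataFrame(
        {
            "subject_id": [i.subject_id for i in dataset.instances],
            "task_id": [i.task_id for i in dataset.instances],
            "row_index": [i.row_index for i in dataset.instances],
            "probability": result.oof_probabilities,
            "label": dataset.labels,
        }
    )
    oof.to_csv(out_dir / "oof_probabilities.csv", index=False)
    log.info("classify: %d patients scored (%d instances, %d pages skipped)",
             len(table), len(dataset.instances), dataset.skipped_pages)
    return scores_path


def stage_roc(config: RunConfig, scores_path: Path) -> Path:
    """Patient-level ROC with Youden-optimal operating metrics."""
    table = pd.read_csv(scores_path)
    roc = roc_curve(table["lr"].to_numpy(), table["label"].to_numpy())
    out_dir = Path(config.out_dir)
    pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    ).to_csv(out_dir / "roc_points.csv", index=False)
    payload = {
        "comparison": config.comparison,
        "auc": roc.auc,
        "youden_j": roc.youden_j,
        "associated_criterion": roc.associated_criterion,
        "sensitivity": roc.operating.sensitivity,
        "specificity": roc.operating.specificity,
        "ppv": roc.operating.ppv,
        "npv": roc.operating.npv,
        "accuracy": roc.operating.accuracy,
        "n_pos": roc.n_pos,
        "n_neg": roc.n_neg,
    }
    roc_path = out_dir / "roc_metrics.json"
    roc_path.write_text(json.dumps(payload, indent=1))
    log.info("roc: AUC=%.3f J=%.3f", roc.auc, roc.youden_j)
    return roc_path


def stage_report(config: RunConfig, summary_path: Path, scores_path: Path,
                 manifest_path: Path) -> Path:
    """Group summaries, pairwise tests and LR-vs-metrics correlations."""
    summary = pd.read_csv(summary_path)
    scores = pd.read_csv(scores_path) if scores_path and Path(scores_path).exists() else None
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    tables = build_report(summary, scores, manifest)
    out_dir = Path(config.out_dir) / "report"
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False)
    log.info("report: wrote %s", sorted(tables))
    return out_dir


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order under one output directory.

    The serialized configuration is written first; a rerun with identical
    config reproduces all deterministic outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(
        json.dumps(_serialize_config(config), indent=1)
    )
    manifest_path = stage_generate(config)
    _, summary_path = stage_metrics(config, manifest_path)
    scores_path = stage_classify(config, manifest_path)
    stage_roc(config, scores_path)
    stage_report(config, summary_path, scores_path, manifest_path)
    return out_dir
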