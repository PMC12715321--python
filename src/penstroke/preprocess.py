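"""Page preprocessing: deskew, row segmentation, and instance extraction.

A scanned sheet carries 10 repetitions of the written text in consecutive
rows.  Each page is split into its rows automatically from the smoothed
horizontal ink-projection profile (binarize, sum ink per scanline, cut at
long zero-runs, merge small fragments), replacing the manual row-basis
cropping that produces one classifier instance per written row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

from . import metrics
from .errors import DatasetError, SegmentationError

#: comparison name -> (subject filter on (group, stage, state), class-1 test)
#: class 1 is the second-named cohort of the comparison.
COMPARISONS = {
    "HS_vs_PD": (
        lambda g, st, state: g == "HS" or (g == "PD" and state != "ON"),
        lambda g, st, state: g == "PD",
    ),
    "early_vs_mid": (
        lambda g, st, state: g == "PD",
        lambda g, st, state: st == "mid_advanced",
    ),
    "OFF_vs_ON": (
        lambda g, st, state: g == "PD",
        lambda g, st, state: state == "ON",
    ),
}


@dataclass(frozen=True)
class RowInstance:
    """One cropped written row, normalized for classification."""

    subject_id: str
    task_id: str
    row_index: int  # 1-based, top to bottom
    raster: np.ndarray  # float32 in [0, 1], ink dark (near 0)
    calibration: float  # mm per pixel of the source page
    box: tuple[int, int, int, int]  # (x0, y0, x1, y1) on the page, half-open


@dataclass
class InstanceDataset:
    """Row instances with subject-level class labels for one comparison."""

    comparison: str
    instances: list[RowInstance]
    labels: np.ndarray  # int {0, 1}, aligned with instances
    subject_to_class: dict[str, int]
    class_names: tuple[str, str]
    skipped_pages: int = 0
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            vals, cnts = np.unique(self.labels, return_counts=True) if len(self.labels) else ([], [])
            self.counts = {int(v): int(c) for v, c in zip(vals, cnts)}


def flatten_illumination(
    page: np.ndarray,
    calibration: float,
    window_mm: float = 3.0,
) -> np.ndarray:
    """Remove smooth illumination gradients by background normalization.

    The paper background is estimated by grayscale morphological closing with
    a window wider than any stroke (``window_mm``), then the page is rescaled
    so the background is uniform white.  A clean, evenly lit page is returned
    unchanged up to rounding.
    """
    # the background is smooth by assumption, so estimate it at reduced
    # resolution: max-pool (removes dark strokes), close, then resample up
    ds = 4
    size = max(2, int(round(window_mm / calibration / ds)))
    pooled = ndimage.maximum_filter(page.astype(float), size=ds)[::ds, ::ds]
    bg_small = ndimage.grey_closing(pooled, size=(size, size))
    bg = ndimage.zoom(bg_small, ds, order=1, mode="nearest")[
        : page.shape[0], : page.shape[1]
    ]
    if bg.shape != page.shape:  # zoom can undershoot by a pixel
        pad_y = page.shape[0] - bg.shape[0]
        pad_x = page.shape[1] - bg.shape[1]
        bg = np.pad(bg, ((0, pad_y), (0, pad_x)), mode="edge")
    bg = np.maximum(bg, 1.0)
    out = page.astype(float) * (255.0 / bg)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def estimate_skew(
    page: np.ndarray,
    calibration: float,
    max_angle: float = 3.0,
) -> float:
    """Estimate page rotation (degrees, counter-clockwise) from the projection.

    Searches the angle maximizing the variance of the horizontal ink-projection
    profile — sharpest row structure — coarse-to-fine on a downsampled binary
    mask.
    """
    step = max(1, int(round(1.0 / calibration / 4)))  # ~4 px per mm
    small = metrics.binarize(
        page[::step, ::step], calibration * step
    ).astype(float)

    def sharpness(angle: float) -> float:
        rot = ndimage.rotate(small, angle, reshape=False, order=1,
                             mode="constant", cval=0.0)
        return float(np.var(rot.sum(axis=1)))

    best = max(np.arange(-max_angle, max_angle + 0.25, 0.5), key=sharpness)
    fine = np.clip(best + np.arange(-0.5, 0.55, 0.1), -max_angle, max_angle)
    best = max(fine, key=sharpness)
    return float(best)


def deskew(page: np.ndarray, calibration: float, max_angle: float = 3.0) -> tuple[np.ndarray, float]:
    """Flatten illumination and rotate the page so its rows are horizontal.

    Returns (page, angle applied).  The applied angle is the one maximizing
    projection sharpness, used with the same rotation convention, so it
    directly undoes the page skew.
    """
    page = flatten_illumination(page, calibration)
    angle = estimate_skew(page, calibration, max_angle)
    if angle == 0.0:
        return page, 0.0
    out = ndimage.rotate(
        page.astype(float), angle, reshape=False, order=1,
        mode="constant", cval=float(np.median(page)),
    )
    return np.clip(np.round(out), 0, 255).astype(page.dtype), angle


def segment_rows(
    page: np.ndarray,
    expected_rows: int,
    calibration: float,
    min_gap_mm: float = 2.0,
    min_band_mm: float = 2.0,
    margin_mm: float = 1.0,
) -> list[tuple[int, int, int, int]]:
    """Locate the written rows of a page from its ink-projection profile.

    Returns exactly ``expected_rows`` boxes (x0, y0, x1, y1), half-open page
    coordinates, sorted top to bottom, each a tight ink bounding box expanded
    by ``margin_mm``.  Bands separated by less than ``min_gap_mm`` of blank
    scanlines are merged; bands shorter than ``min_band_mm`` are dropped.
    Raises :class:`SegmentationError` when the band count disagrees.
    """
    if expected_rows < 1:
        raise ValueError("expected_rows must be >= 1")
    mask = metrics.binarize(page, calibration)
    profile = mask.sum(axis=1).astype(float)
    sigma = 0.5 / calibration  # ~0.5 mm smoothing
    profile = ndimage.gaussian_filter1d(profile, sigma)
    on = profile > 0.5

    # raw runs of inked scanlines
    bands: list[list[int]] = []
    start = None
    for i, v in enumerate(on):
        if v and start is None:
            start = i
        elif not v and start is not None:
            bands.append([start, i])
            start = None
    if start is not None:
        bands.append([start, len(on)])

    # merge bands separated by gaps shorter than the minimum inter-row gap
    min_gap = min_gap_mm / calibration
    merged: list[list[int]] = []
    for band in bands:
        if merged and band[0] - merged[-1][1] < min_gap:
            merged[-1][1] = band[1]
        else:
            merged.append(band)

    min_band = min_band_mm / calibration
    merged = [b for b in merged if b[1] - b[0] >= min_band]

    if len(merged) != expected_rows:
        raise SegmentationError(
            f"found {len(merged)} ink bands, expected {expected_rows}",
            found=len(merged),
            expected=expected_rows,
        )

    # shared horizontal frame (full ink column range of the page) so the
    # crops of one page stay mutually to scale: row length and letter size
    # are informative and must not be normalized away per row
    margin = int(round(margin_mm / calibration))
    cols = np.nonzero(mask.any(axis=0))[0]
    bx0 = max(int(cols.min()) - margin, 0)
    bx1 = min(int(cols.max()) + 1 + margin, page.shape[1])
    boxes = []
    for y0, y1 in merged:
        ys = np.nonzero(mask[y0:y1].any(axis=1))[0]
        by0 = max(y0 + int(ys.min()) - margin, 0)
        by1 = min(y0 + int(ys.max()) + 1 + margin, page.shape[0])
        boxes.append((bx0, by0, bx1, by1))
    return boxes


def crop_and_normalize(
    page: np.ndarray,
    box: tuple[int, int, int, int],
    target_size: tuple[int, int],
) -> np.ndarray:
    """Crop a box, pad to the target aspect ratio, resize, min-max normalize.

    Padding uses the crop's background (maximum) intensity, split equally on
    both sides of the short axis.  Output is float32 in [0, 1] with ink dark;
    a constant crop maps to all zeros.
    """
    x0, y0, x1, y1 = box
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty box {box}")
    crop = np.asarray(page[y0:y1, x0:x1], dtype=float)
    th, tw = target_size
    h, w = crop.shape
    background = float(crop.max())
    # pad the axis that is too short for the target aspect ratio
    if h * tw < w * th:  # too wide -> pad height
        new_h = int(np.ceil(w * th / tw))
        pad = new_h - h
        crop = np.pad(crop, ((pad // 2, pad - pad // 2), (0, 0)),
                      constant_values=background)
    elif h * tw > w * th:  # too tall -> pad width
        new_w = int(np.ceil(h * tw / th))
        pad = new_w - w
        crop = np.pad(crop, ((0, 0), (pad // 2, pad - pad // 2)),
                      constant_values=background)
    out = resize(crop, target_size, order=1, anti_aliasing=True, mode="edge")
    lo, hi = out.min(), out.max()
    if hi == lo:
        return np.zeros(target_size, dtype=np.float32)
    return ((out - lo) / (hi - lo)).astype(np.float32)


def load_page(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale page image."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


def build_dataset(
    manifest: pd.DataFrame | str | Path,
    comparison: str,
    expected_rows: int = 10,
    target_size: tuple[int, int] = (32, 96),
    root: str | Path | None = None,
    tasks: Sequence[str] | None = None,
    apply_deskew: bool = True,
) -> InstanceDataset:
    """Segment and crop every page of a comparison into labeled row instances.

    Pages failing segmentation are skipped with a warning and counted, never
    imputed.  Labels live at subject level: class 1 is the second-named cohort
    (PD, mid_advanced, ON).  Raises :class:`DatasetError` when a class ends up
    empty.
    """
    if comparison not in COMPARISONS:
        raise DatasetError(
            f"unknown comparison {comparison!r}; choose from {sorted(COMPARISONS)}"
        )
    subject_filter, is_class1 = COMPARISONS[comparison]
    if isinstance(manifest, (str, Path)):
        root = Path(manifest).parent if root is None else Path(root)
        manifest = pd.read_csv(manifest, keep_default_na=False)
    else:
        root = Path(".") if root is None else Path(root)
        manifest = manifest.copy()

    if tasks is not None:
        manifest = manifest[manifest["task_id"].isin(tasks)]

    instances: list[RowInstance] = []
    labels: list[int] = []
    subject_to_class: dict[str, int] = {}
    skipped = 0
    for rec in manifest.itertuples(index=False):
        if not subject_filter(rec.group, rec.stage, rec.state):
            continue
        label = int(is_class1(rec.group, rec.stage, rec.state))
        subject_to_class[rec.subject_id] = label
        cal = float(rec.calibration_mm_per_px)
        page = load_page(root / rec.path)
        if apply_deskew:
            page, _ = deskew(page, cal)
        try:
            boxes = segment_rows(page, expected_rows, cal)
        except SegmentationError as exc:
            warnings.warn(
                f"skipping page {rec.path}: {exc}", stacklevel=2
            )
            skipped += 1
            continue
        for i, box in enumerate(boxes):
            instances.append(
                RowInstance(
                    subject_id=rec.subject_id,
                    task_id=rec.task_id,
                    row_index=i + 1,
                    raster=crop_and_normalize(page, box, target_size),
                    calibration=cal,
                    box=box,
                )
            )
            labels.append(label)

    names = tuple(comparison.split("_vs_"))
    labels_arr = np.asarray(labels, dtype=int)
    for cls in (0, 1):
        if subject_to_class and not np.any(labels_arr == cls) :
            raise DatasetError(
                f"comparison {comparison}: class {names[cls]!r} has no instances"
            )
    if not instances:
        raise DatasetError(f"comparison {comparison}: no instances found")
    return InstanceDataset(
        comparison=comparison,
        instances=instances,
        labels=labels_arr,
        subject_to_class=subject_to_class,
        class_names=names,
        skipped_pages=skipped,
    )
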