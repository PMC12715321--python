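"""Synthetic handwriting-sheet generator with known per-row ink areas.

Emulates the study design the pipeline targets: one white A4 sheet
(210 × 297 mm) per subject and task, on which the same short text is written
10 times in consecutive rows from the top down.  Instead of letterforms, each
row is a parametric cursive-like stroke curve whose thickness is solved so
that the binarized ink area hits a prescribed target, giving exact ground
truth for every downstream stage (segmentation, area measurement,
classification).

Per-subject parameters are drawn from group-level normal distributions whose
defaults follow pen-stroke-area statistics reported for clinical cohorts of
healthy subjects (HS) and Parkinson's disease (PD) patients, OFF and ON
L-Dopa, at early and mid-advanced stages.  The within-sheet size decay is a
geometric progression calibrated so the last-5/first-5 mean-area ratio equals
the subject's sequence-effect parameter.  Optional scan artifacts (rotation,
illumination gradient, additive noise) emulate smartphone digitization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import line as draw_line

from .errors import ConfigurationError, GenerationError

PAPER_LEVEL = 255
INK_LEVEL = 0

#: Group parameter defaults: mean and SD of first-row pen-stroke area (mm²).
DEFAULT_GROUP_AREA_PARAMS: dict[str, tuple[float, float]] = {
    "HS": (126.72, 44.85),
    "PD_OFF": (89.78, 26.37),
    "PD_ON": (93.82, 31.20),
    "PD_early_OFF": (84.81, 27.99),
    "PD_early_ON": (84.34, 23.84),
    "PD_mid_OFF": (94.14, 25.94),
    "PD_mid_ON": (102.11, 35.93),
}

#: Group defaults: mean and SD of the sequence effect (last5/first5 area ratio).
#: Subgroup/ON values are not reported separately; they reuse the PD-OFF ones.
DEFAULT_GROUP_SEQEFFECT_PARAMS: dict[str, tuple[float, float]] = {
    "HS": (1.05, 0.16),
    "PD_OFF": (0.92, 0.23),
    "PD_ON": (0.92, 0.23),
    "PD_early_OFF": (0.92, 0.23),
    "PD_early_ON": (0.92, 0.23),
    "PD_mid_OFF": (0.92, 0.23),
    "PD_mid_ON": (0.92, 0.23),
}

# label -> (group, stage, state); stage None on PD labels means round-robin
# early / mid_advanced assignment across the sampled cohort.
_GROUP_LABELS: dict[str, tuple[str, str | None, str | None]] = {
    "HS": ("HS", "none", "none"),
    "PD_OFF": ("PD", None, "OFF"),
    "PD_ON": ("PD", None, "ON"),
    "PD_early_OFF": ("PD", "early", "OFF"),
    "PD_early_ON": ("PD", "early", "ON"),
    "PD_mid_OFF": ("PD", "mid_advanced", "OFF"),
    "PD_mid_ON": ("PD", "mid_advanced", "ON"),
}

DEFAULT_TASKS = ("name", "sentence")


@dataclass(frozen=True)
class ArtifactParams:
    """Smartphone-scan artifact settings.

    rotation_deg: maximum page rotation magnitude (uniform draw), ≤ 3°.
    illumination: peak-to-trough illumination gradient as a fraction of the
        dynamic range, ≤ 0.2.
    noise_sd: additive Gaussian noise SD as a fraction of the range, ≤ 0.05.
    """

    rotation_deg: float = 1.5
    illumination: float = 0.10
    noise_sd: float = 0.02

    def __post_init__(self):
        if not (0 <= self.rotation_deg <= 3.0):
            raise ConfigurationError(
                f"rotation_deg must be in [0, 3], got {self.rotation_deg}"
            )
        if not (0 <= self.illumination <= 0.20):
            raise ConfigurationError(
                f"illumination must be in [0, 0.2], got {self.illumination}"
            )
        if not (0 <= self.noise_sd <= 0.05):
            raise ConfigurationError(
                f"noise_sd must be in [0, 0.05], got {self.noise_sd}"
            )

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0 and self.illumination == 0 and self.noise_sd == 0


@dataclass(frozen=True)
class GeneratorConfig:
    """Page geometry, raster resolution and cohort distribution parameters."""

    page_width_mm: float = 210.0
    page_height_mm: float = 297.0
    dpi: float = 300.0
    rows_per_sheet: int = 10
    tasks_per_subject: int = 2
    group_area_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_AREA_PARAMS)
    )
    group_seqeffect_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SEQEFFECT_PARAMS)
    )
    artifact_params: ArtifactParams | None = None  # None = clean render
    seed: int = 0
    margin_mm: float = 15.0  # page margin on all four sides
    band_pad_frac: float = 0.16  # fraction of band height kept ink-free per side

    def __post_init__(self):
        if self.rows_per_sheet < 2:
            raise ConfigurationError("rows_per_sheet must be >= 2")
        if self.dpi <= 0 or self.page_width_mm <= 0 or self.page_height_mm <= 0:
            raise ConfigurationError("page dimensions and dpi must be positive")
        for name, params in (
            ("group_area_params", self.group_area_params),
            ("group_seqeffect_params", self.group_seqeffect_params),
        ):
            for label, (mean, sd) in params.items():
                if mean <= 0 or sd < 0:
                    raise ConfigurationError(
                        f"{name}[{label}] must have mean > 0 and SD >= 0"
                    )

    @property
    def calibration(self) -> float:
        """mm per pixel."""
        return 25.4 / self.dpi

    @property
    def page_shape(self) -> tuple[int, int]:
        """Raster (rows, cols) = (height_px, width_px)."""
        c = self.calibration
        return (round(self.page_height_mm / c), round(self.page_width_mm / c))


@dataclass(frozen=True)
class SubjectProfile:
    """One participant's identity, class labels and generator parameters."""

    subject_id: str
    group: str  # HS | PD
    stage: str = "none"  # early | mid_advanced | none
    state: str = "none"  # OFF | ON | none
    base_area_mm2: float = 100.0  # target mean ink area of rows 1-5 (mm²)
    seq_effect: float = 1.0  # target last-5/first-5 mean area ratio
    covariates: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.group not in ("HS", "PD"):
            raise ConfigurationError(f"group must be HS or PD, got {self.group}")
        if self.base_area_mm2 <= 0 or self.seq_effect <= 0:
            raise ConfigurationError("base_area_mm2 and seq_effect must be > 0")
        if (self.stage != "none") != (self.group == "PD"):
            raise ConfigurationError("stage must be set iff group is PD")


@dataclass
class SheetGroundTruth:
    """Per-sheet ground truth recorded at render time (for testing)."""

    subject_id: str
    task_id: str
    calibration: float  # mm per pixel
    target_areas_mm2: list[float]
    realized_areas_mm2: list[float]
    boxes: list[tuple[int, int, int, int]]  # (x0, y0, x1, y1), half-open
    rotation_deg: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SheetGroundTruth":
        d = json.loads(text)
        d["boxes"] = [tuple(b) for b in d["boxes"]]
        return cls(**d)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Normal draw rejected below ``lo`` (floor at 10% of group mean upstream)."""
    if sd == 0:
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x >= lo:
            return float(x)
    raise GenerationError(f"truncated normal({mean}, {sd}) failed to exceed {lo}")


def sample_subject_profiles(
    config: GeneratorConfig,
    n_per_group: Mapping[str, int],
    seed: int,
) -> list[SubjectProfile]:
    """Draw per-subject base areas and sequence effects for each cohort.

    Parameters are drawn from the group's normal distribution, truncated
    below at 10% of the group mean.  Group labels must exist in the config's
    parameter maps.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    for label, n in n_per_group.items():
        if label not in _GROUP_LABELS:
            raise ConfigurationError(f"unknown group label: {label!r}")
        if label not in config.group_area_params:
            raise ConfigurationError(f"no area params configured for {label!r}")
        if label not in config.group_seqeffect_params:
            raise ConfigurationError(f"no sequence-effect params for {label!r}")
        group, stage, state = _GROUP_LABELS[label]
        a_mean, a_sd = config.group_area_params[label]
        s_mean, s_sd = config.group_seqeffect_params[label]
        stages = ("early", "mid_advanced")
        for i in range(n):
            profiles.append(
                SubjectProfile(
                    subject_id=f"{label}-{i:03d}",
                    group=group,
                    stage=stage if stage is not None else stages[i % 2],
                    state=state,
                    base_area_mm2=_truncated_normal(rng, a_mean, a_sd, 0.1 * a_mean),
                    seq_effect=_truncated_normal(rng, s_mean, s_sd, 0.1 * s_mean),
                )
            )
    return profiles


def row_area_profile(base_area_mm2: float, seq_effect: float, n_rows: int) -> np.ndarray:
    """Per-row target ink areas following a geometric size progression.

    The progression g(r) = A·ρ^(r-1) is normalized so the mean over the first
    half of the rows is 1 (hence those rows average ``base_area_mm2``) and the
    mean over the last half divided by the first-half mean equals
    ``seq_effect``.  For 10 rows this is the last-5/first-5 ratio.
    """
    k = n_rows // 2
    rho = seq_effect ** (1.0 / (n_rows - k))
    g = rho ** np.arange(n_rows)
    g /= g[:k].mean()
    return base_area_mm2 * g


#: typical row ink area (mm²) at which the curve has its reference size;
#: smaller target areas shrink the written line (micrographia: smaller
#: letters at roughly constant pen width), larger ones enlarge it.
_REFERENCE_AREA_MM2 = 110.0


def _stroke_skeleton(
    shape: tuple[int, int],
    rng: np.random.Generator,
    extent: float,
    cycles_per_mm: float,
    calibration: float,
    scale: float = 1.0,
) -> np.ndarray:
    """Rasterize a cursive-like oscillatory curve skeleton inside a band.

    The curve starts at the left of the band and sweeps rightward across
    ``extent`` of the band width, with a two-harmonic vertical oscillation
    emulating connected letterforms.  ``scale`` shrinks or enlarges the whole
    written line (extent, amplitude and oscillation wavelength together), the
    way letter size varies at constant pen width.  Returns a boolean skeleton
    image of the band shape.
    """
    h, w = shape
    span = extent * min(scale, 0.98 / extent)
    n_cols = max(int(w * span), 8)
    x = np.arange(n_cols)
    length_mm = n_cols * calibration
    n_cyc = max(2.0, length_mm * cycles_per_mm / max(scale, 0.25))
    phase = rng.uniform(0, 2 * np.pi, size=2)
    t = x / max(n_cols - 1, 1)
    amp = min(0.20 * h * scale, 0.38 * h)
    y = (h - 1) / 2.0 + amp * (
        0.72 * np.sin(2 * np.pi * n_cyc * t + phase[0])
        + 0.28 * np.sin(2 * np.pi * 2.33 * n_cyc * t + phase[1])
    )
    y = np.clip(np.round(y).astype(int), 0, h - 1)
    skel = np.zeros(shape, dtype=bool)
    for i in range(n_cols - 1):
        rr, cc = draw_line(y[i], x[i], y[i + 1], x[i + 1])
        skel[rr, cc] = True
    return skel


def _fill_to_area(
    skeleton: np.ndarray,
    target_px: float,
    tol: float = 0.02,
) -> np.ndarray:
    """Thicken a skeleton to hit a target ink-pixel count.

    Ink is the ``n`` pixels closest to the skeleton (by Euclidean distance
    transform), with ``n = round(target_px)``: a uniform stroke dilation whose
    pixel count matches the target exactly (up to rounding), strictly monotone
    in the target.  Ties at the stroke boundary are broken deterministically.
    """
    n = int(round(target_px))
    if skeleton.sum() > target_px * (1 + tol):
        raise GenerationError(
            f"target area {target_px:.0f} px below minimal stroke "
            f"({int(skeleton.sum())} px)"
        )
    if n > skeleton.size:
        raise GenerationError(
            f"target area {target_px:.0f} px exceeds the row band capacity "
            f"({skeleton.size} px)"
        )
    dist = ndimage.distance_transform_edt(~skeleton)
    # break ties at the stroke boundary left-to-right so the realized stroke
    # stays compact (the perturbation is far below EDT level spacing)
    dist = dist + 1e-9 * np.arange(skeleton.shape[1])[None, :]
    idx = np.argpartition(dist.ravel(), n - 1)[:n]
    mask = np.zeros(skeleton.size, dtype=bool)
    mask[idx] = True
    return mask.reshape(skeleton.shape)


# per-task curve settings: horizontal extent of the writing line and the
# oscillation density, tuned so a typical sentence row is written with a
# realistic ballpoint stroke width (~0.5 mm).
_TASK_STYLES: dict[str, tuple[float, float]] = {
    "name": (0.55, 0.06),
    "sentence": (0.95, 0.06),
}


def render_sheet(
    profile: SubjectProfile,
    task_id: str,
    config: GeneratorConfig,
    seed: int,
) -> tuple[np.ndarray, SheetGroundTruth]:
    """Render one grayscale page with ``rows_per_sheet`` pseudo-handwriting rows.

    Row r's target ink area is ``base_area_mm2`` times a geometric progression
    calibrated to the subject's sequence effect (see :func:`row_area_profile`).
    Stroke thickness is solved per row so the realized binarized area matches
    its target within 2%.  Returns the page and its ground truth.  Scan
    artifacts are *not* applied here; see :func:`add_scan_artifacts`.
    """
    rng = np.random.default_rng(seed)
    cal = config.calibration
    page_h, page_w = config.page_shape
    page = np.full((page_h, page_w), PAPER_LEVEL, dtype=np.uint8)

    margin_px = int(round(config.margin_mm / cal))
    content_h = page_h - 2 * margin_px
    band_h = content_h // config.rows_per_sheet
    pad = int(round(config.band_pad_frac * band_h))
    inner_h = band_h - 2 * pad
    inner_w = page_w - 2 * margin_px
    if inner_h < 8 or inner_w < 8:
        raise GenerationError("page geometry leaves no room for writing bands")

    extent, cycles_per_mm = _TASK_STYLES.get(task_id, _TASK_STYLES["sentence"])
    targets = row_area_profile(
        profile.base_area_mm2, profile.seq_effect, config.rows_per_sheet
    )

    realized: list[float] = []
    boxes: list[tuple[int, int, int, int]] = []
    for r in range(config.rows_per_sheet):
        target_px = targets[r] / cal**2
        scale = float(np.sqrt(targets[r] / _REFERENCE_AREA_MM2))
        skel = _stroke_skeleton(
            (inner_h, inner_w), rng, extent, cycles_per_mm, cal, scale=scale
        )
        try:
            mask = _fill_to_area(skel, target_px)
        except GenerationError as exc:
            raise GenerationError(f"row {r + 1}: {exc}") from exc
        y0 = margin_px + r * band_h + pad
        x0 = margin_px
        band = page[y0 : y0 + inner_h, x0 : x0 + inner_w]
        band[mask] = INK_LEVEL
        realized.append(float(mask.sum()) * cal**2)
        ys, xs = np.nonzero(mask)
        boxes.append(
            (x0 + int(xs.min()), y0 + int(ys.min()), x0 + int(xs.max()) + 1, y0 + int(ys.max()) + 1)
        )

    gt = SheetGroundTruth(
        subject_id=profile.subject_id,
        task_id=task_id,
        calibration=cal,
        target_areas_mm2=[float(a) for a in targets],
        realized_areas_mm2=realized,
        boxes=boxes,
    )
    return page, gt


def add_scan_artifacts(
    page: np.ndarray,
    params: ArtifactParams,
    seed: int,
) -> tuple[np.ndarray, float]:
    """Apply smartphone-scan artifacts: rotate → illumination gradient → noise.

    The rotation angle is drawn uniformly in ±``rotation_deg``; the gradient
    direction and noise field derive from ``seed``.  Returns the degraded page
    and the applied rotation angle (positive = counter-clockwise) so the
    calibration metadata can record it.
    """
    if params.is_identity:
        return page.copy(), 0.0
    rng = np.random.default_rng(seed)
    out = page.astype(float)
    angle = float(rng.uniform(-params.rotation_deg, params.rotation_deg))
    if params.rotation_deg > 0:
        out = ndimage.rotate(
            out, angle, reshape=False, order=1, mode="constant", cval=PAPER_LEVEL
        )
    if params.illumination > 0:
        h, w = out.shape
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (np.cos(theta) * xx / max(w - 1, 1)) + (np.sin(theta) * yy / max(h - 1, 1))
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
        out = out * (1.0 - params.illumination * ramp)
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd * 255.0, size=out.shape)
    return np.clip(np.round(out), 0, 255).astype(np.uint8), angle


def write_dataset(
    profiles: Sequence[SubjectProfile],
    config: GeneratorConfig,
    out_dir: str | Path,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Render and save one page per subject × task, plus a manifest CSV.

    Pages are 8-bit grayscale PNGs; per-sheet ground truth is saved as JSON
    alongside.  Scan artifacts are applied when ``config.artifact_params`` is
    set.  Refuses to clobber an existing manifest unless ``overwrite``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise ConfigurationError(f"{manifest_path} exists; pass overwrite=True")

    tasks = DEFAULT_TASKS[: config.tasks_per_subject]
    records = []
    for si, profile in enumerate(profiles):
        for ti, task in enumerate(tasks):
            sheet_seed = int(
                np.random.SeedSequence([config.seed, si, ti]).generate_state(1)[0]
                % (2**31)
            )
            page, gt = render_sheet(profile, task, config, sheet_seed)
            if config.artifact_params is not None:
                page, angle = add_scan_artifacts(
                    page, config.artifact_params, sheet_seed + 1
                )
                gt = replace(gt, rotation_deg=angle)
            stem = f"{profile.subject_id}_{task}"
            png_path = out_dir / f"{stem}.png"
            gt_path = out_dir / f"{stem}.gt.json"
            Image.fromarray(page, mode="L").save(png_path)
            gt_path.write_text(gt.to_json())
            records.append(
                {
                    "subject_id": profile.subject_id,
                    "group": profile.group,
                    "stage": profile.stage,
                    "state": profile.state,
                    "task_id": task,
                    "path": png_path.name,
                    "gt_path": gt_path.name,
                    "calibration_mm_per_px": config.calibration,
                }
            )
    manifest = pd.DataFrame(
        records,
        columns=[
            "subject_id",
            "group",
            "stage",
            "state",
            "task_id",
            "path",
            "gt_path",
            "calibration_mm_per_px",
        ],
    )
    manifest.to_csv(manifest_path, index=False)
    return manifest
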