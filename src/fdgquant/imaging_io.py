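"""On-disk formats and core domain containers.

A dynamic scan is stored as a 4-D NIfTI-1 volume (4th axis = time) holding
decay-corrected activity concentration in kBq/mL, accompanied by a JSON
sidecar with the frame schedule::

    {"frame_starts_s": [...], "frame_durations_s": [...], "units": "kBq/mL"}

VOI masks are integer-label NIfTI volumes on the identical voxel grid plus a
JSON label→organ name table.  Session metadata (injected activity, body
weight, blood glucose) travels in a flat CSV manifest, and all analysis
output is written as tidy CSV (subject, week, organ, metric, value, units).

Masks must share the image grid exactly; no resampling is performed.  Decay
correction is assumed to have been applied upstream during reconstruction and
is never re-applied here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    EmptyVoiError,
    FormatError,
    GridMismatchError,
    UnknownOrganError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Frame durations (seconds) of the 23-frame, 60-min dynamic mouse FDG
#: acquisition: 8x5 s, 2x10 s, 2x30 s, 3x60 s, 2x150 s, 2x300 s, 4x600 s.
FRAME_DURATIONS_23_S: tuple[int, ...] = (
    (5,) * 8 + (10,) * 2 + (30,) * 2 + (60,) * 3 + (150,) * 2 + (300,) * 2 + (600,) * 4
)

TIDY_COLUMNS = ("subject", "week", "organ", "metric", "value", "units")


def voxel_size_from_fov(fov_mm: float, matrix: int) -> float:
    """Voxel edge length (mm) implied by a field of view and matrix size."""
    if fov_mm <= 0 or matrix <= 0:
        raise ValidationError("field of view and matrix size must be positive")
    return fov_mm / matrix


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing, in seconds from injection.

    Frames must be contiguous, non-overlapping, start at zero and have
    strictly positive durations.  ``mid_times_min`` (start + duration/2,
    in minutes) is the reference time assigned to each frame-averaged
    TAC sample.
    """

    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)
        if starts.ndim != 1 or durs.ndim != 1 or starts.size != durs.size:
            raise ValidationError("frame starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ValidationError("schedule must contain at least one frame")
        if not np.all(np.isfinite(starts)) or not np.all(np.isfinite(durs)):
            raise ValidationError("frame timing must be finite")
        if np.any(durs <= 0):
            raise ValidationError("frame durations must be strictly positive")
        if starts[0] != 0:
            raise ValidationError("first frame must start at t=0")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1], rtol=0, atol=1e-9):
            raise ValidationError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_durations(cls, durations_s: Sequence[float]) -> "FrameSchedule":
        durs = np.asarray(durations_s, dtype=float)
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    def __len__(self) -> int:
        return int(self.frame_starts.size)

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def total_duration_s(self) -> float:
        return float(self.frame_ends[-1])

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes post-injection."""
        return (self.frame_starts + self.frame_durations / 2.0) / 60.0

    def to_sidecar(self, units: str = "kBq/mL") -> dict:
        return {
            "frame_starts_s": self.frame_starts.tolist(),
            "frame_durations_s": self.frame_durations.tolist(),
            "units": units,
        }


def mouse_dynamic_schedule() -> FrameSchedule:
    """The standard 23-frame, 60-min dynamic mouse FDG schedule."""
    return FrameSchedule.from_durations(FRAME_DURATIONS_23_S)


@dataclass
class DynamicImage:
    """4-D activity-concentration grid with frame timing and voxel geometry.

    ``values`` is indexed (x, y, z, frame) and holds decay-corrected activity
    concentration; ``voxel_spacing`` is the (dx, dy, dz) edge length in mm.
    """

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    schedule: FrameSchedule
    units: str = "kBq/mL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValidationError("dynamic image must be 4-D (x, y, z, frame)")
        if self.values.shape[3] != len(self.schedule):
            raise FormatError(
                f"image has {self.values.shape[3]} frames but schedule has "
                f"{len(self.schedule)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("image values must be finite")
        spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError("voxel spacing must be three positive lengths (mm)")
        self.voxel_spacing = spacing

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))


@dataclass
class VoiMask:
    """Integer label volume naming the organs drawn on an image's grid."""

    labels: np.ndarray
    label_names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("mask must be a 3-D label volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("mask labels must be integers")
        self.label_names = {int(k): str(v) for k, v in dict(self.label_names).items()}

    @property
    def organ_labels(self) -> dict[str, int]:
        return {name: label for label, name in self.label_names.items()}

    def check_compatible(self, image: DynamicImage) -> None:
        if self.labels.shape != image.spatial_shape:
            raise GridMismatchError(
                f"mask grid {self.labels.shape} does not match image grid "
                f"{image.spatial_shape}"
            )

    def voxels_for(self, organ: str) -> np.ndarray:
        """Boolean voxel selector for a named organ; raises if unknown/empty."""
        try:
            label = self.organ_labels[organ]
        except KeyError:
            raise UnknownOrganError(
                f"no label named {organ!r}; known: {sorted(self.organ_labels)}"
            ) from None
        sel = self.labels == label
        if not sel.any():
            raise EmptyVoiError(f"VOI {organ!r} (label {label}) covers no voxels")
        return sel


@dataclass
class ScanSession:
    """Per-scan metadata: subject, timing, dose, weight and blood glucose."""

    subject_id: str
    week: int
    injected_activity_mbq: float
    body_weight_g: float
    glucose_pre_mmol_l: float
    glucose_post_mmol_l: float | None = None
    route: str = "iv"
    image: DynamicImage | None = None
    mask: VoiMask | None = None

    def __post_init__(self) -> None:
        if self.week not in (1, 2, 3, 4):
            raise ValidationError(f"week must be 1-4, got {self.week}")
        if self.injected_activity_mbq <= 0:
            raise ValidationError("injected activity must be positive (MBq)")
        if self.body_weight_g <= 0:
            raise ValidationError("body weight must be positive (g)")
        if self.glucose_pre_mmol_l <= 0:
            raise ValidationError("blood glucose must be positive (mmol/L)")
        if self.glucose_post_mmol_l is not None and self.glucose_post_mmol_l <= 0:
            raise ValidationError("blood glucose must be positive (mmol/L)")
        if self.route not in ("iv", "ip"):
            raise ValidationError("administration route must be 'iv' or 'ip'")


# ---------------------------------------------------------------------------
# readers / writers


def _affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def read_dynamic_image(volume_path: str | Path, sidecar_path: str | Path) -> DynamicImage:
    """Load a 4-D NIfTI volume and its JSON frame-schedule sidecar."""
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{volume_path}: expected a 4-D volume, got {data.ndim}-D")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    try:
        starts = sidecar["frame_starts_s"]
        durs = sidecar["frame_durations_s"]
    except KeyError as exc:
        raise FormatError(f"{sidecar_path}: missing sidecar field {exc}") from None
    if len(starts) != data.shape[3] or len(durs) != data.shape[3]:
        raise FormatError(
            f"{sidecar_path}: sidecar lists {len(starts)} frames but volume has "
            f"{data.shape[3]} time points"
        )
    schedule = FrameSchedule(np.asarray(starts, float), np.asarray(durs, float))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicImage(
        values=data,
        voxel_spacing=spacing,
        schedule=schedule,
        units=sidecar.get("units", "kBq/mL"),
    )


def write_dynamic_image(
    image: DynamicImage, volume_path: str | Path, sidecar_path: str | Path
) -> None:
    nifti = nib.Nifti1Image(image.values.astype(np.float64), _affine_from_spacing(image.voxel_spacing))
    nifti.header.set_zooms(image.voxel_spacing + (1.0,))
    nib.save(nifti, str(volume_path))
    with open(sidecar_path, "w") as fh:
        json.dump(image.schedule.to_sidecar(image.units), fh, indent=1)


def read_mask_set(mask_path: str | Path, names_path: str | Path) -> VoiMask:
    """Load an integer-label NIfTI mask plus its JSON label→organ table."""
    img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{mask_path}: mask voxels are not integer labels")
    data = np.round(data).astype(np.int32)
    if data.ndim != 3:
        raise FormatError(f"{mask_path}: expected a 3-D label volume, got {data.ndim}-D")
    with open(names_path) as fh:
        raw = json.load(fh)
    names = {int(k): str(v) for k, v in raw.items()}
    return VoiMask(labels=data, label_names=names)


def write_mask_set(mask: VoiMask, mask_path: str | Path, names_path: str | Path,
                   voxel_spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> None:
    nifti = nib.Nifti1Image(mask.labels.astype(np.int32), _affine_from_spacing(voxel_spacing))
    nib.save(nifti, str(mask_path))
    with open(names_path, "w") as fh:
        json.dump({str(k): v for k, v in mask.label_names.items()}, fh, indent=1)


_MANIFEST_COLUMNS = {
    "subject_id": str,
    "week": int,
    "injected_activity_mbq": float,
    "body_weight_g": float,
    "glucose_pre_mmol_l": float,
}


def load_session_manifest(manifest_path: str | Path) -> list[ScanSession]:
    """Read a CSV manifest (one row per scan) into validated sessions.

    A missing ``glucose_post_mmol_l`` is tolerated with a logged warning;
    downstream glucose averaging then falls back to the pre-scan value.
    Rows are returned sorted by (subject_id, week).
    """
    df = pd.read_csv(manifest_path)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{manifest_path}: missing manifest columns {sorted(missing)}")
    sessions: list[ScanSession] = []
    for _, row in df.iterrows():
        post = row.get("glucose_post_mmol_l", np.nan)
        if post is None or (isinstance(post, float) and np.isnan(post)):
            logger.warning(
                "subject %s week %s: no post-scan glucose; using pre-scan value",
                row["subject_id"], row["week"],
            )
            post = None
        sessions.append(
            ScanSession(
                subject_id=str(row["subject_id"]),
                week=int(row["week"]),
                injected_activity_mbq=float(row["injected_activity_mbq"]),
                body_weight_g=float(row["body_weight_g"]),
                glucose_pre_mmol_l=float(row["glucose_pre_mmol_l"]),
                glucose_post_mmol_l=None if post is None else float(post),
                route=str(row.get("route", "iv")),
            )
        )
    sessions.sort(key=lambda s: (s.subject_id, s.week))
    return sessions


def write_session_manifest(sessions: Iterable[ScanSession], manifest_path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "week": s.week,
            "injected_activity_mbq": s.injected_activity_mbq,
            "body_weight_g": s.body_weight_g,
            "glucose_pre_mmol_l": s.glucose_pre_mmol_l,
            "glucose_post_mmol_l": s.glucose_post_mmol_l,
            "route": s.route,
        }
        for s in sessions
    ]
    pd.DataFrame(rows).to_csv(manifest_path, index=False)


def write_tidy_results(
    records: Iterable[Mapping] | pd.DataFrame, out_path: str | Path
) -> pd.DataFrame:
    """Write analysis records as a tidy CSV with a stable column and row order.

    Rows are sorted by (subject, week, organ, metric) so repeated runs are
    byte-identical; an empty record list yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        df = pd.DataFrame(columns=TIDY_COLUMNS)
    missing = set(TIDY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"tidy records missing columns {sorted(missing)}")
    df = df.loc[:, list(TIDY_COLUMNS)]
    if not df.empty:
        df = df.sort_values(["subject", "week", "organ", "metric"], kind="mergesort")
    df.to_csv(out_path, index=False)
    return df.reset_index(drop=True)


def read_tidy_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
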