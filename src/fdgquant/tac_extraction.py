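"""Time–activity curves, SUV conversion and static uptake metrics.

A TAC is the per-frame unweighted mean of the activity concentration over the
member voxels of a VOI, referenced to the frame mid-time.  SUV follows the
body-weight convention with tissue density taken as 1 g/mL (the universal
rodent convention):

    SUV(t) = C(t) [kBq/mL] / (1000 * injected_activity [MBq] / body_weight [g])

SUVglu multiplies SUV by the scan-averaged blood glucose (mmol/L), a
glucose-corrected semiquantitative uptake metric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import UnitError, ValidationError
from .imaging_io import DynamicImage, ScanSession, VoiMask
from .kinetics import average_blood_glucose, suv_glu

SUV_UNITS = "SUV"


@dataclass
class TimeActivityCurve:
    """Mean activity of one VOI per frame.

    ``values`` are in kBq/mL, or unitless SUV after :func:`tac_to_suv`
    (flagged by ``units``).  ``mid_times_min`` is strictly increasing and has
    one entry per frame.
    """

    mid_times_min: np.ndarray
    values: np.ndarray
    organ: str
    n_voxels: int
    units: str = "kBq/mL"

    def __post_init__(self) -> None:
        self.mid_times_min = np.asarray(self.mid_times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mid_times_min.shape != self.values.shape or self.mid_times_min.ndim != 1:
            raise ValidationError("TAC times and values must be matching 1-D arrays")
        if np.any(np.diff(self.mid_times_min) <= 0):
            raise ValidationError("TAC times must be strictly increasing")
        if self.n_voxels < 1:
            raise ValidationError("a TAC needs at least one member voxel")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class UptakeMetrics:
    """Static VOI uptake: SUV mean/max, glucose-corrected variants, volume."""

    suv_mean: float
    suv_max: float
    suvglu_mean: float
    suvglu_max: float
    volume_mm3: float

    def __post_init__(self) -> None:
        if not (self.suv_max >= self.suv_mean >= 0):
            raise ValidationError("requires suv_max >= suv_mean >= 0")
        if self.volume_mm3 <= 0:
            raise ValidationError("VOI volume must be positive")


def extract_tac(image: DynamicImage, mask: VoiMask, organ: str) -> TimeActivityCurve:
    """Per-frame unweighted mean over the voxels of the named VOI."""
    mask.check_compatible(image)
    sel = mask.voxels_for(organ)
    values = image.values[sel].mean(axis=0)
    return TimeActivityCurve(
        mid_times_min=image.schedule.mid_times_min,
        values=values,
        organ=organ,
        n_voxels=int(sel.sum()),
        units=image.units,
    )


def suv_scale(injected_activity_mbq: float, body_weight_g: float) -> float:
    """kBq/mL per SUV unit: 1000 * MBq / g (density 1 g/mL)."""
    if injected_activity_mbq <= 0 or body_weight_g <= 0:
        raise ValidationError("injected activity and body weight must be positive")
    return 1000.0 * injected_activity_mbq / body_weight_g


def tac_to_suv(
    tac: TimeActivityCurve, injected_activity_mbq: float, body_weight_g: float
) -> TimeActivityCurve:
    """Convert a kBq/mL TAC to SUV units."""
    if tac.units != "kBq/mL":
        raise UnitError(f"expected a TAC in kBq/mL, got {tac.units!r}")
    scale = suv_scale(injected_activity_mbq, body_weight_g)
    return replace(tac, values=tac.values / scale, units=SUV_UNITS)


def tac_auc(tac: TimeActivityCurve, t0_min: float, t1_min: float) -> float:
    """Trapezoidal area under the TAC between two times (minutes).

    A virtual (0, 0) point is prepended — activity at injection is zero — so
    integration may start at t=0 even though the first frame mid-time is
    later.  Past the last mid-time the curve is held flat at its final
    frame-mean value, so the conventional 0-60 min AUC covers the trailing
    half of the last frame.  Returns kBq·min/mL (or SUV·min for an SUV
    curve).
    """
    if t1_min < t0_min:
        raise ValidationError("AUC bounds are reversed")
    times = np.concatenate([[0.0], tac.mid_times_min])
    vals = np.concatenate([[0.0], tac.values])
    if t0_min < 0:
        raise ValidationError("AUC bounds must be nonnegative")
    if t0_min == t1_min:
        return 0.0
    grid = np.unique(np.concatenate([times, [t0_min, t1_min]]))
    grid = grid[(grid >= t0_min) & (grid <= t1_min)]
    interp = np.interp(grid, times, vals)
    return float(np.trapezoid(interp, grid))


def static_uptake_metrics(
    image: DynamicImage,
    mask: VoiMask,
    organ: str,
    session: ScanSession,
    frame_index: int | None = None,
) -> UptakeMetrics:
    """SUV_mean, SUV_max, SUVglu and VOI volume from a static frame.

    ``image`` is either a single-frame static acquisition (the 45–60 min
    post-injection window image, used as-is) or a dynamic image with
    ``frame_index`` designating the frame to analyze.
    """
    mask.check_compatible(image)
    if frame_index is None:
        if image.values.shape[3] != 1:
            raise ValidationError(
                "dynamic image: designate the frame to analyze with frame_index"
            )
        frame_index = 0
    sel = mask.voxels_for(organ)
    voxels = image.values[sel][:, frame_index]
    scale = suv_scale(session.injected_activity_mbq, session.body_weight_g)
    suv_voxels = voxels / scale
    suv_mean = float(suv_voxels.mean())
    suv_max = float(suv_voxels.max())
    cglu = average_blood_glucose(session.glucose_pre_mmol_l, session.glucose_post_mmol_l)
    return UptakeMetrics(
        suv_mean=suv_mean,
        suv_max=suv_max,
        suvglu_mean=suv_glu(suv_mean, cglu),
        suvglu_max=suv_glu(suv_max, cglu),
        volume_mm3=float(sel.sum()) * image.voxel_volume_mm3,
    )
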