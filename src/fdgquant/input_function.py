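"""Image-derived plasma input function (IDIF).

The whole-blood curve is taken from a vena-cava VOI, rescaled so its
last-frame value matches the liver curve's last-frame value (the liver VOI is
large and far less affected by partial volume than the narrow vena cava), and
converted to plasma with a time-dependent plasma-to-blood equilibrium ratio

    r(t) = r_eq + (r0 - r_eq) * exp(-t / tau_r),      plasma = blood * r(t).

"Last time frame" means the final frame's mean value as extracted — no
tail-fitting or smoothing — and no dispersion or delay correction is applied
between the vena cava and tissue curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError, ParameterError, ValidationError
from .tac_extraction import TimeActivityCurve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlasmaBloodRatio:
    """Saturating-exponential plasma-to-blood equilibrium ratio.

    r0 is the ratio at injection, r_eq the late equilibrium value, tau_r the
    approach time constant in minutes.  For FDG in mice plasma activity
    exceeds whole blood at late times (r_eq > 1) because erythrocyte uptake
    lags.
    """

    r0: float = 1.0
    r_eq: float = 1.2
    tau_r_min: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_r_min <= 0:
            raise ParameterError("ratio time constant must be positive")
        if self.r0 <= 0 or self.r_eq <= 0:
            raise ParameterError("plasma-to-blood ratio must stay positive")

    def __call__(self, t_min: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_min, dtype=float)
        r = self.r_eq + (self.r0 - self.r_eq) * np.exp(-t / self.tau_r_min)
        if np.any(r <= 0):
            raise ParameterError("plasma-to-blood ratio is nonpositive on the grid")
        return r if t.ndim else float(r)


@dataclass
class InputFunction:
    """Plasma activity curve C_p(t) on the acquisition time grid.

    ``scale_factor`` and ``ratio_params`` record how the curve was derived
    from the raw vena-cava TAC (provenance for the IDIF).
    """

    mid_times_min: np.ndarray
    plasma_values: np.ndarray
    scale_factor: float = 1.0
    ratio_params: PlasmaBloodRatio | None = None

    def __post_init__(self) -> None:
        self.mid_times_min = np.asarray(self.mid_times_min, dtype=float)
        self.plasma_values = np.asarray(self.plasma_values, dtype=float)
        if self.mid_times_min.shape != self.plasma_values.shape:
            raise ValidationError("input-function times and values must match")
        if not np.all(np.isfinite(self.plasma_values)):
            raise ValidationError("input-function values must be finite")
        if self.scale_factor <= 0:
            raise ValidationError("IDIF scale factor must be positive")


def _clip_negatives(tac: TimeActivityCurve) -> TimeActivityCurve:
    # reconstruction corrections can push VOI means below zero
    n_neg = int(np.sum(tac.values < 0))
    if n_neg:
        logger.warning("clipped %d negative values in %s TAC before scaling",
                       n_neg, tac.organ)
        return replace(tac, values=np.clip(tac.values, 0.0, None))
    return tac


def scale_vena_cava_to_liver(
    vc_tac: TimeActivityCurve, liver_tac: TimeActivityCurve
) -> tuple[TimeActivityCurve, float]:
    """Rescale the vena-cava TAC so its last frame matches the liver's.

    Returns the scaled whole-blood curve and the scale factor
    liver(T_last) / vc(T_last).  The output's last-frame value equals the
    liver last-frame value exactly; the curve shape is preserved.
    """
    if vc_tac.mid_times_min.shape != liver_tac.mid_times_min.shape or not np.allclose(
        vc_tac.mid_times_min, liver_tac.mid_times_min
    ):
        raise ValidationError("vena-cava and liver TACs must share one time grid")
    vc_tac = _clip_negatives(vc_tac)
    liver_tac = _clip_negatives(liver_tac)
    vc_last = float(vc_tac.values[-1])
    if vc_last <= 0:
        raise DegenerateInputError("vena-cava last-frame value is not positive")
    scale_factor = float(liver_tac.values[-1]) / vc_last
    if scale_factor <= 0:
        raise DegenerateInputError("liver last-frame value is not positive")
    scaled = replace(vc_tac, values=vc_tac.values * scale_factor)
    return scaled, scale_factor


def plasma_input_from_blood(
    blood_tac: TimeActivityCurve, ratio_params: PlasmaBloodRatio
) -> InputFunction:
    """Apply the plasma-to-blood ratio: plasma(t) = blood(t) * r(t)."""
    r = ratio_params(blood_tac.mid_times_min)
    return InputFunction(
        mid_times_min=blood_tac.mid_times_min,
        plasma_values=blood_tac.values * r,
        scale_factor=1.0,
        ratio_params=ratio_params,
    )


def build_input_function(
    vc_tac: TimeActivityCurve,
    liver_tac: TimeActivityCurve,
    ratio_params: PlasmaBloodRatio | None = None,
) -> InputFunction:
    """Full IDIF pipeline: scale vena cava to liver, then convert to plasma."""
    ratio_params = ratio_params or PlasmaBloodRatio()
    scaled, scale_factor = scale_vena_cava_to_liver(vc_tac, liver_tac)
    input_fn = plasma_input_from_blood(scaled, ratio_params)
    input_fn.scale_factor = scale_factor
    return input_fn
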