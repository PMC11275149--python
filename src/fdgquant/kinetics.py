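"""Patlak graphical analysis and the glucose-metric algebra.

For an irreversibly trapped tracer such as [18F]FDG, plotting

    y(T) = C_ROI(T) / C_p(T)    against    x(T) = ∫0..T C_p(t) dt / C_p(T)

becomes linear once the exchangeable compartments have equilibrated; the
slope of the late-time line is the net influx rate Ki (mL plasma cleared per
minute per mL tissue) and the intercept approximates the exchangeable
distribution volume.  In this pipeline the plot is treated as linear after
t* = 10 min and points are included by frame mid-time.

From Ki the metabolic rate of glucose follows as

    MRGlu = Cglu * Ki / LC        [µmol·min⁻¹·mL⁻¹]

with Cglu the scan-averaged blood glucose in mmol/L (≡ µmol/mL) and LC the
organ-specific lumped constant converting FDG flux to glucose flux:
LC = 1 (tumor), 0.625 (brain), 0.67 (heart).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import integrate, stats

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    MissingDataError,
    SingularFitError,
    UnknownOrganError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .input_function import InputFunction
    from .tac_extraction import TimeActivityCurve

logger = logging.getLogger(__name__)

#: Organ-specific lumped constants (unitless).
LUMPED_CONSTANTS: dict[str, float] = {"tumor": 1.0, "brain": 0.625, "heart": 0.67}

DEFAULT_T_STAR_MIN = 10.0


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak plot coordinates with per-frame inclusion flags.

    ``x`` is the normalized plasma integral (minutes — "funny time"), ``y``
    the tissue-to-plasma ratio (unitless).  ``included`` marks frames with
    mid-time >= t*.
    """

    mid_times_min: np.ndarray
    x: np.ndarray
    y: np.ndarray
    included: np.ndarray
    t_star_min: float


@dataclass(frozen=True)
class PatlakResult:
    """Least-squares line through the included Patlak points."""

    ki: float
    intercept: float
    r_squared: float
    t_star_min: float
    n_points: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("a Patlak fit needs at least 3 points")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class MetabolicResult:
    """Glucose metabolic rate derived from a Patlak Ki."""

    mrglu: float  # µmol·min⁻¹·mL⁻¹
    cglu_mean_mmol_l: float
    lumped_constant: float
    ki: float

    def __post_init__(self) -> None:
        if self.lumped_constant <= 0:
            raise ValidationError("lumped constant must be positive")
        if np.sign(self.mrglu) != np.sign(self.ki) and self.ki != 0:
            raise ValidationError("MRGlu must carry the sign of Ki")


def cumulative_plasma_integral(mid_times_min: np.ndarray, plasma: np.ndarray) -> np.ndarray:
    """Trapezoidal ∫0..T C_p dt at each frame mid-time, anchored at (0, 0)."""
    times = np.concatenate([[0.0], np.asarray(mid_times_min, float)])
    vals = np.concatenate([[0.0], np.asarray(plasma, float)])
    return integrate.cumulative_trapezoid(vals, times)


def patlak_points(
    tissue_tac: "TimeActivityCurve",
    input_fn: "InputFunction",
    t_star_min: float = DEFAULT_T_STAR_MIN,
    tissue_as_auc: bool = False,
) -> PatlakPoints:
    """Patlak plot coordinates for one tissue curve against a plasma input.

    ``tissue_as_auc`` replaces the conventional tissue term C_ROI(T) with the
    tissue AUC from 0 to T.  This non-standard reading is exposed for
    comparison only and is never the default.
    """
    t = np.asarray(tissue_tac.mid_times_min, float)
    cp = np.asarray(input_fn.plasma_values, float)
    if t.shape != np.asarray(input_fn.mid_times_min).shape or not np.allclose(
        t, input_fn.mid_times_min
    ):
        raise ValidationError("tissue TAC and input function must share one time grid")
    included = t >= t_star_min
    if included.sum() < 3:
        raise InsufficientDataError(
            f"only {int(included.sum())} frames at mid-time >= {t_star_min} min; "
            "need at least 3"
        )
    if np.any(cp[included] <= 0):
        raise DegenerateInputError("plasma activity is zero/negative at an included frame")
    cum_cp = cumulative_plasma_integral(t, cp)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(cp > 0, cum_cp / cp, np.nan)
        if tissue_as_auc:
            ct = np.asarray(tissue_tac.values, float)
            cum_ct = cumulative_plasma_integral(t, ct)
            y = np.where(cp > 0, cum_ct / cp, np.nan)
        else:
            y = np.where(cp > 0, np.asarray(tissue_tac.values, float) / cp, np.nan)
    return PatlakPoints(mid_times_min=t, x=x, y=y, included=included, t_star_min=t_star_min)


def patlak_fit(points: PatlakPoints) -> PatlakResult:
    """Ordinary least squares on the included Patlak points.

    Ki is the slope, Int the intercept.  A zero-variance y (flat plot) is a
    degenerate fit: Ki = 0, Int = mean(y), R² reported as 0 with the
    ``degenerate`` flag set.
    """
    x = points.x[points.included]
    y = points.y[points.included]
    if x.size < 3:
        raise InsufficientDataError("need at least 3 included Patlak points")
    if np.ptp(x) == 0:
        raise SingularFitError("all Patlak abscissae identical; slope undefined")
    if np.ptp(y) == 0:
        return PatlakResult(
            ki=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            t_star_min=points.t_star_min,
            n_points=int(x.size),
            degenerate=True,
        )
    fit = stats.linregress(x, y)
    return PatlakResult(
        ki=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        t_star_min=points.t_star_min,
        n_points=int(x.size),
    )


def average_blood_glucose(
    pre_mmol_l: float, post_mmol_l: float | None = None
) -> float:
    """Mean of the pre- and post-scan glucometer readings (mmol/L).

    Falls back to the pre-scan value, with a logged warning, when the
    post-scan reading is missing.
    """
    if pre_mmol_l is None and post_mmol_l is None:
        raise MissingDataError("no blood glucose measurement available")
    if pre_mmol_l is None:
        pre_mmol_l, post_mmol_l = post_mmol_l, None
    if pre_mmol_l <= 0 or (post_mmol_l is not None and post_mmol_l <= 0):
        raise ValidationError("blood glucose must be positive (mmol/L)")
    if post_mmol_l is None:
        logger.warning("post-scan glucose missing; using single measurement %.2f mmol/L",
                       pre_mmol_l)
        return float(pre_mmol_l)
    return float((pre_mmol_l + post_mmol_l) / 2.0)


def metabolic_rate_glucose(
    ki: float,
    cglu_mean_mmol_l: float,
    organ: str | None = None,
    lumped_constant: float | None = None,
) -> MetabolicResult:
    """MRGlu = Cglu * Ki / LC, in µmol·min⁻¹·mL⁻¹.

    The lumped constant is looked up by organ (tumor/brain/heart) unless
    supplied explicitly.
    """
    if lumped_constant is None:
        if organ is None or organ not in LUMPED_CONSTANTS:
            raise UnknownOrganError(
                f"no lumped constant for organ {organ!r}; supply lumped_constant "
                f"or use one of {sorted(LUMPED_CONSTANTS)}"
            )
        lumped_constant = LUMPED_CONSTANTS[organ]
    mrglu = cglu_mean_mmol_l * ki / lumped_constant
    return MetabolicResult(
        mrglu=float(mrglu),
        cglu_mean_mmol_l=float(cglu_mean_mmol_l),
        lumped_constant=float(lumped_constant),
        ki=float(ki),
    )


def suv_glu(suv: float, cglu_mean_mmol_l: float) -> float:
    """Glucose-corrected SUV: SUVglu = SUV * Cglu (SUV·mmol/L)."""
    if suv < 0 or cglu_mean_mmol_l < 0:
        raise ValidationError("SUV and glucose must be nonnegative")
    return float(suv * cglu_mean_mmol_l)
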