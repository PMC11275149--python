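"""Phantom scan sessions and growth cohorts with known ground truth.

No public imaging dataset accompanies the study design this pipeline serves,
so every downstream stage is exercised on synthetic data built here:

* an arterial plasma input from the Feng tri-exponential family (the standard
  parametric FDG input with a recirculation term),
* organ time–activity curves from the irreversible two-tissue compartment
  model (net influx Ki = K1*k3/(k2+k3)),
* a whole-blood vena-cava curve related to plasma by the time-dependent
  plasma-to-blood equilibrium ratio,
* a voxelized ellipsoid phantom sampled on the 23-frame/60-min mouse
  acquisition schedule, with optional counting-statistics-like noise,
* exponential tumor-growth cohorts calibrated to the published weekly mean
  volumes.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import ConfigError, ParameterError
from .imaging_io import (
    DynamicImage,
    FrameSchedule,
    ScanSession,
    VoiMask,
    mouse_dynamic_schedule,
)
from .input_function import PlasmaBloodRatio

# Week-1 dynamic-cohort session means (MBq, g, mmol/L) used as simulation
# defaults throughout.
DEFAULT_INJECTED_ACTIVITY_MBQ = 9.0
DEFAULT_BODY_WEIGHT_G = 25.9
DEFAULT_BLOOD_GLUCOSE_MMOL_L = 9.9

#: Published weekly mean tumor volumes (mm³) at the mean MR-scan days after
#: implantation; the calibration anchor for the growth generator.
WEEKLY_MEAN_VOLUME_DAYS = np.array([7.7, 15.0, 22.0, 29.0])
WEEKLY_MEAN_VOLUMES_MM3 = np.array([18.0, 44.0, 127.0, 332.0])

#: Cohort-level doubling time (days) reported from per-animal growth fits.
REPORTED_DOUBLING_TIME_DAYS = 6.4


# ---------------------------------------------------------------------------
# kinetic ground truth and input model


@dataclass(frozen=True)
class KineticGroundTruth:
    """Irreversible two-tissue-compartment rate constants.

    k1 in mL·min⁻¹·mL⁻¹, k2/k3 in min⁻¹, vb the fractional blood volume.
    The implied net influx rate is Ki = K1*k3/(k2+k3).
    """

    k1: float
    k2: float
    k3: float
    vb: float = 0.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 <= 0 or self.k3 < 0:
            raise ParameterError("need K1 >= 0, k2 > 0, k3 >= 0")
        if not (0.0 <= self.vb < 1.0):
            raise ParameterError("fractional blood volume must lie in [0, 1)")

    @property
    def ki(self) -> float:
        """Net influx rate K1*k3/(k2+k3), mL·min⁻¹·mL⁻¹."""
        return self.k1 * self.k3 / (self.k2 + self.k3)


@dataclass(frozen=True)
class InputModelParams:
    """Feng-style tri-exponential plasma input plus plasma-to-blood ratio.

    C_p(t) = (A1*t - A2 - A3)*exp(-l1*t) + A2*exp(-l2*t) + A3*exp(-l3*t),
    clipped at zero.  A's in kBq/mL (A1 in kBq/mL/min), decay rates in min⁻¹
    with l1 > l2 > l3 > 0.  Defaults give a realistic bolus peaking within
    the first minute; the intermediate clearance rate (l2, t½ ≈ 1.2 min)
    reflects the fast blood-pool clearance of mice, so that by the
    graphical-analysis start time t* = 10 min the tail is governed by the
    slow component alone and the late-time plot is linear to high accuracy.
    """

    a1: float = 851.1
    a2: float = 21.9
    a3: float = 20.8
    lambda1: float = 4.13
    lambda2: float = 0.6
    lambda3: float = 0.01
    ratio: PlasmaBloodRatio = field(default_factory=PlasmaBloodRatio)

    def __post_init__(self) -> None:
        if not (self.lambda1 > self.lambda2 > self.lambda3 > 0):
            raise ParameterError("decay rates must satisfy l1 > l2 > l3 > 0")
        if self.a1 < 0 or self.a2 < 0 or self.a3 < 0:
            raise ParameterError("input amplitudes must be nonnegative")


def feng_plasma_input(params: InputModelParams, times_min: np.ndarray) -> np.ndarray:
    """Evaluate the Feng plasma curve (kBq/mL) on a time grid (minutes)."""
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ParameterError("times must be a nonnegative increasing 1-D grid")
    cp = (
        (params.a1 * t - params.a2 - params.a3) * np.exp(-params.lambda1 * t)
        + params.a2 * np.exp(-params.lambda2 * t)
        + params.a3 * np.exp(-params.lambda3 * t)
    )
    return np.clip(cp, 0.0, None)


def blood_from_plasma(
    plasma: np.ndarray, times_min: np.ndarray, params: InputModelParams | PlasmaBloodRatio
) -> np.ndarray:
    """Whole-blood curve implied by a plasma curve: blood = plasma / r(t).

    Exact inverse of ``input_function.plasma_input_from_blood`` under the
    same ratio parameters.
    """
    ratio = params.ratio if isinstance(params, InputModelParams) else params
    r = ratio(np.asarray(times_min, dtype=float))
    return np.asarray(plasma, dtype=float) / r


# ---------------------------------------------------------------------------
# two-tissue forward model


def two_tissue_concentration(
    gt: KineticGroundTruth,
    times_min: np.ndarray,
    plasma: np.ndarray,
    blood: np.ndarray | None = None,
) -> np.ndarray:
    """Tissue concentration on a (fine) time grid for piecewise-linear plasma.

    Solves  dC1/dt = K1*Cp - (k2+k3)*C1,  dC2/dt = k3*C1  with C1(0)=C2(0)=0
    using the exact exponential update over each grid interval (the plasma
    curve is treated as linear within an interval), then returns
    (1-vb)*(C1+C2) + vb*Cb.  ``blood`` defaults to the plasma curve.
    """
    t = np.asarray(times_min, dtype=float)
    cp = np.asarray(plasma, dtype=float)
    if blood is None:
        blood = cp
    a = gt.k2 + gt.k3
    n = t.size
    c1 = np.zeros(n)
    if gt.k1 > 0:
        for i in range(n - 1):
            h = t[i + 1] - t[i]
            p0, p1 = cp[i], cp[i + 1]
            e = np.exp(-a * h)
            # exact integral of the linear segment against the exponential kernel
            integral = p1 * (1 - e) / a - (p1 - p0) * (1 - e - a * h * e) / (a * a * h)
            c1[i + 1] = c1[i] * e + gt.k1 * integral
    c2 = gt.k3 * integrate.cumulative_trapezoid(c1, t, initial=0.0)
    return (1.0 - gt.vb) * (c1 + c2) + gt.vb * np.asarray(blood, dtype=float)


def _fine_grid_min(schedule: FrameSchedule, dt_s: float) -> np.ndarray:
    n = int(round(schedule.total_duration_s / dt_s))
    return np.arange(n + 1) * dt_s / 60.0


def frame_average(
    fine_times_min: np.ndarray, curve: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Average a fine-grid curve over each acquisition frame.

    The fine grid must contain every frame boundary (use a step that divides
    all frame durations).
    """
    t_s = np.asarray(fine_times_min) * 60.0
    dt = t_s[1] - t_s[0]
    out = np.empty(len(schedule))
    for k, (start, dur) in enumerate(zip(schedule.frame_starts, schedule.frame_durations)):
        i0 = int(round(start / dt))
        i1 = int(round((start + dur) / dt))
        out[k] = np.trapezoid(curve[i0 : i1 + 1], t_s[i0 : i1 + 1]) / dur
    return out


def simulate_tissue_tac(
    gt: KineticGroundTruth,
    input_params: InputModelParams,
    schedule: FrameSchedule | None = None,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Frame-averaged noise-free tissue TAC (kBq/mL) for one organ."""
    schedule = schedule or mouse_dynamic_schedule()
    if dt_s <= 0 or dt_s > 1.0:
        raise ParameterError("internal ODE step must be positive and at most 1 s")
    fine = _fine_grid_min(schedule, dt_s)
    plasma = feng_plasma_input(input_params, fine)
    blood = blood_from_plasma(plasma, fine, input_params)
    tissue = two_tissue_concentration(gt, fine, plasma, blood)
    return frame_average(fine, tissue, schedule)


# ---------------------------------------------------------------------------
# voxelized phantom


@dataclass(frozen=True)
class OrganSpec:
    """An ellipsoidal organ: center as grid fractions, semi-axes in mm.

    ``kinetics=None`` marks a blood-pool region (filled with the whole-blood
    curve), used for the vena cava.
    """

    label: int
    center_frac: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    kinetics: KineticGroundTruth | None


def default_organs() -> dict[str, OrganSpec]:
    """Mouse-like organ layout with typical FDG rate constants.

    Tumor kinetics give Ki = 0.1*0.05/0.25 = 0.02 mL·min⁻¹·mL⁻¹.  Tumor and
    brain carry zero fractional blood volume so their graphical-analysis
    slope equals the compartmental Ki identically; heart and liver include a
    blood fraction.
    """
    return {
        "brain": OrganSpec(4, (0.50, 0.50, 0.10), (2.5, 2.5, 2.0),
                           KineticGroundTruth(0.15, 0.25, 0.06, 0.0)),
        "heart": OrganSpec(3, (0.50, 0.45, 0.30), (2.5, 2.5, 2.5),
                           KineticGroundTruth(0.70, 1.10, 0.10, 0.20)),
        "liver": OrganSpec(2, (0.55, 0.55, 0.52), (6.0, 5.0, 5.0),
                           KineticGroundTruth(0.60, 0.90, 0.01, 0.10)),
        "tumor": OrganSpec(1, (0.45, 0.30, 0.66), (2.0, 2.0, 2.0),
                           KineticGroundTruth(0.10, 0.20, 0.05, 0.0)),
        "vena_cava": OrganSpec(5, (0.25, 0.50, 0.42), (0.6, 0.6, 12.0), None),
    }


@dataclass
class PhantomConfig:
    """Everything needed to voxelize one synthetic scan session."""

    grid_shape: tuple[int, int, int] = (64, 64, 96)
    voxel_spacing: tuple[float, float, float] = (0.4, 0.4, 0.8)
    schedule: FrameSchedule = field(default_factory=mouse_dynamic_schedule)
    organs: dict[str, OrganSpec] = field(default_factory=default_organs)
    input_params: InputModelParams = field(default_factory=InputModelParams)
    #: liver last-frame value relative to whole-blood last-frame value; 1.0
    #: makes the vena-cava-to-liver IDIF rescaling exact by construction.
    liver_blood_last_frame_ratio: float = 1.0
    #: per-voxel Gaussian noise with SD = noise_level*sqrt(value/frame_min);
    #: 1.0 gives a few-percent SD on late 10-min frames, typical of mouse
    #: VOI data.  Set 0 for analytic phantoms.
    noise_level: float = 1.0
    subject_id: str = "phantom"
    week: int = 1
    injected_activity_mbq: float = DEFAULT_INJECTED_ACTIVITY_MBQ
    body_weight_g: float = DEFAULT_BODY_WEIGHT_G
    glucose_pre_mmol_l: float = DEFAULT_BLOOD_GLUCOSE_MMOL_L
    glucose_post_mmol_l: float = DEFAULT_BLOOD_GLUCOSE_MMOL_L
    route: str = "iv"
    ode_step_s: float = 1.0


@dataclass
class PhantomSession:
    """A generated session plus the ground truth needed for recovery tests."""

    session: ScanSession
    ground_truth: dict[str, KineticGroundTruth | None]
    organ_curves: dict[str, np.ndarray]  # noise-free frame-averaged TACs
    blood_curve: np.ndarray  # frame-averaged whole blood
    plasma_curve: np.ndarray  # frame-averaged plasma
    input_params: InputModelParams

    def ground_truth_dict(self) -> dict:
        out: dict = {"ki_true": {}, "rate_constants": {}}
        for organ, gt in self.ground_truth.items():
            if gt is None:
                continue
            out["ki_true"][organ] = gt.ki
            out["rate_constants"][organ] = {
                "K1": gt.k1, "k2": gt.k2, "k3": gt.k3, "vb": gt.vb
            }
        return out


def _ellipsoid_voxels(
    grid_shape: Sequence[int], spacing: Sequence[float], spec: OrganSpec
) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    center = [f * n * s for f, n, s in zip(spec.center_frac, grid_shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = sum(
        ((g - c) / a) ** 2
        for g, c, a in zip((xx, yy, zz), center, spec.semi_axes_mm)
    )
    return d2 <= 1.0


def build_phantom_session(
    config: PhantomConfig | None = None, seed: int = 0
) -> PhantomSession:
    """Voxelize a complete synthetic scan session.

    Each organ ellipsoid is filled with its simulated frame-averaged TAC, the
    vena-cava region with the whole-blood curve, and the liver curve is
    rescaled so its last-frame value equals the blood last-frame value times
    ``liver_blood_last_frame_ratio``.  Per-voxel noise (variance proportional
    to value over frame duration, a quadrature approximation to counting
    noise) is added and zero-clipped.  Fully reproducible for a fixed seed.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    schedule = config.schedule

    fine = _fine_grid_min(schedule, config.ode_step_s)
    plasma_fine = feng_plasma_input(config.input_params, fine)
    blood_fine = blood_from_plasma(plasma_fine, fine, config.input_params)
    plasma_frames = frame_average(fine, plasma_fine, schedule)
    blood_frames = frame_average(fine, blood_fine, schedule)

    organ_curves: dict[str, np.ndarray] = {}
    for organ, spec in config.organs.items():
        if spec.kinetics is None:
            organ_curves[organ] = blood_frames.copy()
        else:
            tissue_fine = two_tissue_concentration(
                spec.kinetics, fine, plasma_fine, blood_fine
            )
            organ_curves[organ] = frame_average(fine, tissue_fine, schedule)
    if "liver" in organ_curves:
        target_last = config.liver_blood_last_frame_ratio * blood_frames[-1]
        organ_curves["liver"] = organ_curves["liver"] * (
            target_last / organ_curves["liver"][-1]
        )

    labels = np.zeros(config.grid_shape, dtype=np.int32)
    values = np.zeros(config.grid_shape + (len(schedule),), dtype=float)
    for organ, spec in config.organs.items():
        sel = _ellipsoid_voxels(config.grid_shape, config.voxel_spacing, spec)
        if not sel.any():
            raise ConfigError(f"organ {organ!r} covers no voxels on this grid")
        if np.any(labels[sel] != 0):
            raise ConfigError(f"organ {organ!r} overlaps another organ")
        labels[sel] = spec.label
        values[sel] = organ_curves[organ]

    if config.noise_level > 0:
        dur_min = schedule.frame_durations / 60.0
        sigma = config.noise_level * np.sqrt(np.clip(values, 0.0, None) / dur_min)
        values = np.clip(values + rng.normal(0.0, 1.0, values.shape) * sigma, 0.0, None)

    image = DynamicImage(values=values, voxel_spacing=config.voxel_spacing,
                         schedule=schedule)
    mask = VoiMask(
        labels=labels,
        label_names={spec.label: organ for organ, spec in config.organs.items()},
    )
    session = ScanSession(
        subject_id=config.subject_id,
        week=config.week,
        injected_activity_mbq=config.injected_activity_mbq,
        body_weight_g=config.body_weight_g,
        glucose_pre_mmol_l=config.glucose_pre_mmol_l,
        glucose_post_mmol_l=config.glucose_post_mmol_l,
        route=config.route,
        image=image,
        mask=mask,
    )
    return PhantomSession(
        session=session,
        ground_truth={o: s.kinetics for o, s in config.organs.items()},
        organ_curves=organ_curves,
        blood_curve=blood_frames,
        plasma_curve=plasma_frames,
        input_params=config.input_params,
    )


# ---------------------------------------------------------------------------
# tumor-growth cohorts


@dataclass(frozen=True)
class GrowthModelParams:
    """Exponential growth with lognormal inter-animal and measurement noise.

    Volumes follow V_i(d) = V0 * g_i * 2^(d/Td) * eps_{i,d}; the lognormal
    factors g and eps are mean-one (log-mean −sigma²/2) so the cohort
    expectation is exactly V0 * 2^(d/Td).
    """

    v0_mm3: float
    doubling_time_days: float
    sigma_animal: float = 0.3
    sigma_meas: float = 0.1
    measurement_days: tuple[float, ...] = tuple(WEEKLY_MEAN_VOLUME_DAYS)

    def __post_init__(self) -> None:
        if self.v0_mm3 <= 0 or self.doubling_time_days <= 0:
            raise ParameterError("V0 and doubling time must be positive")
        if self.sigma_animal < 0 or self.sigma_meas < 0:
            raise ParameterError("noise SDs must be nonnegative")

    def mean_volume(self, day: float | np.ndarray) -> float | np.ndarray:
        """Closed-form cohort mean volume at a given day (mm³)."""
        return self.v0_mm3 * 2.0 ** (np.asarray(day, dtype=float) / self.doubling_time_days)


def _loglinear_growth_fit(days: np.ndarray, volumes: np.ndarray) -> tuple[float, float]:
    fit = stats.linregress(days, np.log(volumes))
    return float(np.exp(fit.intercept)), float(np.log(2.0) / fit.slope)


def growth_preset(name: str = "weekly-means", **overrides) -> GrowthModelParams:
    """Named growth parameterizations.

    ``weekly-means``: (V0, Td) from a log-linear least-squares fit of the
    published weekly mean volumes (18/44/127/332 mm³ at days 7.7/15/22/29) —
    the default study conditions.  ``reported-doubling``: the published
    6.4-day cohort doubling rate, with V0 chosen by least squares given that
    slope.
    """
    days, vols = WEEKLY_MEAN_VOLUME_DAYS, WEEKLY_MEAN_VOLUMES_MM3
    if name == "weekly-means":
        v0, td = _loglinear_growth_fit(days, vols)
    elif name == "reported-doubling":
        td = REPORTED_DOUBLING_TIME_DAYS
        v0 = float(np.exp(np.mean(np.log(vols) - np.log(2.0) / td * days)))
    else:
        raise ConfigError(f"unknown growth preset {name!r}")
    return GrowthModelParams(v0_mm3=v0, doubling_time_days=td, **overrides)


def generate_growth_cohort(
    params: GrowthModelParams, n_animals: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate per-animal weekly tumor volumes.

    Returns a tidy frame (subject_id, day, volume_mm3), one row per animal
    per measurement day, deterministic for a fixed seed.
    """
    if n_animals < 1:
        raise ParameterError("need at least one animal")
    rng = np.random.default_rng(seed)
    days = np.asarray(params.measurement_days, dtype=float)
    g = np.exp(rng.normal(0.0, params.sigma_animal, n_animals)
               - params.sigma_animal**2 / 2.0)
    eps = np.exp(rng.normal(0.0, params.sigma_meas, (n_animals, days.size))
                 - params.sigma_meas**2 / 2.0)
    vols = params.v0_mm3 * g[:, None] * 2.0 ** (days[None, :] / params.doubling_time_days) * eps
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat([f"M{i:04d}" for i in range(n_animals)], days.size),
            "day": np.tile(days, n_animals),
            "volume_mm3": vols.ravel(),
        }
    )
    return frame
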