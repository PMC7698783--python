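"""Virtual cohorts emulating a polymyxin B therapeutic-drug-monitoring study.

The generator reproduces the study conditions end to end: adult demographics
(age 51.5 ± 13.4 y, weight 69.7 ± 20.2 kg, CrCL 84 ± 47 mL/min, 12/13 male),
weight-guided q12h dosing (50/75/100 mg per dose targeting 1.7–3.0 mg/kg/day,
infused over 0.5–4 h), a four-sample design spanning one steady-state dosing
interval, and proportional assay error (default CV 5%).

Creatinine clearance is drawn first and serum creatinine back-solved through
the Cockcroft–Gault formula, so that re-deriving CrCL from the demographics
reproduces the drawn value exactly.  True clearance is by default drawn
independently of weight and CrCL (null covariate effect) from a log-normal
with median 2.5 L/h and a deliberately wide CV of 65%; an optional
weight-coupled mode (``cl_weight_power``) and a normal-on-CL mode
(``cl_dist="normal"``) support calibration experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .pkcore import (
    ConcentrationPoint,
    DosingRegimen,
    PKParams1C,
    PKParams2C,
    PKValidationError,
    auc24_from_cl,
    steady_state_conc,
)
from .poppk import Patient

__all__ = [
    "CohortSpec",
    "SimulatedSubject",
    "InfeasibleScheduleError",
    "generate_cohort",
    "assign_regimen",
    "draw_sample_times",
    "simulate_observations",
    "simulate_cohort",
    "subjects_to_frames",
]


class InfeasibleScheduleError(ValueError):
    """A sampling window is empty after clipping to the dosing interval."""


def _sigma_from_cv(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the virtual cohort.

    Demographic moments and dosing ranges default to the study population;
    the true-parameter distributions are stand-ins (the study reports no
    generative variances) chosen so the median terminal half-life matches
    the reported 6.8 h and between-subject clearance spread is substantial.
    """

    n_subjects: int = 13
    seed: int = 0

    age_mean_y: float = 51.5
    age_sd_y: float = 13.4
    weight_mean_kg: float = 69.7
    weight_sd_kg: float = 20.2
    crcl_mean_mL_min: float = 84.0
    crcl_sd_mL_min: float = 47.0
    male_fraction: float = 12.0 / 13.0

    dose_choices_mg: tuple[float, ...] = (50.0, 75.0, 100.0)
    tau_h: float = 12.0
    tinf_range_h: tuple[float, float] = (0.5, 4.0)
    daily_mg_per_kg_range: tuple[float, float] = (1.7, 3.0)

    true_order: int = 1
    cl_dist: str = "lognormal"  # or "normal"
    cl_median_L_h: float = 2.5
    cl_cv: float = 0.65
    cl_mean_L_h: float = 2.5  # normal mode only
    cl_sd_L_h: float = 0.75  # normal mode only
    cl_weight_power: float = 0.0  # 0 = null covariate effect
    v_median_L: float = 25.0
    v_cv: float = 0.30
    q_median_L_h: float = 3.0
    q_cv: float = 0.30
    v2_median_L: float = 30.0
    v2_cv: float = 0.30

    proportional_error_cv: float = 0.05

    # physiological truncation bounds
    age_bounds_y: tuple[float, float] = (21.0, 100.0)
    weight_bounds_kg: tuple[float, float] = (35.0, 140.0)
    crcl_bounds_mL_min: tuple[float, float] = (5.0, 300.0)
    cl_bounds_L_h: tuple[float, float] = (0.2, 20.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise PKValidationError("n_subjects must be >= 1")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise PKValidationError("male_fraction must be in [0, 1]")
        for name in ("age_sd_y", "weight_sd_kg", "crcl_sd_mL_min",
                     "proportional_error_cv", "cl_cv", "v_cv"):
            if getattr(self, name) < 0.0:
                raise PKValidationError(f"{name} must be >= 0")
        if self.true_order not in (1, 2):
            raise PKValidationError("true_order must be 1 or 2")
        if self.cl_dist not in ("lognormal", "normal"):
            raise PKValidationError("cl_dist must be 'lognormal' or 'normal'")
        lo, hi = self.daily_mg_per_kg_range
        if not (0 < lo < hi):
            raise PKValidationError("daily_mg_per_kg_range must be a positive interval")
        lo, hi = self.tinf_range_h
        if not (0 < lo <= hi <= self.tau_h):
            raise PKValidationError("tinf_range_h must lie within (0, tau_h]")


@dataclass(frozen=True)
class SimulatedSubject:
    """One virtual patient with truth, design, and noisy observations."""

    patient: Patient
    regimen: DosingRegimen
    true_params: PKParams1C | PKParams2C
    sample_times_h: tuple[float, float, float, float]
    observations: tuple[ConcentrationPoint, ...]

    @property
    def true_auc_mg_h_L(self) -> float:
        return auc24_from_cl(self.regimen.daily_dose_mg, self.true_params.cl_L_h)


@lru_cache(maxsize=64)
def _truncnorm_loc(target_mean: float, sd: float, bounds: tuple[float, float]) -> float:
    """Location of a truncated normal whose *truncated* mean equals the target.

    Truncating at physiological bounds shifts the realized mean away from the
    nominal one (noticeably for weight >= 35 kg and CrCL >= 5 mL/min); the
    location is recentred so the generated cohort reproduces the reported
    cohort moments.
    """
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    def gap(loc: float) -> float:
        a, b = (bounds[0] - loc) / sd, (bounds[1] - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(brentq(gap, target_mean - 5.0 * sd, target_mean + 5.0 * sd,
                        xtol=1e-9))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], match_mean: bool = True) -> float:
    if sd == 0.0:
        return float(min(max(mean, bounds[0]), bounds[1]))
    loc = _truncnorm_loc(mean, sd, bounds) if match_mean else mean
    for _ in range(10_000):
        x = rng.normal(loc, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    raise PKValidationError(
        f"could not draw within bounds {bounds} from N({mean}, {sd})"
    )


def generate_cohort(spec: CohortSpec,
                    rng: np.random.Generator | None = None) -> list[Patient]:
    """Draw ``n_subjects`` patients; serum creatinine is back-solved from CrCL.

    Deterministic under a fixed ``spec.seed`` (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    patients = []
    for i in range(spec.n_subjects):
        sex = "male" if rng.random() < spec.male_fraction else "female"
        age = _truncated_normal(rng, spec.age_mean_y, spec.age_sd_y, spec.age_bounds_y)
        weight = _truncated_normal(rng, spec.weight_mean_kg, spec.weight_sd_kg,
                                   spec.weight_bounds_kg)
        crcl = _truncated_normal(rng, spec.crcl_mean_mL_min, spec.crcl_sd_mL_min,
                                 spec.crcl_bounds_mL_min)
        # invert Cockcroft-Gault so that cockcroft_gault(...) == crcl
        sex_factor = 0.85 if sex == "female" else 1.0
        scr = (140.0 - age) * weight * sex_factor / (72.0 * crcl)
        patients.append(
            Patient(id=f"S{i + 1:03d}", age_y=age, sex=sex, weight_kg=weight,
                    scr_mg_dL=scr)
        )
    return patients


def assign_regimen(p: Patient, rng: np.random.Generator,
                   spec: CohortSpec | None = None) -> DosingRegimen:
    """Choose a q12h dose so the daily mg/kg lands in the target range.

    Doses with daily exposure inside [1.7, 3.0] mg/kg are sampled uniformly;
    if none of the available strengths is feasible for the patient's weight
    (very light or very heavy patients), the nearest-feasible strength is
    used.  Infusion duration is uniform over the allowed range.
    """
    if spec is None:
        spec = CohortSpec()
    lo, hi = spec.daily_mg_per_kg_range
    per_day = 24.0 / spec.tau_h
    feasible = [d for d in spec.dose_choices_mg
                if lo <= d * per_day / p.weight_kg <= hi]
    if feasible:
        dose = feasible[int(rng.integers(len(feasible)))]
    else:
        target = 0.5 * (lo + hi)
        dose = min(spec.dose_choices_mg,
                   key=lambda d: abs(d * per_day / p.weight_kg - target))
    tinf = float(rng.uniform(*spec.tinf_range_h))
    return DosingRegimen(dose_mg=float(dose), tau_h=spec.tau_h, tinf_h=tinf)


def draw_sample_times(r: DosingRegimen,
                      rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Four sample times per the study windows, all within [0, tau].

    1. within 0.5 h before the next dose;
    2. 0.5–1 h after the end of the infusion;
    3. 3–8 h after the end of the infusion (clipped at the interval end);
    4. within 4 h before the next dose.
    """
    tau, tinf = r.tau_h, r.tinf_h
    windows = [
        (max(tau - 0.5, 0.0), tau),
        (tinf + 0.5, tinf + 1.0),
        (tinf + 3.0, min(tinf + 8.0, tau)),
        (max(tau - 4.0, 0.0), tau),
    ]
    times = []
    for i, (lo, hi) in enumerate(windows, start=1):
        lo, hi = max(lo, 0.0), min(hi, tau)
        if not (lo < hi) or lo >= tau:
            raise InfeasibleScheduleError(
                f"sampling window {i} is empty after clipping to [0, {tau}] h "
                f"(infusion duration {tinf} h)"
            )
        times.append(float(rng.uniform(lo, hi)))
    return tuple(times)


def _draw_true_params(spec: CohortSpec, p: Patient, rng: np.random.Generator):
    if spec.cl_dist == "normal":
        cl = _truncated_normal(rng, spec.cl_mean_L_h, spec.cl_sd_L_h, spec.cl_bounds_L_h)
    else:
        mu = math.log(spec.cl_median_L_h)
        if spec.cl_weight_power != 0.0:
            mu += spec.cl_weight_power * math.log(p.weight_kg / 70.0)
        for _ in range(10_000):
            cl = float(rng.lognormal(mu, _sigma_from_cv(spec.cl_cv)))
            if spec.cl_bounds_L_h[0] <= cl <= spec.cl_bounds_L_h[1]:
                break
        else:  # pragma: no cover
            raise PKValidationError("clearance draw failed within bounds")
    v = float(rng.lognormal(math.log(spec.v_median_L), _sigma_from_cv(spec.v_cv)))
    if spec.true_order == 1:
        return PKParams1C(cl_L_h=cl, v_L=v)
    q = float(rng.lognormal(math.log(spec.q_median_L_h), _sigma_from_cv(spec.q_cv)))
    v2 = float(rng.lognormal(math.log(spec.v2_median_L), _sigma_from_cv(spec.v2_cv)))
    return PKParams2C(cl_L_h=cl, v1_L=v, q_L_h=q, v2_L=v2)


def simulate_observations(true_params, regimen: DosingRegimen,
                          sample_times, error_cv: float,
                          rng: np.random.Generator) -> tuple[ConcentrationPoint, ...]:
    """Noisy observations y_i = C_ss(t_i) · (1 + eps_i), eps ~ N(0, cv²), y > 0."""
    if error_cv < 0.0:
        raise PKValidationError("error_cv must be >= 0")
    truth = np.atleast_1d(steady_state_conc(np.asarray(sample_times, float),
                                            true_params, regimen))
    points = []
    for t, c in zip(sample_times, truth):
        y = c
        if error_cv > 0.0:
            for _ in range(10_000):
                y = c * (1.0 + rng.normal(0.0, error_cv))
                if y > 0.0:
                    break
        points.append(ConcentrationPoint(t_h=float(t), conc_mg_L=float(y)))
    return tuple(points)


def simulate_cohort(spec: CohortSpec,
                    rng: np.random.Generator | None = None) -> list[SimulatedSubject]:
    """Full pipeline input: demographics, regimens, truth, design, observations."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    subjects = []
    for p in generate_cohort(spec, rng):
        regimen = assign_regimen(p, rng, spec)
        true_params = _draw_true_params(spec, p, rng)
        times = draw_sample_times(regimen, rng)
        obs = simulate_observations(true_params, regimen, times,
                                    spec.proportional_error_cv, rng)
        subjects.append(
            SimulatedSubject(patient=p, regimen=regimen, true_params=true_params,
                             sample_times_h=times, observations=obs)
        )
    return subjects


def subjects_to_frames(subjects) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tidy (demographics, concentrations, truth) frames for I/O and fitting."""
    demo, conc, truth = [], [], []
    for s in subjects:
        p, r = s.patient, s.regimen
        demo.append(
            {"id": p.id, "age": p.age_y, "sex": p.sex, "weight_kg": p.weight_kg,
             "scr": p.scr_mg_dL, "scr_unit": "mg/dL",
             "crcl_mL_min": p.creatinine_clearance}
        )
        for pt in s.observations:
            conc.append(
                {"id": p.id, "time_h": pt.t_h, "conc_mg_L": pt.conc_mg_L,
                 "dose_mg": r.dose_mg, "tau_h": r.tau_h, "tinf_h": r.tinf_h}
            )
        row = {"id": p.id, "true_order": 1 if isinstance(s.true_params, PKParams1C) else 2,
               "true_cl_L_h": s.true_params.cl_L_h,
               "true_auc_mg_h_L": s.true_auc_mg_h_L}
        if isinstance(s.true_params, PKParams1C):
            row["true_v_L"] = s.true_params.v_L
        else:
            row.update(true_v1_L=s.true_params.v1_L, true_q_L_h=s.true_params.q_L_h,
                       true_v2_L=s.true_params.v2_L)
        truth.append(row)
    return pd.DataFrame(demo), pd.DataFrame(conc), pd.DataFrame(truth)
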