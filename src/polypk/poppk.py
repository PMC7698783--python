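"""Published population-PK models of polymyxin B and covariate conditioning.

Five literature models are represented by their structural order (one or two
compartments), a typical total clearance, a between-subject dispersion (SD)
of clearance, and an optional covariate equation (body weight or estimated
creatinine clearance).  Conditioning a model on a patient and regimen yields
a point AUC prediction (daily dose / typical CL) and a 68% exposure interval
obtained by repeating the prediction at typical CL ± one SD.

The shipped registry (``data/registry_synthetic_defaults.json``) encodes the
published structure of each model, but the dispersion values and covariate
equations are synthetic placeholders: the source publications' exact values
should be transcribed into a user registry for quantitative work.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .pkcore import DosingRegimen, PKValidationError, auc24_from_cl

__all__ = [
    "Patient",
    "PopModelSpec",
    "ConditioningError",
    "cockcroft_gault",
    "typical_clearance",
    "predict_auc",
    "auc_prediction_interval",
    "load_registry",
    "save_registry",
    "default_registry",
]

COVARIATES = ("none", "body_weight", "creatinine_clearance")
EQUATION_TYPES = ("constant", "proportional", "power", "saturating")

#: serum creatinine unit conversion: µmol/L per mg/dL
_SCR_UMOL_PER_MG_DL = 88.4


class ConditioningError(ValueError):
    """A model cannot be conditioned on a patient (missing/degenerate inputs)."""


def cockcroft_gault(age_y: float, weight_kg: float, scr_mg_dL: float, sex: str) -> float:
    """Estimated creatinine clearance (mL/min) by Cockcroft–Gault.

    CrCL = (140 − age) · weight / (72 · Scr), multiplied by 0.85 for females.
    Serum creatinine in mg/dL (the 72 constant assumes those units).
    """
    if sex not in ("male", "female"):
        raise PKValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    if not (21.0 <= age_y < 140.0):
        raise PKValidationError(f"age must be in [21, 140) years, got {age_y}")
    if not (weight_kg > 0.0):
        raise PKValidationError(f"weight must be positive, got {weight_kg}")
    if not (scr_mg_dL > 0.0):
        raise PKValidationError(f"serum creatinine must be positive, got {scr_mg_dL}")
    crcl = (140.0 - age_y) * weight_kg / (72.0 * scr_mg_dL)
    if sex == "female":
        crcl *= 0.85
    return crcl


@dataclass(frozen=True)
class Patient:
    """Demographics and renal function used to condition covariate models.

    ``scr_mg_dL`` is serum creatinine in mg/dL (pass ``scr_umol_L`` to convert
    from SI units).  ``crcl_mL_min`` may be supplied directly; otherwise it is
    derived by Cockcroft–Gault on access.
    """

    id: str
    age_y: float
    sex: str
    weight_kg: float
    scr_mg_dL: float | None = None
    crcl_mL_min: float | None = None
    scr_umol_L: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise PKValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (self.age_y >= 21.0):
            raise PKValidationError(
                f"study eligibility requires age >= 21 y, got {self.age_y}"
            )
        if not (self.weight_kg > 0.0):
            raise PKValidationError(f"weight must be positive, got {self.weight_kg}")
        if self.scr_mg_dL is None and self.scr_umol_L is not None:
            object.__setattr__(self, "scr_mg_dL", self.scr_umol_L / _SCR_UMOL_PER_MG_DL)
        if self.scr_mg_dL is not None and not (self.scr_mg_dL > 0.0):
            raise PKValidationError(
                f"serum creatinine must be positive, got {self.scr_mg_dL}"
            )

    @property
    def creatinine_clearance(self) -> float:
        """CrCL (mL/min): supplied value, else Cockcroft–Gault from demographics."""
        if self.crcl_mL_min is not None:
            return self.crcl_mL_min
        if self.scr_mg_dL is None:
            raise ConditioningError(
                f"patient {self.id!r}: neither crcl_mL_min nor serum creatinine available"
            )
        return cockcroft_gault(self.age_y, self.weight_kg, self.scr_mg_dL, self.sex)


@dataclass(frozen=True)
class PopModelSpec:
    """One published population-PK model of polymyxin B.

    ``equation_type``/``equation_params`` define how the covariate maps to CL:

    - ``constant``: CL = cl_typical (no covariate)
    - ``proportional``: CL = cl_typical · (x / reference)
    - ``power``: CL = cl_typical · (x / reference) ** exponent
    - ``saturating``: CL = cl_max · x / (x50 + x)  (dispersion acts on cl_max)
    """

    name: str
    structural_order: int
    cl_typical_L_h: float
    cl_sd_L_h: float
    covariate: str = "none"
    equation_type: str = "constant"
    equation_params: dict = field(default_factory=dict)
    reference: str = ""

    def __post_init__(self) -> None:
        if self.structural_order not in (1, 2):
            raise PKValidationError("structural_order must be 1 or 2")
        if not (self.cl_typical_L_h > 0.0):
            raise PKValidationError("cl_typical_L_h must be positive")
        if self.cl_sd_L_h < 0.0:
            raise PKValidationError("cl_sd_L_h must be >= 0")
        if self.covariate not in COVARIATES:
            raise PKValidationError(f"covariate must be one of {COVARIATES}")
        if self.equation_type not in EQUATION_TYPES:
            raise PKValidationError(f"equation_type must be one of {EQUATION_TYPES}")
        if (self.covariate == "none") != (self.equation_type == "constant"):
            raise PKValidationError(
                "equation_type 'constant' iff covariate 'none' "
                f"(got {self.covariate!r} with {self.equation_type!r})"
            )

    # -- covariate machinery -------------------------------------------------

    def _covariate_value(self, p: Patient) -> float:
        if self.covariate == "body_weight":
            return p.weight_kg
        if self.covariate == "creatinine_clearance":
            try:
                return p.creatinine_clearance
            except ConditioningError as exc:
                raise ConditioningError(
                    f"model {self.name!r} needs creatinine clearance: {exc}"
                ) from exc
        raise ConditioningError(f"model {self.name!r} has no covariate")

    def _clearance(self, p: Patient, shift_sd: float = 0.0) -> float:
        """Conditioned CL; ``shift_sd`` moves the dispersed quantity by that many SD.

        For ``saturating`` equations the dispersion acts on cl_max (the
        model's maximum-clearance parameter); otherwise it acts directly on
        the conditioned clearance.
        """
        if self.equation_type == "constant":
            cl = self.cl_typical_L_h + shift_sd * self.cl_sd_L_h
        elif self.equation_type == "saturating":
            x = self._covariate_value(p)
            cl_max = float(self.equation_params["cl_max"]) + shift_sd * self.cl_sd_L_h
            x50 = float(self.equation_params["x50"])
            cl = cl_max * x / (x50 + x)
        else:
            x = self._covariate_value(p)
            ref = float(self.equation_params["reference"])
            if self.equation_type == "proportional":
                cl = self.cl_typical_L_h * (x / ref)
            else:  # power
                cl = self.cl_typical_L_h * (x / ref) ** float(
                    self.equation_params["exponent"]
                )
            cl += shift_sd * self.cl_sd_L_h
        return cl

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopModelSpec":
        return cls(**d)


def typical_clearance(m: PopModelSpec, p: Patient) -> float:
    """Typical total clearance (L/h) for this patient under model ``m``."""
    cl = m._clearance(p)
    if not (cl > 0.0):
        raise ConditioningError(
            f"model {m.name!r} yields non-positive clearance {cl:.3g} L/h "
            f"for patient {p.id!r}"
        )
    return cl


def predict_auc(m: PopModelSpec, p: Patient, r: DosingRegimen) -> float:
    """Model-predicted steady-state 24-h AUC (mg·h/L): daily dose / typical CL."""
    return auc24_from_cl(r.daily_dose_mg, typical_clearance(m, p))


def auc_prediction_interval(m: PopModelSpec, p: Patient,
                            r: DosingRegimen) -> tuple[float, float]:
    """68% AUC interval from typical CL ± one SD.

    Lower bound uses CL + SD, upper bound CL − SD, so the point prediction
    always lies inside.  Raises if the SD reaches the conditioned CL
    (degenerate interval).
    """
    cl_lo = m._clearance(p, shift_sd=-1.0)  # low clearance -> high AUC
    cl_hi = m._clearance(p, shift_sd=+1.0)
    if not (cl_lo > 0.0):
        raise ConditioningError(
            f"model {m.name!r}: CL dispersion ({m.cl_sd_L_h} L/h) reaches the "
            f"typical clearance; the upper AUC limit is undefined"
        )
    daily = r.daily_dose_mg
    return (daily / cl_hi, daily / cl_lo)


# -- registry I/O -------------------------------------------------------------

def _parse_registry(objs: Iterable[dict]) -> list[PopModelSpec]:
    models = [PopModelSpec.from_dict(o) for o in objs]
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise PKValidationError(f"duplicate model names in registry: {names}")
    return models


def load_registry(path: str | Path | None = None) -> list[PopModelSpec]:
    """Load popPK models from a JSON registry; default to the shipped registry."""
    if path is None:
        text = (resources.files("polypk") / "data" /
                "registry_synthetic_defaults.json").read_text()
    else:
        text = Path(path).read_text()
    return _parse_registry(json.loads(text))


def save_registry(models: Iterable[PopModelSpec], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in models], indent=2) + "\n")


def default_registry() -> list[PopModelSpec]:
    """The five shipped models (synthetic placeholder dispersions/equations)."""
    return load_registry(None)
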