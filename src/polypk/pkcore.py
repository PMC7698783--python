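"""Closed-form steady-state kinetics for intermittent zero-order infusions.

One- and two-compartment mammillary disposition models with drug input at a
constant rate ``R0 = dose / T_inf`` over the infusion duration, dosed every
``tau`` hours.  At steady state each exponential term of the single-dose
response accumulates by the factor ``1 / (1 - exp(-lambda * tau))``, which
gives a closed-form concentration profile over one dosing interval without
any superposition over past doses.

Time is measured from the start of the most recent infusion; the dosing
interval is the closed set ``[0, tau]``.  Units are fixed throughout the
package: amounts in mg, volumes in L, times in h, concentrations in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKValidationError",
    "PKDomainError",
    "DosingRegimen",
    "PKParams1C",
    "PKParams2C",
    "ConcentrationPoint",
    "conc_ss_1c",
    "conc_ss_2c",
    "steady_state_conc",
    "auc24_from_cl",
    "terminal_half_life",
]

LN2 = math.log(2.0)


class PKValidationError(ValueError):
    """Structural parameters or dosing settings are invalid (non-positive, inconsistent)."""


class PKDomainError(ValueError):
    """A sampling time falls outside the steady-state dosing interval [0, tau]."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0.0) or not math.isfinite(value):
            raise PKValidationError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class DosingRegimen:
    """A repeated intravenous infusion schedule.

    Parameters
    ----------
    dose_mg : float
        Drug amount per administration (mg).
    tau_h : float
        Dosing interval (h).  The study drug is given every 12 h.
    tinf_h : float
        Infusion duration (h); must not exceed the interval.
    """

    dose_mg: float
    tau_h: float = 12.0
    tinf_h: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(dose_mg=self.dose_mg, tau_h=self.tau_h, tinf_h=self.tinf_h)
        if self.tinf_h > self.tau_h:
            raise PKValidationError(
                f"infusion duration {self.tinf_h} h exceeds dosing interval {self.tau_h} h"
            )

    @property
    def daily_dose_mg(self) -> float:
        """Total dose per 24 h (mg)."""
        return self.dose_mg * (24.0 / self.tau_h)

    @property
    def rate_mg_per_h(self) -> float:
        """Zero-order input rate R0 during the infusion (mg/h)."""
        return self.dose_mg / self.tinf_h


@dataclass(frozen=True)
class PKParams1C:
    """One-compartment parameters: total clearance CL (L/h) and volume V (L)."""

    cl_L_h: float
    v_L: float

    n_params = 2

    def __post_init__(self) -> None:
        _require_positive(cl_L_h=self.cl_L_h, v_L=self.v_L)

    @property
    def k_h(self) -> float:
        """First-order elimination rate constant k = CL/V (1/h)."""
        return self.cl_L_h / self.v_L

    @property
    def t_half_h(self) -> float:
        return LN2 / self.k_h

    def exponential_terms(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        """Unit-bolus response ``C(t) = sum_i a_i exp(-lam_i t)`` as (a, lam)."""
        return (1.0 / self.v_L,), (self.k_h,)


@dataclass(frozen=True)
class PKParams2C:
    """Two-compartment parameters in clearance form.

    CL (total clearance, L/h), V1 (central volume, L), Q (intercompartmental
    clearance, L/h), V2 (peripheral volume, L).  Macro rate constants
    (alpha >= beta > 0) are derived from the characteristic equation
    ``lam^2 - (k10 + k12 + k21) lam + k10 k21 = 0``; exposure (AUC) depends
    only on CL, which is why published models condition covariates on CL.
    """

    cl_L_h: float
    v1_L: float
    q_L_h: float
    v2_L: float

    n_params = 4

    def __post_init__(self) -> None:
        _require_positive(
            cl_L_h=self.cl_L_h, v1_L=self.v1_L, q_L_h=self.q_L_h, v2_L=self.v2_L
        )

    @property
    def k10_h(self) -> float:
        return self.cl_L_h / self.v1_L

    @property
    def k12_h(self) -> float:
        return self.q_L_h / self.v1_L

    @property
    def k21_h(self) -> float:
        return self.q_L_h / self.v2_L

    def macro_rates(self) -> tuple[float, float]:
        """Hybrid rate constants (alpha, beta), alpha >= beta > 0."""
        k10, k12, k21 = self.k10_h, self.k12_h, self.k21_h
        s = k10 + k12 + k21
        # discriminant = (k10 + k12 - k21)^2 + 4 k12 k21 > 0 for positive params
        disc = math.sqrt(max((k10 + k12 - k21) ** 2 + 4.0 * k12 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        if beta <= 0.0:  # guard against catastrophic cancellation
            beta = (k10 * k21) / alpha
        return alpha, beta

    @property
    def t_half_h(self) -> float:
        """Terminal half-life ln2 / beta (h)."""
        return LN2 / self.macro_rates()[1]

    def exponential_terms(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        alpha, beta = self.macro_rates()
        k21 = self.k21_h
        span = alpha - beta
        if span <= 0.0 or span < 1e-12 * alpha:
            raise PKValidationError(
                "two-compartment hybrid rates are numerically degenerate (alpha ~ beta)"
            )
        a = (alpha - k21) / (self.v1_L * span)
        b = (k21 - beta) / (self.v1_L * span)
        return (a, b), (alpha, beta)


@dataclass(frozen=True)
class ConcentrationPoint:
    """A timed plasma concentration within one steady-state dosing interval."""

    t_h: float
    conc_mg_L: float

    def __post_init__(self) -> None:
        if not (self.t_h >= 0.0) or not math.isfinite(self.t_h):
            raise PKValidationError(f"sample time must be >= 0 h, got {self.t_h!r}")
        if not (self.conc_mg_L >= 0.0) or not math.isfinite(self.conc_mg_L):
            raise PKValidationError(
                f"concentration must be >= 0 mg/L, got {self.conc_mg_L!r}"
            )


def _profile(
    t: np.ndarray,
    coefs: tuple[float, ...],
    lams: tuple[float, ...],
    rate: float,
    tinf: float,
    tau: float,
) -> np.ndarray:
    """Steady-state profile for a sum-of-exponentials unit-bolus response.

    During the infusion (t <= tinf) the profile is the rising infusion term
    plus the accumulated tail of all previous doses; afterwards only the
    accumulated washout remains.  ``expm1`` keeps 1 - exp(-x) accurate for
    small rate-time products.
    """
    during = t <= tinf
    out = np.zeros(t.shape, dtype=float)
    for a, lam in zip(coefs, lams):
        acc = -math.expm1(-lam * tau)  # 1 - exp(-lam*tau)
        einf = -math.expm1(-lam * tinf)  # 1 - exp(-lam*tinf)
        amp = rate * a / lam
        rising = -np.expm1(-lam * t) + einf * np.exp(-lam * (t + tau - tinf)) / acc
        # exponent clipped at 0: the washout branch is only used for t > tinf
        washout = einf * np.exp(np.minimum(-lam * (t - tinf), 0.0)) / acc
        out += amp * np.where(during, rising, washout)
    return out


def _eval_profile(t, params, regimen: DosingRegimen):
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > regimen.tau_h):
        raise PKDomainError(
            f"times must lie within the dosing interval [0, {regimen.tau_h}] h"
        )
    coefs, lams = params.exponential_terms()
    out = _profile(np.atleast_1d(arr), coefs, lams, regimen.rate_mg_per_h,
                   regimen.tinf_h, regimen.tau_h)
    return float(out[0]) if arr.ndim == 0 else out


def conc_ss_1c(t, p: PKParams1C, r: DosingRegimen):
    """Steady-state one-compartment concentration (mg/L) at time t (h).

    t may be a scalar or array; every value must lie in [0, tau].
    """
    if not isinstance(p, PKParams1C):
        raise PKValidationError("conc_ss_1c requires one-compartment parameters")
    return _eval_profile(t, p, r)


def conc_ss_2c(t, p: PKParams2C, r: DosingRegimen):
    """Steady-state two-compartment concentration (mg/L) at time t (h)."""
    if not isinstance(p, PKParams2C):
        raise PKValidationError("conc_ss_2c requires two-compartment parameters")
    return _eval_profile(t, p, r)


def steady_state_conc(t, params, regimen: DosingRegimen):
    """Dispatch on the structural order of ``params`` (PKParams1C or PKParams2C)."""
    if isinstance(params, PKParams1C):
        return conc_ss_1c(t, params, regimen)
    if isinstance(params, PKParams2C):
        return conc_ss_2c(t, params, regimen)
    raise PKValidationError(f"unsupported parameter type {type(params).__name__}")


def auc24_from_cl(daily_dose_mg: float, cl_L_h: float) -> float:
    """Steady-state 24-h area under the curve: daily dose / CL (mg·h/L)."""
    _require_positive(daily_dose_mg=daily_dose_mg, cl_L_h=cl_L_h)
    return daily_dose_mg / cl_L_h


def terminal_half_life(p) -> float:
    """Terminal elimination half-life (h): ln2·V/CL for one compartment, ln2/beta for two."""
    if isinstance(p, (PKParams1C, PKParams2C)):
        return p.t_half_h
    raise PKValidationError(f"unsupported parameter type {type(p).__name__}")
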