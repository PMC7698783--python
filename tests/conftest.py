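"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the package's accumulation-factor closed form:
steady state is reached either by explicit superposition of analytic
single-dose profiles (one compartment) or by direct ODE integration over many
dosing intervals (two compartments).
"""

from __future__ import annotations

import math

import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.integrate import solve_ivp

from polypk import DosingRegimen, PKParams1C, PKParams2C

matplotlib.use("Agg")

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def single_dose_1c(t: float, p: PKParams1C, r: DosingRegimen) -> float:
    """Analytic single-dose infusion profile (t >= 0 from infusion start)."""
    k = p.cl_L_h / p.v_L
    r0 = r.dose_mg / r.tinf_h
    if t <= r.tinf_h:
        return r0 / p.cl_L_h * (1.0 - math.exp(-k * t))
    return (r0 / p.cl_L_h * (1.0 - math.exp(-k * r.tinf_h))
            * math.exp(-k * (t - r.tinf_h)))


def superposition_1c(t, p: PKParams1C, r: DosingRegimen, n_doses: int = 30):
    """Steady-state approximation by summing n successive single doses."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return np.array([
        sum(single_dose_1c(ti + i * r.tau_h, p, r) for i in range(n_doses))
        for ti in t
    ])


def ode_steady_state_2c(times, p: PKParams2C, r: DosingRegimen,
                        n_doses: int = 30) -> np.ndarray:
    """Two-compartment steady state by segment-wise ODE integration.

    Integrates amounts (central, peripheral) across ``n_doses`` intervals,
    splitting every interval at the end of the infusion so the integrator
    never steps across the input discontinuity, then evaluates the final
    interval at ``times``.
    """
    k10, k12, k21 = p.k10_h, p.k12_h, p.k21_h
    r0 = r.rate_mg_per_h

    def rhs(rate):
        def f(_, y):
            a1, a2 = y
            return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]
        return f

    y = np.array([0.0, 0.0])
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    for dose_i in range(n_doses):
        last = dose_i == n_doses - 1
        for (t0, t1, rate) in [(0.0, r.tinf_h, r0), (r.tinf_h, r.tau_h, 0.0)]:
            if t1 <= t0:
                continue
            t_eval = None
            if last:
                inside = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
                t_eval = np.unique(np.clip(
                    np.concatenate([times[inside], [t0, t1]]), t0, t1))
            sol = solve_ivp(rhs(rate), (t0, t1), y, rtol=1e-11, atol=1e-13,
                            t_eval=t_eval, method="LSODA")
            y = sol.y[:, -1]
            if last and t_eval is not None:
                for j, tv in enumerate(sol.t):
                    hits = np.isclose(times, tv)
                    out[hits] = sol.y[0, j] / p.v1_L
    return out


@pytest.fixture
def regimen() -> DosingRegimen:
    return DosingRegimen(dose_mg=100.0, tau_h=12.0, tinf_h=1.0)


@pytest.fixture
def params_1c() -> PKParams1C:
    return PKParams1C(cl_L_h=2.5, v_L=25.0)


@pytest.fixture
def params_2c() -> PKParams2C:
    return PKParams2C(cl_L_h=2.5, v1_L=15.0, q_L_h=5.0, v2_L=20.0)
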