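"""Predictive-performance scoring of popPK AUC predictions.

Per subject, prediction error is expressed relative to the observed exposure:
% bias = (predicted − observed) · 100 / observed (signed) and % precision is
its absolute value.  Per model, the cohort summary carries the arithmetic
means of both, the squared Pearson correlation between observed and predicted
AUC, and the coverage — the percentage of subjects whose observed AUC falls
inside the 68% interval implied by typical CL ± one SD (bounds inclusive).

Observed and predicted AUC are always paired at the same structural order:
a one-compartment population model is compared against one-compartment
individual fits, a two-compartment model against two-compartment fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import CompartmentalPKResults, UndefinedRSquaredError
from .pkcore import DosingRegimen, PKValidationError
from .poppk import Patient, PopModelSpec, auc_prediction_interval, predict_auc

__all__ = [
    "PairingError",
    "PairedExposure",
    "EvalSummary",
    "percent_bias",
    "percent_precision",
    "pair_exposures",
    "summarize_model",
    "evaluate_registry",
    "pairs_to_dataframe",
    "plot_observed_vs_predicted",
]


class PairingError(ValueError):
    """Observed fits at the model's structural order are missing for some subjects."""


def percent_bias(predicted_auc: float, observed_auc: float) -> float:
    """Signed prediction error: (predicted − observed) × 100 / observed."""
    if not (observed_auc > 0.0):
        raise PKValidationError(f"observed AUC must be positive, got {observed_auc}")
    return (predicted_auc - observed_auc) * 100.0 / observed_auc


def percent_precision(predicted_auc: float, observed_auc: float) -> float:
    """Absolute prediction error: |predicted − observed| × 100 / observed."""
    return abs(percent_bias(predicted_auc, observed_auc))


@dataclass(frozen=True)
class PairedExposure:
    """Observed and model-predicted AUC for one subject, with the 68% interval."""

    patient_id: str
    observed_auc: float
    predicted_auc: float
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.observed_auc > 0.0 and self.predicted_auc > 0.0):
            raise PKValidationError("AUC values must be positive")
        lo, hi = self.interval
        if not (lo < hi):
            raise PKValidationError(f"interval must satisfy lower < upper, got {self.interval}")

    @property
    def bias_pct(self) -> float:
        return percent_bias(self.predicted_auc, self.observed_auc)

    @property
    def precision_pct(self) -> float:
        return percent_precision(self.predicted_auc, self.observed_auc)

    @property
    def captured(self) -> bool:
        """Observed AUC inside the 68% interval; boundary ties count as captured."""
        lo, hi = self.interval
        return lo <= self.observed_auc <= hi


@dataclass(frozen=True)
class EvalSummary:
    """Cohort-level predictive performance of one population model."""

    model_name: str
    mean_bias_pct: float
    mean_precision_pct: float
    r2_obs_pred: float
    coverage_pct: float
    n_subjects: int


def pair_exposures(
    fit_results_by_order: Mapping[int, Mapping[str, CompartmentalPKResults]],
    model: PopModelSpec,
    patients: Sequence[Patient],
    regimens: Mapping[str, DosingRegimen],
) -> list[PairedExposure]:
    """Pair each patient's observed AUC (at the model's structural order) with
    the model's prediction and 68% interval.

    Raises
    ------
    PairingError
        If fits at the required order are missing for any patient — observed
        and predicted exposure must come from the same structural model.
    """
    order = model.structural_order
    fits = fit_results_by_order.get(order, {})
    missing = [p.id for p in patients if p.id not in fits]
    if missing:
        raise PairingError(
            f"model {model.name!r} is a {order}-compartment model but no "
            f"{order}-compartment fits are available for subjects: {missing}"
        )
    wrong = [p.id for p in patients if fits[p.id].structural_order != order]
    if wrong:
        raise PairingError(
            f"fits supplied under order {order} have a different structural "
            f"order for subjects: {wrong}"
        )
    pairs = []
    for p in patients:
        r = regimens[p.id]
        pairs.append(
            PairedExposure(
                patient_id=p.id,
                observed_auc=fits[p.id].observed_auc_mg_h_L,
                predicted_auc=predict_auc(model, p, r),
                interval=auc_prediction_interval(model, p, r),
            )
        )
    return pairs


def summarize_model(pairs: Sequence[PairedExposure], model_name: str) -> EvalSummary:
    """Cohort summary: mean % bias/precision, obs-vs-pred r², % captured."""
    n = len(pairs)
    if n < 3:
        raise PKValidationError(
            f"at least 3 paired exposures are needed for a summary, got {n}"
        )
    obs = np.array([p.observed_auc for p in pairs])
    pred = np.array([p.predicted_auc for p in pairs])
    if float(np.std(obs)) == 0.0 or float(np.std(pred)) == 0.0:
        raise UndefinedRSquaredError(
            "r² undefined: observed or predicted AUC has zero variance"
        )
    rho = float(np.corrcoef(obs, pred)[0, 1])
    return EvalSummary(
        model_name=model_name,
        mean_bias_pct=float(np.mean([p.bias_pct for p in pairs])),
        mean_precision_pct=float(np.mean([p.precision_pct for p in pairs])),
        r2_obs_pred=min(rho * rho, 1.0),
        coverage_pct=100.0 * sum(p.captured for p in pairs) / n,
        n_subjects=n,
    )


def evaluate_registry(
    fit_results_by_order: Mapping[int, Mapping[str, CompartmentalPKResults]],
    models: Sequence[PopModelSpec],
    patients: Sequence[Patient],
    regimens: Mapping[str, DosingRegimen],
) -> tuple[pd.DataFrame, dict[str, list[PairedExposure]]]:
    """Score every registry model; returns (summary frame, per-model pairs)."""
    rows, all_pairs = [], {}
    for m in models:
        pairs = pair_exposures(fit_results_by_order, m, patients, regimens)
        s = summarize_model(pairs, m.name)
        rows.append(
            {
                "model": s.model_name,
                "structural_order": m.structural_order,
                "mean_bias_pct": s.mean_bias_pct,
                "mean_precision_pct": s.mean_precision_pct,
                "r2_obs_pred": s.r2_obs_pred,
                "coverage_pct": s.coverage_pct,
                "n_subjects": s.n_subjects,
            }
        )
        all_pairs[m.name] = pairs
    return pd.DataFrame(rows), all_pairs


def pairs_to_dataframe(pairs_by_model: Mapping[str, Sequence[PairedExposure]]) -> pd.DataFrame:
    """Long per-subject table: patient, model, observed, predicted, bias, captured."""
    rows = []
    for model_name, pairs in pairs_by_model.items():
        for p in pairs:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "model": model_name,
                    "observed_auc": p.observed_auc,
                    "predicted_auc": p.predicted_auc,
                    "bias_pct": p.bias_pct,
                    "precision_pct": p.precision_pct,
                    "interval_lower": p.interval[0],
                    "interval_upper": p.interval[1],
                    "captured": p.captured,
                }
            )
    return pd.DataFrame(rows)


def plot_observed_vs_predicted(pairs: Sequence[PairedExposure], model_name: str = "",
                               ax=None):
    """Scatter of observed vs predicted AUC with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    obs = [p.observed_auc for p in pairs]
    pred = [p.predicted_auc for p in pairs]
    ax.plot(obs, pred, "o", mfc="none", color="C0")
    lim = (0.0, 1.05 * max(max(obs), max(pred)))
    ax.plot(lim, lim, "--", color="0.6", lw=1)
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel("observed AUC (mg·h/L)")
    ax.set_ylabel("predicted AUC (mg·h/L)")
    if model_name:
        try:
            r2 = summarize_model(pairs, model_name).r2_obs_pred
            ax.set_title(f"{model_name} (r² = {r2:.2f})")
        except (PKValidationError, UndefinedRSquaredError):
            ax.set_title(model_name)
    return ax
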