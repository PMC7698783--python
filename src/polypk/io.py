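"""Tabular readers/writers and cohort-level fitting helpers.

All datasets are flat CSV with explicit headers (no event-record coding):

- demographics: ``id, age, sex, weight_kg, scr, scr_unit[, crcl_mL_min]``
- concentrations: ``id, time_h, conc_mg_L, dose_mg, tau_h, tinf_h`` — times in
  hours from the start of the most recent infusion, one row per sample
- truth (simulation only): ``id, true_order, true_cl_L_h, ..., true_auc_mg_h_L``
- fits: one row per subject per structural order

Floats are written with six significant digits, which round-trips the
pipeline's decisions (dose selection, capture counts) losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import FitConfig, FitError, fit_individual
from .pkcore import ConcentrationPoint, DosingRegimen, PKParams1C
from .poppk import Patient

__all__ = [
    "write_table",
    "read_table",
    "patients_from_demographics",
    "regimens_from_concentrations",
    "points_from_concentrations",
    "fit_cohort",
    "fits_to_table",
    "write_manifest",
]

_FLOAT_FMT = "%.6g"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})


def patients_from_demographics(df: pd.DataFrame) -> list[Patient]:
    """Build patients from a demographics frame; SI creatinine is converted."""
    patients = []
    for row in df.itertuples(index=False):
        unit = getattr(row, "scr_unit", "mg/dL")
        kwargs = dict(id=str(row.id), age_y=float(row.age), sex=str(row.sex),
                      weight_kg=float(row.weight_kg))
        if unit in ("umol/L", "µmol/L"):
            kwargs["scr_umol_L"] = float(row.scr)
        else:
            kwargs["scr_mg_dL"] = float(row.scr)
        if hasattr(row, "crcl_mL_min") and not pd.isna(row.crcl_mL_min):
            kwargs["crcl_mL_min"] = float(row.crcl_mL_min)
        patients.append(Patient(**kwargs))
    return patients


def regimens_from_concentrations(df: pd.DataFrame) -> dict[str, DosingRegimen]:
    """One regimen per subject; dosing columns must be constant within subject."""
    regimens = {}
    for sid, grp in df.groupby("id", sort=False):
        vals = {}
        for col in ("dose_mg", "tau_h", "tinf_h"):
            uniq = grp[col].unique()
            if len(uniq) != 1:
                raise ValueError(f"subject {sid}: column {col!r} is not constant")
            vals[col] = float(uniq[0])
        regimens[str(sid)] = DosingRegimen(**vals)
    return regimens


def points_from_concentrations(df: pd.DataFrame) -> dict[str, list[ConcentrationPoint]]:
    points: dict[str, list[ConcentrationPoint]] = {}
    for sid, grp in df.groupby("id", sort=False):
        points[str(sid)] = [
            ConcentrationPoint(float(t), float(c))
            for t, c in zip(grp["time_h"], grp["conc_mg_L"])
        ]
    return points


def fit_cohort(
    conc_df: pd.DataFrame,
    orders: Sequence[int] = (1, 2),
    weight_scheme: str = "inverse_prediction_squared",
    config_by_order: Mapping[int, FitConfig] | None = None,
) -> tuple[dict[int, dict[str, object]], list[tuple[str, int, str]]]:
    """Fit every subject at every requested structural order.

    Returns ``(fits_by_order, failures)`` where ``fits_by_order[order][id]``
    is a :class:`~polypk.fitting.CompartmentalPKResults` and ``failures``
    lists ``(id, order, reason)`` for subjects that could not be fitted —
    the run continues past individual failures.
    """
    regimens = regimens_from_concentrations(conc_df)
    points = points_from_concentrations(conc_df)
    fits: dict[int, dict[str, object]] = {o: {} for o in orders}
    failures: list[tuple[str, int, str]] = []
    for order in orders:
        if config_by_order and order in config_by_order:
            cfg = config_by_order[order]
        else:
            cfg = FitConfig(structural_order=order, weight_scheme=weight_scheme)
        for sid, pts in points.items():
            try:
                fits[order][sid] = fit_individual(pts, regimens[sid], cfg)
            except FitError as exc:
                failures.append((sid, order, str(exc)))
    return fits, failures


def fits_to_table(fits_by_order: Mapping[int, Mapping[str, object]],
                  failures: Sequence[tuple[str, int, str]] = ()) -> pd.DataFrame:
    """Long fit table: one row per subject per order, failures flagged."""
    rows = []
    for order in sorted(fits_by_order):
        for sid, res in fits_by_order[order].items():
            p = res.params
            row = {
                "id": sid, "order": order, "status": "ok",
                "cl_L_h": p.cl_L_h,
                "v_L": p.v_L if isinstance(p, PKParams1C) else p.v1_L,
                "q_L_h": np.nan if isinstance(p, PKParams1C) else p.q_L_h,
                "v2_L": np.nan if isinstance(p, PKParams1C) else p.v2_L,
                "r2_fit": res.r2_fit,
                "observed_auc_mg_h_L": res.observed_auc_mg_h_L,
                "t_half_h": res.half_life_h,
                "objective": res.objective_value,
                "n_points": res.n_points,
            }
            rows.append(row)
    for sid, order, reason in failures:
        rows.append({"id": sid, "order": order, "status": f"failed: {reason}"})
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, stage: str, seed: int | None,
                   config: Mapping, counts: Mapping[str, int]) -> Path:
    """Run metadata: stage, seed, a stable hash of the configuration, counts."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(blob),
        "counts": dict(counts),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
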