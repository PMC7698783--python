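"""Bias/precision formulas, coverage counting, structural pairing."""

import numpy as np
import pytest

from polypk import (
    DosingRegimen,
    PairedExposure,
    PairingError,
    Patient,
    PKValidationError,
    PopModelSpec,
    pair_exposures,
    percent_bias,
    percent_precision,
    summarize_model,
)
from polypk.evaluation import evaluate_registry, pairs_to_dataframe
from polypk.fitting import UndefinedRSquaredError


class TestErrorMetrics:
    @pytest.mark.parametrize("pred,obs,bias", [
        (100.0, 100.0, 0.0),
        (80.0, 100.0, -20.0),
        (130.0, 100.0, 30.0),
        (55.0, 110.0, -50.0),
        (173.4, 85.0, 104.0),
    ])
    def test_bias_hand_computed(self, pred, obs, bias):
        assert percent_bias(pred, obs) == pytest.approx(bias)
        assert percent_precision(pred, obs) == pytest.approx(abs(bias))

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(PKValidationError):
            percent_bias(80.0, 0.0)

    def test_precision_is_absolute_bias_subject_wise(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pred, obs = rng.uniform(10.0, 200.0, size=2)
            assert percent_precision(pred, obs) == abs(percent_bias(pred, obs))


def make_pair(pid, obs, pred, lo, hi):
    return PairedExposure(patient_id=pid, observed_auc=obs, predicted_auc=pred,
                          interval=(lo, hi))


class TestSummaries:
    def test_perfect_predictions(self):
        obs = [60.0, 80.0, 100.0, 120.0]
        pairs = [make_pair(f"P{i}", o, o, o - 10.0, o + 10.0)
                 for i, o in enumerate(obs)]
        s = summarize_model(pairs, "perfect")
        assert s.mean_bias_pct == pytest.approx(0.0)
        assert s.mean_precision_pct == pytest.approx(0.0)
        assert s.coverage_pct == pytest.approx(100.0)
        assert s.r2_obs_pred == pytest.approx(1.0)

    @pytest.mark.parametrize("n_inside,expected", [(10, 76.9), (11, 84.6)])
    def test_coverage_granularity_13_subjects(self, n_inside, expected):
        pairs = []
        for i in range(13):
            inside = i < n_inside
            obs = 80.0 if inside else 200.0
            pairs.append(make_pair(f"P{i}", obs, 75.0 + i, 60.0, 100.0))
        s = summarize_model(pairs, "m")
        assert s.coverage_pct == pytest.approx(expected, abs=0.05)

    def test_coverage_equals_brute_force_count_with_ties(self):
        rng = np.random.default_rng(11)
        pairs = []
        for i in range(40):
            lo, hi = sorted(rng.uniform(40.0, 160.0, size=2))
            if hi - lo < 1.0:
                hi = lo + 1.0
            # force boundary ties for a few subjects
            obs = lo if i % 7 == 0 else (hi if i % 11 == 0
                                         else float(rng.uniform(30.0, 180.0)))
            pairs.append(make_pair(f"P{i}", obs, float(rng.uniform(50.0, 150.0)),
                                   lo, hi))
        brute = sum(1 for p in pairs
                    if p.interval[0] <= p.observed_auc <= p.interval[1])
        s = summarize_model(pairs, "m")
        assert s.coverage_pct == pytest.approx(100.0 * brute / len(pairs))

    def test_mean_precision_bounds_mean_bias(self):
        rng = np.random.default_rng(23)
        pairs = [make_pair(f"P{i}", float(rng.uniform(40, 160)),
                           float(rng.uniform(40, 160)), 50.0, 150.0)
                 for i in range(25)]
        s = summarize_model(pairs, "m")
        assert s.mean_precision_pct >= abs(s.mean_bias_pct)

    def test_r2_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(7)
        obs = rng.uniform(40.0, 160.0, 12)
        pred = obs * rng.uniform(0.8, 1.2, 12)
        pairs = [make_pair(f"P{i}", o, p, 10.0, 300.0)
                 for i, (o, p) in enumerate(zip(obs, pred))]
        scaled = [make_pair(f"P{i}", 3.7 * o, 3.7 * p, 10.0, 3000.0)
                  for i, (o, p) in enumerate(zip(obs, pred))]
        assert summarize_model(pairs, "m").r2_obs_pred == pytest.approx(
            summarize_model(scaled, "m").r2_obs_pred, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        pairs = [make_pair("a", 80.0, 90.0, 60.0, 100.0),
                 make_pair("b", 85.0, 90.0, 60.0, 100.0)]
        with pytest.raises(PKValidationError):
            summarize_model(pairs, "m")

    def test_zero_variance_r2_undefined(self):
        pairs = [make_pair(f"P{i}", 80.0, 70.0 + i, 60.0, 100.0)
                 for i in range(5)]
        with pytest.raises(UndefinedRSquaredError):
            summarize_model(pairs, "m")


class _StubFit:
    def __init__(self, order, auc):
        self.structural_order = order
        self.observed_auc_mg_h_L = auc


@pytest.fixture
def cohort():
    patients = [Patient(id=f"P{i}", age_y=40.0 + i, sex="male",
                        weight_kg=70.0 + 5.0 * i, scr_mg_dL=1.0) for i in range(4)]
    regimens = {p.id: DosingRegimen(50.0 + 25.0 * i, 12.0, 1.0)
                for i, p in enumerate(patients)}
    return patients, regimens


class TestPairing:
    def test_pairs_use_matching_structural_order(self, cohort):
        patients, regimens = cohort
        fits = {
            1: {p.id: _StubFit(1, 80.0 + i) for i, p in enumerate(patients)},
            2: {p.id: _StubFit(2, 90.0 + i) for i, p in enumerate(patients)},
        }
        m1 = PopModelSpec(name="one", structural_order=1, cl_typical_L_h=2.5,
                          cl_sd_L_h=0.5)
        m2 = PopModelSpec(name="two", structural_order=2, cl_typical_L_h=2.5,
                          cl_sd_L_h=0.5)
        pairs1 = pair_exposures(fits, m1, patients, regimens)
        pairs2 = pair_exposures(fits, m2, patients, regimens)
        assert [p.observed_auc for p in pairs1] == [80.0, 81.0, 82.0, 83.0]
        assert [p.observed_auc for p in pairs2] == [90.0, 91.0, 92.0, 93.0]

    def test_missing_order_raises_with_subject_ids(self, cohort):
        patients, regimens = cohort
        fits = {1: {p.id: _StubFit(1, 80.0) for p in patients}}
        m2 = PopModelSpec(name="two", structural_order=2, cl_typical_L_h=2.5,
                          cl_sd_L_h=0.5)
        with pytest.raises(PairingError, match="P0"):
            pair_exposures(fits, m2, patients, regimens)

    def test_partially_missing_subjects_named(self, cohort):
        patients, regimens = cohort
        fits = {1: {p.id: _StubFit(1, 80.0) for p in patients[:2]}}
        m1 = PopModelSpec(name="one", structural_order=1, cl_typical_L_h=2.5,
                          cl_sd_L_h=0.5)
        with pytest.raises(PairingError) as err:
            pair_exposures(fits, m1, patients, regimens)
        assert "P2" in str(err.value) and "P3" in str(err.value)

    def test_mislabelled_order_rejected(self, cohort):
        patients, regimens = cohort
        fits = {2: {p.id: _StubFit(1, 80.0) for p in patients}}
        m2 = PopModelSpec(name="two", structural_order=2, cl_typical_L_h=2.5,
                          cl_sd_L_h=0.5)
        with pytest.raises(PairingError):
            pair_exposures(fits, m2, patients, regimens)

    def test_evaluate_registry_summary_and_long_table(self, cohort):
        patients, regimens = cohort
        rng = np.random.default_rng(4)
        fits = {o: {p.id: _StubFit(o, float(rng.uniform(50, 150)))
                    for p in patients} for o in (1, 2)}
        models = [
            PopModelSpec(name="one", structural_order=1, cl_typical_L_h=2.5,
                         cl_sd_L_h=0.5),
            PopModelSpec(name="two", structural_order=2, cl_typical_L_h=2.5,
                         cl_sd_L_h=0.5),
        ]
        summary, pairs = evaluate_registry(fits, models, patients, regimens)
        assert list(summary["model"]) == ["one", "two"]
        long = pairs_to_dataframe(pairs)
        assert len(long) == 8
        assert set(long["model"]) == {"one", "two"}
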