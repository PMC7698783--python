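"""Population-model registry, Cockcroft-Gault, conditioning, AUC intervals."""

import json

import numpy as np
import pytest

from polypk import (
    ConditioningError,
    DosingRegimen,
    Patient,
    PKValidationError,
    PopModelSpec,
    auc_prediction_interval,
    cockcroft_gault,
    default_registry,
    load_registry,
    predict_auc,
    save_registry,
    typical_clearance,
)


@pytest.fixture
def patient():
    return Patient(id="P1", age_y=40.0, sex="male", weight_kg=72.0, scr_mg_dL=1.0)


@pytest.fixture
def constant_model():
    return PopModelSpec(name="flat", structural_order=1, cl_typical_L_h=2.5,
                        cl_sd_L_h=0.5)


class TestCockcroftGault:
    @pytest.mark.parametrize("age,weight,scr,sex,expected", [
        (40.0, 72.0, 1.0, "male", 100.0),
        (40.0, 72.0, 1.0, "female", 85.0),
        (68.0, 72.0, 1.0, "male", 72.0),
    ])
    def test_hand_computed_values(self, age, weight, scr, sex, expected):
        assert cockcroft_gault(age, weight, scr, sex) == pytest.approx(expected)

    @pytest.mark.parametrize("kwargs", [
        dict(age_y=18.0), dict(age_y=150.0), dict(weight_kg=0.0),
        dict(scr_mg_dL=0.0), dict(sex="other"),
    ])
    def test_out_of_range_rejected(self, kwargs):
        base = dict(age_y=40.0, weight_kg=72.0, scr_mg_dL=1.0, sex="male")
        base.update(kwargs)
        with pytest.raises(PKValidationError):
            cockcroft_gault(**base)


class TestPatient:
    def test_derived_crcl_matches_formula(self, patient):
        assert patient.creatinine_clearance == pytest.approx(100.0)

    def test_si_creatinine_converted(self):
        p = Patient(id="P2", age_y=40.0, sex="male", weight_kg=72.0,
                    scr_umol_L=88.4)
        assert p.scr_mg_dL == pytest.approx(1.0)
        assert p.creatinine_clearance == pytest.approx(100.0)

    def test_supplied_crcl_takes_precedence(self):
        p = Patient(id="P3", age_y=40.0, sex="male", weight_kg=72.0,
                    scr_mg_dL=1.0, crcl_mL_min=55.0)
        assert p.creatinine_clearance == 55.0

    def test_under_age_rejected(self):
        with pytest.raises(PKValidationError):
            Patient(id="P4", age_y=20.0, sex="male", weight_kg=72.0, scr_mg_dL=1.0)

    def test_missing_renal_data_raises_on_access(self):
        p = Patient(id="P5", age_y=40.0, sex="male", weight_kg=72.0)
        with pytest.raises(ConditioningError):
            _ = p.creatinine_clearance


class TestConditioning:
    def test_covariate_free_is_patient_independent(self, constant_model, patient):
        other = Patient(id="P9", age_y=65.0, sex="female", weight_kg=110.0,
                        scr_mg_dL=2.0)
        assert typical_clearance(constant_model, patient) == 2.5
        assert typical_clearance(constant_model, other) == 2.5

    def test_weight_model_identity_at_reference(self):
        m = PopModelSpec(name="wt", structural_order=2, cl_typical_L_h=2.5,
                         cl_sd_L_h=0.5, covariate="body_weight",
                         equation_type="proportional",
                         equation_params={"reference": 70.0})
        at_ref = Patient(id="R", age_y=40.0, sex="male", weight_kg=70.0,
                         scr_mg_dL=1.0)
        assert typical_clearance(m, at_ref) == pytest.approx(2.5)
        heavier = Patient(id="H", age_y=40.0, sex="male", weight_kg=105.0,
                          scr_mg_dL=1.0)
        assert typical_clearance(m, heavier) == pytest.approx(3.75)

    def test_crcl_model_monotone_in_crcl(self):
        m = PopModelSpec(name="renal", structural_order=2, cl_typical_L_h=2.5,
                         cl_sd_L_h=0.5, covariate="creatinine_clearance",
                         equation_type="saturating",
                         equation_params={"cl_max": 4.0, "x50": 50.0})
        cls = [typical_clearance(
            m, Patient(id=f"C{i}", age_y=40.0, sex="male", weight_kg=70.0,
                       crcl_mL_min=crcl, scr_mg_dL=1.0))
            for i, crcl in enumerate(np.linspace(10.0, 200.0, 25))]
        assert np.all(np.diff(cls) > 0.0)

    def test_missing_covariate_named_in_error(self):
        m = PopModelSpec(name="renal", structural_order=2, cl_typical_L_h=2.5,
                         cl_sd_L_h=0.5, covariate="creatinine_clearance",
                         equation_type="saturating",
                         equation_params={"cl_max": 4.0, "x50": 50.0})
        p = Patient(id="NOSCR", age_y=40.0, sex="male", weight_kg=70.0)
        with pytest.raises(ConditioningError, match="creatinine clearance"):
            typical_clearance(m, p)

    def test_conditioning_is_pure(self, constant_model, patient):
        r = DosingRegimen(100.0, 12.0, 1.0)
        first = predict_auc(constant_model, patient, r)
        assert all(predict_auc(constant_model, patient, r) == first
                   for _ in range(3))


class TestPrediction:
    def test_point_prediction_arithmetic(self, constant_model, patient):
        r = DosingRegimen(100.0, 12.0, 1.0)  # 200 mg/day
        assert predict_auc(constant_model, patient, r) == pytest.approx(80.0)

    def test_prediction_linear_in_dose(self, constant_model, patient):
        r1 = DosingRegimen(50.0, 12.0, 1.0)
        r2 = DosingRegimen(100.0, 12.0, 1.0)
        assert predict_auc(constant_model, patient, r2) == pytest.approx(
            2.0 * predict_auc(constant_model, patient, r1))

    def test_interval_arithmetic(self, constant_model, patient):
        r = DosingRegimen(100.0, 12.0, 1.0)
        lo, hi = auc_prediction_interval(constant_model, patient, r)
        assert lo == pytest.approx(200.0 / 3.0)
        assert hi == pytest.approx(100.0)
        assert lo < predict_auc(constant_model, patient, r) < hi

    def test_zero_sd_collapses_interval(self, patient):
        m = PopModelSpec(name="sd0", structural_order=1, cl_typical_L_h=2.5,
                         cl_sd_L_h=0.0)
        r = DosingRegimen(100.0, 12.0, 1.0)
        lo, hi = auc_prediction_interval(m, patient, r)
        assert lo == hi == pytest.approx(predict_auc(m, patient, r))

    def test_interval_width_increasing_in_sd(self, patient):
        r = DosingRegimen(100.0, 12.0, 1.0)
        widths = []
        for sd in np.linspace(0.1, 2.0, 10):
            m = PopModelSpec(name="s", structural_order=1, cl_typical_L_h=2.5,
                             cl_sd_L_h=float(sd))
            lo, hi = auc_prediction_interval(m, patient, r)
            widths.append(hi - lo)
        assert np.all(np.diff(widths) > 0.0)

    def test_sd_reaching_cl_is_degenerate(self, patient):
        m = PopModelSpec(name="wide", structural_order=1, cl_typical_L_h=2.5,
                         cl_sd_L_h=2.5)
        with pytest.raises(ConditioningError):
            auc_prediction_interval(m, patient, DosingRegimen(100.0, 12.0, 1.0))


class TestRegistry:
    def test_shipped_registry_structure(self):
        models = {m.name: m for m in default_registry()}
        assert set(models) == {"Sandri", "Manchandani", "Kubin", "Avedissian",
                               "Miglis"}
        assert models["Sandri"].structural_order == 2
        assert models["Sandri"].covariate == "body_weight"
        assert models["Manchandani"].structural_order == 1
        assert models["Kubin"].structural_order == 1
        assert models["Avedissian"].covariate == "creatinine_clearance"
        assert models["Miglis"].covariate == "none"
        covariate_free = sorted(m.cl_typical_L_h for m in models.values()
                                if m.covariate == "none")
        assert covariate_free == [2.4, 2.5, 2.6]

    def test_roundtrip_reproduces_predictions_bitwise(self, tmp_path, patient):
        r = DosingRegimen(100.0, 12.0, 1.0)
        models = default_registry()
        path = tmp_path / "registry.json"
        save_registry(models, path)
        reloaded = load_registry(path)
        for m, m2 in zip(models, reloaded):
            assert m == m2
            assert predict_auc(m, patient, r) == predict_auc(m2, patient, r)
            assert auc_prediction_interval(m, patient, r) == \
                auc_prediction_interval(m2, patient, r)

    def test_duplicate_names_rejected(self, tmp_path, constant_model):
        path = tmp_path / "dup.json"
        path.write_text(json.dumps([constant_model.to_dict()] * 2))
        with pytest.raises(PKValidationError):
            load_registry(path)
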