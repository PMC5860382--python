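"""Equation layer: closed forms, unit dialects, flags, and oracle equivalence."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spotna24.config import CreatinineSpec, convert_creatinine, load_coefficients
from spotna24.equations import (
    NonPositiveCreatinineError,
    predict,
    predict_all,
    predict_intersalt,
    predict_mage,
    predict_power_law,
    predicted_creatinine,
)
from spotna24.types import ParticipantProfile, SpotMeasurement

MG_PER_MMOL = 23.0


def linear_cr_spec(**terms):
    return CreatinineSpec(form="linear", strata_by=(), terms={"all": terms})


class TestPredictedCreatinine:
    @pytest.mark.parametrize("terms, expected", [
        ({"age": -2.04, "weight": 14.89, "height": 16.14,
          "intercept": -2244.45}, 1568.15),
        ({"age": -12.63, "weight": 15.12, "height": 7.39,
          "intercept": -79.9}, 1628.20),
    ])
    def test_linear_form(self, profile, terms, expected):
        got = predicted_creatinine(profile, linear_cr_spec(**terms))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_raises_with_inputs(self):
        p = ParticipantProfile(id="x", sex="male", race="white", age=0,
                               height=0, weight=0, bmi=0)
        spec = linear_cr_spec(age=1.0, weight=1.0, height=1.0, intercept=-5.0)
        with pytest.raises(NonPositiveCreatinineError) as exc:
            predicted_creatinine(p, spec)
        assert exc.value.inputs["age"] == 0

    def test_mage_power_form(self, lib, profile):
        # k (140-age) W^1.5 H^0.5 / 1000 for a white man
        expected = 1.93 * 80 * 80**1.5 * 170**0.5 / 1000
        got = predicted_creatinine(profile, lib["mage"].predicted_creatinine)
        assert got == pytest.approx(expected, rel=1e-12)


class TestPowerLaw:
    @pytest.mark.parametrize("equation, scale, exponent", [
        ("tanaka", 21.98, 0.392), ("kawasaki", 16.3, 0.5)])
    def test_unit_base(self, lib, profile, equation, scale, exponent):
        """Ratio term equal to 1 in dialect units returns scale mmol/day."""
        eq = lib[equation]
        eq_unit = type(eq)(**{**eq.__dict__})
        eq_unit.predicted_creatinine = linear_cr_spec(
            age=0.0, weight=0.0, height=0.0, intercept=1.0)
        # spot creatinine 0.1 mg/dL -> 1 mg/L; sodium 1 mmol/L; PRCr 1 mg/day
        spot = SpotMeasurement(sodium_conc=1.0, creatinine_conc=0.1,
                               window="morning")
        rec = predict_power_law(spot, profile, eq_unit, lib)
        assert rec.quality_flag == "ok"
        assert rec.predicted_na == pytest.approx(scale * MG_PER_MMOL, rel=1e-12)

    @pytest.mark.parametrize("equation, frozen", [
        # independently evaluated: scale * (100/1000 * PRCr)^exp * 23
        ("tanaka", 3667.3086619702426),
        ("kawasaki", 4783.7592569233675),
    ])
    def test_frozen_oracle_value(self, lib, profile, equation, frozen):
        spot = SpotMeasurement(sodium_conc=100.0, creatinine_conc=100.0,
                               window="morning")
        rec = predict(spot, profile, equation, lib)
        assert rec.predicted_na == pytest.approx(frozen, rel=1e-9)

    def test_zero_creatinine_flags_missing(self, lib, profile):
        spot = SpotMeasurement(sodium_conc=100.0, creatinine_conc=0.0,
                               window="morning")
        rec = predict(spot, profile, "tanaka", lib)
        assert rec.quality_flag == "missing_input"
        assert rec.predicted_na is None

    def test_kawasaki_strict_window(self, lib, profile):
        spot = SpotMeasurement(sodium_conc=100.0, creatinine_conc=100.0,
                               window="evening")
        assert predict(spot, profile, "kawasaki", lib).quality_flag == "missing_input"
        relaxed = predict(spot, profile, "kawasaki", lib, window_policy="relaxed")
        assert relaxed.quality_flag == "ok"


class TestIntersalt:
    def test_male_worked_example(self, lib):
        p = ParticipantProfile(id="x", sex="male", race="white", age=60,
                               height=170, weight=86.7, bmi=30.0)
        # spot creatinine 10 mmol/L supplied as mg/dL
        spot = SpotMeasurement(sodium_conc=100.0, creatinine_conc=10 * 11.312,
                               potassium_conc=50.0, window="morning")
        rec = predict_intersalt(spot, p, lib["intersalt"], lib)
        assert rec.predicted_na == pytest.approx(176.06 * MG_PER_MMOL, rel=1e-6)

    def test_intercept_only(self, lib):
        p = ParticipantProfile(id="x", sex="male", race="white", age=0,
                               height=170, weight=80, bmi=0.0)
        spot = SpotMeasurement(sodium_conc=0.0, creatinine_conc=0.0,
                               potassium_conc=0.0, window="morning")
        rec = predict_intersalt(spot, p, lib["intersalt"], lib)
        assert rec.quality_flag == "ok"
        assert rec.predicted_na == pytest.approx(25.46 * MG_PER_MMOL, rel=1e-12)

    def test_negative_sum_is_nonphysical(self, lib):
        p = ParticipantProfile(id="x", sex="male", race="white", age=0,
                               height=170, weight=80, bmi=0.0)
        spot = SpotMeasurement(sodium_conc=0.0, creatinine_conc=20 * 11.312,
                               potassium_conc=0.0, window="morning")
        rec = predict_intersalt(spot, p, lib["intersalt"], lib)
        assert rec.quality_flag == "nonphysical"
        assert rec.predicted_na is None

    def test_missing_potassium_not_imputed(self, lib, profile):
        spot = SpotMeasurement(sodium_conc=100.0, creatinine_conc=100.0,
                               potassium_conc=None, window="morning")
        rec = predict_intersalt(spot, profile, lib["intersalt"], lib)
        assert rec.quality_flag == "missing_input"


class TestMage:
    def test_ratio_scaling_arithmetic(self, lib, profile):
        """100 mmol Na per g creatinine x 1.5 g/day CER -> 3,450 mg/day."""
        eq = type(lib["mage"])(**{**lib["mage"].__dict__})
        eq.predicted_creatinine = linear_cr_spec(
            age=0.0, weight=0.0, height=0.0, intercept=1500.0)
        spot = SpotMeasurement(sodium_conc=100.0, creatinine_conc=100.0,
                               window="morning")  # 1 g/L
        rec = predict_mage(spot, profile, eq, lib)
        assert rec.predicted_na == pytest.approx(3450.0, rel=1e-12)

    def test_zero_sodium_nonphysical(self, lib, profile):
        spot = SpotMeasurement(sodium_conc=0.0, creatinine_conc=100.0,
                               window="morning")
        rec = predict_mage(spot, profile, lib["mage"], lib)
        assert rec.quality_flag == "nonphysical"

    def test_linear_in_expected_creatinine(self, lib, profile):
        spot = SpotMeasurement(sodium_conc=120.0, creatinine_conc=90.0,
                               window="morning")
        base = predict_mage(spot, profile, lib["mage"], lib).predicted_na
        doubled = type(lib["mage"])(**{**lib["mage"].__dict__})
        k = lib["mage"].predicted_creatinine.terms["male|white"]["k"]
        doubled.predicted_creatinine = CreatinineSpec(
            form="mage_power", strata_by=("sex", "race"),
            terms={"male|white": {"k": 2 * k}})
        assert predict_mage(spot, profile, doubled, lib).predicted_na == \
            pytest.approx(2 * base, rel=1e-12)


class TestPredictAll:
    def _specimens(self, windows):
        import pandas as pd
        return pd.DataFrame({
            "participant_id": "P0", "day": 1, "window": list(windows),
            "clock_time": "09:00", "na_mmol_l": 100.0, "k_mmol_l": 50.0,
            "cr_mg_dl": 100.0})

    def _profiles(self):
        import pandas as pd
        return pd.DataFrame({
            "participant_id": ["P0"], "sex": "male", "race": "white",
            "age_years": 60.0, "height_cm": 170.0, "weight_kg": 80.0,
            "bmi": 27.7})

    def test_grid_counts(self, lib):
        all4 = ("overnight", "morning", "afternoon", "evening")
        out = predict_all(self._specimens(all4), self._profiles(), lib)
        assert len(out) == 13  # Kawasaki restricted to morning
        assert set(out[out.equation == "kawasaki"].window) == {"morning"}

    def test_morning_only_participant(self, lib):
        out = predict_all(self._specimens(["morning"]), self._profiles(), lib)
        assert len(out) == 4

    def test_relaxed_policy(self, lib):
        all4 = ("overnight", "morning", "afternoon", "evening")
        out = predict_all(self._specimens(all4), self._profiles(), lib,
                          window_policy="relaxed")
        assert len(out) == 16

    def test_empty_dataset_warns(self, lib):
        import pandas as pd
        out = predict_all(pd.DataFrame(), self._profiles(), lib)
        assert out.empty


class TestInvariants:
    def test_unit_round_trip(self, lib):
        x = 1234.567
        assert lib.mg_to_mmol(lib.mmol_to_mg(x)) == pytest.approx(x, rel=1e-9)

    def test_creatinine_dialects(self):
        assert convert_creatinine(100.0, "mg_per_l") == 1000.0
        assert convert_creatinine(100.0, "g_per_l") == 1.0
        assert convert_creatinine(113.12, "mmol_per_l") == pytest.approx(10.0)
        with pytest.raises(ValueError):
            convert_creatinine(1.0, "furlongs")

    def test_config_strata_structure(self, lib):
        assert set(lib["intersalt"].terms) == {"male", "female"}
        assert set(lib["kawasaki"].predicted_creatinine.terms) == {"male", "female"}
        assert set(lib["mage"].predicted_creatinine.terms) == {
            "male|white", "male|african_american",
            "female|white", "female|african_american"}
        assert set(lib["tanaka"].predicted_creatinine.terms) == {"all"}
        for name in ("tanaka", "kawasaki"):
            assert lib[name].exponent > 0

    @given(na=st.floats(1, 300), cr=st.floats(10, 400), k=st.floats(2, 150),
           age=st.floats(45, 79), wt=st.floats(45, 140), ht=st.floats(145, 200))
    def test_oracle_equivalence(self, na, cr, k, age, wt, ht):
        """Each equation matches an independent single-expression evaluation."""
        lib = load_coefficients()
        bmi = wt / (ht / 100) ** 2
        p = ParticipantProfile(id="x", sex="female", race="african_american",
                               age=age, height=ht, weight=wt, bmi=bmi)
        spot = SpotMeasurement(sodium_conc=na, creatinine_conc=cr,
                               potassium_conc=k, window="morning")
        got = {e: predict(spot, p, e, lib).predicted_na
               for e in ("intersalt", "tanaka", "kawasaki", "mage")}
        oracle = {
            "intersalt": (5.07 + 0.34 * na - 2.16 * (cr * 10 / 113.12)
                          - 0.09 * k + 2.39 * bmi + 2.35 * age
                          - 0.03 * age ** 2) * 23,
            "tanaka": 21.98 * (na / (cr * 10)
                               * (-2.04 * age + 14.89 * wt + 16.14 * ht
                                  - 2244.45)) ** 0.392 * 23,
            "kawasaki": 16.3 * (na / (cr * 10)
                                * (-4.72 * age + 8.58 * wt + 5.09 * ht
                                   - 74.95)) ** 0.5 * 23,
            "mage": na / (cr / 100)
                    * (1.74 * (140 - age) * wt ** 1.5 * ht ** 0.5 / 1e6) * 23,
        }
        for name, expected in oracle.items():
            if expected <= 0:
                assert got[name] is None
            else:
                assert got[name] == pytest.approx(expected, rel=1e-9), name

    @given(na=st.floats(10, 250), cr=st.floats(20, 300),
           dna=st.floats(1, 50), dcr=st.floats(1, 50))
    def test_power_law_monotonicity(self, na, cr, dna, dcr):
        lib = load_coefficients()
        p = ParticipantProfile(id="x", sex="male", race="white", age=60,
                               height=170, weight=80, bmi=27.7)
        for eq in ("tanaka", "kawasaki"):
            def val(n, c):
                return predict(SpotMeasurement(n, c, "morning"), p, eq,
                               lib).predicted_na
            assert val(na + dna, cr) > val(na, cr)
            assert val(na, cr + dcr) < val(na, cr)
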