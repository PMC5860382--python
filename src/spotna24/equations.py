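"""The four published spot-urine equations for 24-hour sodium excretion.

Three functional forms cover them:

* ``linear`` (INTERSALT): sex-specific linear combination of spot sodium,
  potassium and creatinine concentrations, BMI and age (women add an age^2
  term), in mmol/day.
* ``power_law`` (Tanaka, Kawasaki): scale * (spot Na / spot creatinine *
  predicted 24-h creatinine) ** exponent, in mmol/day, with spot creatinine
  taken in the equation's unit dialect (mg/L for both) and predicted
  creatinine from an anthropometric linear equation (mg/day).
* ``ratio_scaling`` (Mage): spot sodium per gram of spot creatinine scaled by
  the expected 24-h creatinine excretion (g/day) from the Mage power form.

All outputs are converted to mg/day with the configured sodium molar factor
(23.0 mg/mmol by default). Non-positive results are flagged ``nonphysical``
rather than clamped; missing required inputs flag ``missing_input``. The
numeric prediction is surfaced only when the flag is ``ok``.
"""
from __future__ import annotations

import logging

import pandas as pd

from .config import CoefficientLibrary, CreatinineSpec, EquationSpec, convert_creatinine
from .types import ParticipantProfile, PredictionRecord, SpotMeasurement

log = logging.getLogger(__name__)


class NonPositiveCreatinineError(ValueError):
    """Predicted 24-h creatinine came out <= 0: out-of-domain anthropometry."""

    def __init__(self, inputs: dict, value: float):
        self.inputs = inputs
        self.value = value
        super().__init__(
            f"non-positive predicted creatinine ({value:.2f} mg/day) for inputs {inputs}"
        )


def predicted_creatinine(profile: ParticipantProfile, spec: CreatinineSpec) -> float:
    """Expected 24-hour creatinine excretion (mg/day) from anthropometry.

    ``linear`` form: intercept + age*c_age + weight*c_wt + height*c_ht.
    ``mage_power`` form: k * (140 - age) * weight^1.5 * height^0.5 / 1000.
    """
    terms = spec.terms[spec.stratum_key(profile.sex, profile.race)]
    if spec.form == "linear":
        value = (
            terms["intercept"]
            + terms["age"] * profile.age
            + terms["weight"] * profile.weight
            + terms["height"] * profile.height
        )
    elif spec.form == "mage_power":
        value = (
            terms["k"] * (140.0 - profile.age)
            * profile.weight ** 1.5 * profile.height ** 0.5 / 1000.0
        )
    else:
        raise ValueError(f"unknown predicted-creatinine form {spec.form!r}")
    if value <= 0:
        raise NonPositiveCreatinineError(
            {"age": profile.age, "weight": profile.weight, "height": profile.height,
             "sex": profile.sex, "race": profile.race}, value)
    return value


def _record(pid: str, eq: str, window: str, mg: float | None, flag: str) -> PredictionRecord:
    return PredictionRecord(pid, eq, window, mg if flag == "ok" else None, flag)


def predict_power_law(
    spot: SpotMeasurement, profile: ParticipantProfile, eq: EquationSpec,
    lib: CoefficientLibrary, *, strict_windows: bool = True,
) -> PredictionRecord:
    """Tanaka / Kawasaki form prediction for one spot specimen."""
    if strict_windows and spot.window not in eq.windows:
        return _record(profile.id, eq.name, spot.window, None, "missing_input")
    if spot.creatinine_conc <= 0:
        return _record(profile.id, eq.name, spot.window, None, "missing_input")
    prcr = predicted_creatinine(profile, eq.predicted_creatinine)
    cr = convert_creatinine(spot.creatinine_conc, eq.unit_dialect["creatinine"])
    mmol = eq.scale * (spot.sodium_conc / cr * prcr) ** eq.exponent
    flag = "ok" if mmol > 0 else "nonphysical"
    return _record(profile.id, eq.name, spot.window, lib.mmol_to_mg(mmol), flag)


def predict_intersalt(
    spot: SpotMeasurement, profile: ParticipantProfile, eq: EquationSpec,
    lib: CoefficientLibrary,
) -> PredictionRecord:
    """Sex-specific INTERSALT (with-potassium) linear prediction."""
    if spot.potassium_conc is None or pd.isna(spot.potassium_conc):
        log.info("INTERSALT: missing potassium for %s/%s", profile.id, spot.window)
        return _record(profile.id, eq.name, spot.window, None, "missing_input")
    t = eq.terms[eq.stratum_key(profile.sex, profile.race)]
    cr = convert_creatinine(spot.creatinine_conc, eq.unit_dialect["creatinine"])
    mmol = (
        t["intercept"]
        + t["na"] * spot.sodium_conc
        + t["cr"] * cr
        + t["k"] * spot.potassium_conc
        + t["bmi"] * profile.bmi
        + t["age"] * profile.age
        + t["age_sq"] * profile.age ** 2
    )
    flag = "ok" if mmol > 0 else "nonphysical"
    return _record(profile.id, eq.name, spot.window, lib.mmol_to_mg(mmol), flag)


def predict_mage(
    spot: SpotMeasurement, profile: ParticipantProfile, eq: EquationSpec,
    lib: CoefficientLibrary,
) -> PredictionRecord:
    """Mage ratio-scaling prediction: spot Na per g creatinine x expected CER."""
    if spot.creatinine_conc <= 0:
        return _record(profile.id, eq.name, spot.window, None, "missing_input")
    cer_g = predicted_creatinine(profile, eq.predicted_creatinine) / 1000.0
    cr_g_l = convert_creatinine(spot.creatinine_conc, eq.unit_dialect["creatinine"])
    mmol = spot.sodium_conc / cr_g_l * cer_g
    flag = "ok" if mmol > 0 else "nonphysical"
    return _record(profile.id, eq.name, spot.window, lib.mmol_to_mg(mmol), flag)


def predict(
    spot: SpotMeasurement, profile: ParticipantProfile, equation: str,
    lib: CoefficientLibrary, *, window_policy: str = "strict",
) -> PredictionRecord:
    """Dispatch one (specimen, equation) prediction.

    ``window_policy='strict'`` restricts each equation to its configured
    windows (Kawasaki: morning only); ``'relaxed'`` applies every equation to
    every window.
    """
    eq = lib[equation]
    strict = window_policy == "strict"
    if eq.form == "linear":
        if strict and spot.window not in eq.windows:
            return _record(profile.id, eq.name, spot.window, None, "missing_input")
        return predict_intersalt(spot, profile, eq, lib)
    if eq.form == "power_law":
        return predict_power_law(spot, profile, eq, lib, strict_windows=strict)
    if eq.form == "ratio_scaling":
        if strict and spot.window not in eq.windows:
            return _record(profile.id, eq.name, spot.window, None, "missing_input")
        return predict_mage(spot, profile, eq, lib)
    raise ValueError(f"unknown equation form {eq.form!r}")


def predict_all(
    specimens: pd.DataFrame, profiles: pd.DataFrame, lib: CoefficientLibrary,
    *, window_policy: str = "strict",
) -> pd.DataFrame:
    """Run the full equation x window grid over a specimens table.

    One output row per (participant, day, equation, applicable window); under
    the default strict policy Kawasaki rows exist only for morning specimens,
    so a participant with all four windows yields 13 records. Nonphysical and
    missing-input records are kept (flagged) for bookkeeping and excluded by
    the validation layer; exclusion counts are logged.
    """
    if specimens.empty:
        log.warning("predict_all called with an empty specimens table")
        return pd.DataFrame(columns=[
            "participant_id", "day", "equation", "window",
            "predicted_na_mg_day", "quality_flag"])
    prof_by_id = {
        str(r.participant_id): ParticipantProfile(
            id=str(r.participant_id), sex=r.sex, race=r.race, age=r.age_years,
            height=r.height_cm, weight=r.weight_kg, bmi=r.bmi)
        for r in profiles.itertuples()
    }
    rows = []
    for r in specimens.itertuples():
        profile = prof_by_id[str(r.participant_id)]
        spot = SpotMeasurement(
            sodium_conc=r.na_mmol_l, creatinine_conc=r.cr_mg_dl,
            potassium_conc=getattr(r, "k_mmol_l", None), window=r.window)
        for name, eq in lib.equations.items():
            if window_policy == "strict" and spot.window not in eq.windows:
                continue
            rec = predict(spot, profile, name, lib, window_policy=window_policy)
            rows.append({
                "participant_id": rec.participant_id, "day": r.day,
                "equation": rec.equation, "window": rec.window,
                "predicted_na_mg_day": rec.predicted_na,
                "quality_flag": rec.quality_flag,
            })
    out = pd.DataFrame(rows)
    n_bad = int((out.quality_flag != "ok").sum())
    if n_bad:
        log.info("predict_all: %d of %d records flagged (excluded downstream)",
                 n_bad, len(out))
    return out
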