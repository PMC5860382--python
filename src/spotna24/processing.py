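"""Raw per-void records -> timed spot specimens and QC'd 24-hour totals.

Implements the study's collection rules: minute-resolution timed windows,
duration-adjusted volumes and analyte excretions, completeness criteria
(volume >= 500 mL, duration > 20 h, no menstruation, at most one missed or
spilled void), the measured-to-expected creatinine ratio sensitivity filter,
and the four-level hypertension classification.
"""
from __future__ import annotations

import logging

import pandas as pd

from .config import CoefficientLibrary
from .equations import predicted_creatinine
from .types import CompletenessCriteria, ParticipantProfile

log = logging.getLogger(__name__)

#: minute-of-day windows, inclusive at both ends, exactly as printed:
#: overnight additionally requires the first-void-after-longest-sleep flag.
WINDOW_MINUTES = {
    "overnight": (4 * 60, 12 * 60),          # 04:00 - 12:00
    "morning": (8 * 60 + 30, 12 * 60 + 30),  # 08:30 - 12:30
    "afternoon": (12 * 60 + 31, 17 * 60 + 30),
    "evening": (17 * 60 + 31, 23 * 60 + 59),
}


def parse_clock(hhmm: str) -> int:
    """'HH:MM' -> minutes since midnight."""
    h, m = hhmm.split(":")
    minutes = int(h) * 60 + int(m)
    if not 0 <= minutes <= 1439:
        raise ValueError(f"clock time out of range: {hhmm!r}")
    return minutes


def format_clock(minutes: float) -> str:
    minutes = int(round(minutes)) % 1440
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def assign_timed_windows(voids: pd.DataFrame) -> dict[str, pd.Series]:
    """Select up to four timed spot specimens from one day's voids.

    For each window the first qualifying void by clock time is chosen;
    overnight additionally requires ``first_after_sleep``. Because the
    overnight and morning windows overlap (08:30-12:00), a single void may
    serve both; the overlap use is logged. Absent windows are simply absent
    from the result.
    """
    df = voids.assign(_minutes=voids["clock_time"].map(parse_clock))
    df = df.sort_values("_minutes", kind="stable")
    chosen: dict[str, pd.Series] = {}
    for window, (lo, hi) in WINDOW_MINUTES.items():
        sel = df[(df["_minutes"] >= lo) & (df["_minutes"] <= hi)]
        if window == "overnight":
            sel = sel[sel["first_after_sleep"].astype(bool)]
        if not sel.empty:
            chosen[window] = sel.iloc[0]
    if {"overnight", "morning"} <= chosen.keys() and (
            chosen["overnight"]["clock_time"] == chosen["morning"]["clock_time"]):
        log.info("one void at %s serves both overnight and morning windows",
                 chosen["morning"]["clock_time"])
    return chosen


def adjust_volume(total_volume: float, duration: float) -> float:
    """Scale a collection's volume to a 24-hour basis: (volume/duration)*24."""
    if duration <= 0:
        raise ValueError(f"collection duration must be positive, got {duration}")
    return total_volume / duration * 24.0


def daily_excretion(
    voids: pd.DataFrame, duration: float, *, sodium_mg_per_mmol: float = 23.0,
) -> dict[str, float]:
    """Duration-adjusted 24-h analyte excretion from one day's voids.

    Analyte amount = sum(concentration_i x volume_i), scaled by 24/duration.
    Sodium is reported in mg/day (molar factor), potassium in mmol/day,
    creatinine in mg/day (mg/dL x dL).
    """
    for col in ("na_mmol_l", "k_mmol_l", "cr_mg_dl", "volume_ml"):
        bad = voids[voids[col].isna()]
        if not bad.empty:
            raise ValueError(
                f"missing {col} for void(s) at {list(bad['clock_time'])}")
    scale = 24.0 / duration
    vol_l = voids["volume_ml"] / 1000.0
    na_mmol = float((voids["na_mmol_l"] * vol_l).sum()) * scale
    k_mmol = float((voids["k_mmol_l"] * vol_l).sum()) * scale
    cr_mg = float((voids["cr_mg_dl"] * voids["volume_ml"] / 100.0).sum()) * scale
    return {
        "na_mg_day": na_mmol * sodium_mg_per_mmol,
        "k_mmol_day": k_mmol,
        "cr_mg_day": cr_mg,
    }


def check_completeness(
    total_volume: float, duration: float, menstruating: bool,
    missed_or_spilled: int, criteria: CompletenessCriteria | None = None,
) -> tuple[bool, list[str]]:
    """Apply the collection completeness rules; every failure is a reason.

    Volume is inclusive (>= 500 mL passes), duration strict (> 20 h passes),
    menstruation at any time excludes, and more than one missed or spilled
    void excludes.
    """
    c = criteria or CompletenessCriteria()
    reasons = []
    if total_volume < c.min_volume:
        reasons.append("volume")
    if duration <= c.min_duration:
        reasons.append("duration")
    if c.menstruation_excludes and menstruating:
        reasons.append("menstruation")
    if missed_or_spilled > c.max_missed_voids:
        reasons.append("missed_voids")
    return (not reasons, reasons)


def creatinine_ratio_filter(
    measured_cr: float, expected_cr: float, floor: float = 0.6,
) -> tuple[bool, float]:
    """Measured-to-expected 24-h creatinine ratio filter (inclusive floor)."""
    if expected_cr <= 0:
        raise ValueError(f"expected creatinine must be positive, got {expected_cr}")
    ratio = measured_cr / expected_cr
    return ratio >= floor, ratio


def classify_hypertension(
    sbp: float | None, dbp: float | None, on_bp_meds: bool,
    *, strict_gt: bool = True,
) -> str:
    """Four-level BP classification from exam BP (average of readings 2, 3).

    Hypertensive iff BP exceeds 140/90 or on BP-lowering medication; among
    the medicated, below-threshold BP is 'controlled', above is
    'uncontrolled'. ``strict_gt`` follows the study wording (>140 or >90);
    set False for the conventional >=140/>=90.
    """
    if sbp is None or dbp is None or pd.isna(sbp) or pd.isna(dbp):
        raise ValueError("blood pressure readings required for classification")
    high = (sbp > 140 or dbp > 90) if strict_gt else (sbp >= 140 or dbp >= 90)
    if on_bp_meds:
        return "uncontrolled" if high else "controlled"
    return "untreated_hypertensive" if high else "normotensive"


def process_study(
    voids: pd.DataFrame, collections: pd.DataFrame, profiles: pd.DataFrame,
    lib: CoefficientLibrary, criteria: CompletenessCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn raw tables into (timed specimens, daily collection summaries).

    The expected 24-h creatinine used for the ratio filter comes from the
    Mage-form anthropometric equation in the coefficient library.
    """
    criteria = criteria or CompletenessCriteria()
    prof_idx = profiles.set_index(profiles["participant_id"].astype(str))
    spec_rows, daily_rows = [], []
    n_incomplete = 0
    for (pid, day), vg in voids.groupby(["participant_id", "day"], sort=True):
        pid = str(pid)
        coll = collections[
            (collections["participant_id"].astype(str) == pid)
            & (collections["day"] == day)].iloc[0]
        prow = prof_idx.loc[pid]
        vg = vg.sort_values("hours_since_start", kind="stable")

        for window, v in assign_timed_windows(vg).items():
            spec_rows.append({
                "participant_id": pid, "day": day, "window": window,
                "clock_time": v["clock_time"], "na_mmol_l": v["na_mmol_l"],
                "k_mmol_l": v["k_mmol_l"], "cr_mg_dl": v["cr_mg_dl"],
            })

        duration = float(coll["duration_h"])
        total_volume = float(vg["volume_ml"].sum())
        excretion = daily_excretion(
            vg, duration, sodium_mg_per_mmol=lib.sodium_mg_per_mmol)
        missed = int(coll["reported_missed_voids"]) + int(
            vg["missed_or_spilled"].astype(bool).sum())
        complete, reasons = check_completeness(
            total_volume, duration, bool(coll["menstruating"]), missed, criteria)
        n_incomplete += not complete

        profile = ParticipantProfile(
            id=pid, sex=prow["sex"], race=prow["race"], age=prow["age_years"],
            height=prow["height_cm"], weight=prow["weight_kg"], bmi=prow["bmi"])
        expected_cr = predicted_creatinine(
            profile, lib["mage"].predicted_creatinine)
        cr_pass, cr_ratio = creatinine_ratio_filter(
            excretion["cr_mg_day"], expected_cr, criteria.creatinine_ratio_floor)
        htn_class = classify_hypertension(
            prow.get("sbp_mmhg"), prow.get("dbp_mmhg"), bool(prow["on_bp_meds"]))

        daily_rows.append({
            "participant_id": pid, "day": day, "duration_h": duration,
            "total_volume_ml": total_volume,
            "adjusted_volume_ml_24h": adjust_volume(total_volume, duration),
            "complete": int(complete), "reasons": ";".join(reasons),
            **excretion,
            "expected_cr_mg_day": expected_cr, "cr_ratio": cr_ratio,
            "cr_ratio_pass": int(cr_pass), "hypertension_class": htn_class,
        })
    if n_incomplete:
        log.info("process_study: %d of %d collections incomplete",
                 n_incomplete, len(daily_rows))
    return pd.DataFrame(spec_rows), pd.DataFrame(daily_rows)
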