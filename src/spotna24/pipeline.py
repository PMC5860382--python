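"""Stage glue: joins, filters and the validation/report drivers.

Keeps the analysis scripts and the CLI thin: each stage is one function from
tables to tables.
"""
from __future__ import annotations

import logging

import pandas as pd

from .config import CoefficientLibrary
from .stats import DEFAULT_STRATA, EXTRA_STRATA, bland_altman, grid_report, variance_components

log = logging.getLogger(__name__)


def build_paired(
    predictions: pd.DataFrame, daily: pd.DataFrame, profiles: pd.DataFrame,
    *, day: int = 1, require_complete: bool = True,
    creatinine_ratio_floor: float | None = None,
) -> pd.DataFrame:
    """Join same-day predictions with measured 24-h excretion and stratifiers.

    Keeps only quality-flag ``ok`` predictions (flag counts logged); by
    default restricts to complete day-1 collections. Passing a creatinine
    ratio floor additionally applies the measured-to-expected filter.
    """
    meas = daily[daily.day == day].copy()
    n0 = len(meas)
    if require_complete:
        meas = meas[meas.complete.astype(bool)]
    if creatinine_ratio_floor is not None:
        meas = meas[meas.cr_ratio >= creatinine_ratio_floor]
    log.info("build_paired: %d/%d day-%d collections retained", len(meas), n0, day)

    preds = predictions[(predictions.day == day)]
    flag_counts = preds.quality_flag.value_counts().to_dict()
    log.info("build_paired: prediction flags %s", flag_counts)
    preds = preds[preds.quality_flag == "ok"]

    paired = preds.merge(
        meas[["participant_id", "na_mg_day", "hypertension_class"]],
        on="participant_id", how="inner",
    ).rename(columns={"na_mg_day": "measured_na_mg_day"})
    paired = paired.merge(
        profiles[["participant_id", "sex", "race", "diuretic_user", "egfr"]],
        on="participant_id", how="left")
    return paired[paired.measured_na_mg_day > 0]


def duplicate_day_pairs(daily: pd.DataFrame, profiles: pd.DataFrame,
                        column: str = "na_mg_day") -> pd.DataFrame:
    """Wide (day1, day2) table for participants with two complete collections."""
    complete = daily[daily.complete.astype(bool)]
    wide = complete.pivot_table(index="participant_id", columns="day",
                                values=column, aggfunc="first")
    wide = wide.dropna(subset=[1, 2]) if {1, 2} <= set(wide.columns) else wide.iloc[:0]
    wide = wide.rename(columns={1: "day1", 2: "day2"}).reset_index()
    return wide.merge(profiles[["participant_id", "sex", "race"]], on="participant_id")


def validate_study(
    predictions: pd.DataFrame, daily: pd.DataFrame, profiles: pd.DataFrame,
    lib: CoefficientLibrary, *, strata: dict | None = None,
    creatinine_ratio_floor: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Full validation stage: bias/agreement grid, variance components, BA points."""
    paired = build_paired(predictions, daily, profiles,
                          creatinine_ratio_floor=creatinine_ratio_floor)
    lib_windows = {name: eq.windows for name, eq in lib.equations.items()}
    bias, agreement = grid_report(paired, lib_windows, strata=strata)

    ba_rows = []
    for (eq, window), cell in paired.groupby(["equation", "window"]):
        if len(cell) < 3:
            continue
        _, points = bland_altman(cell.predicted_na_mg_day, cell.measured_na_mg_day)
        points.insert(0, "equation", eq)
        points.insert(1, "window", window)
        points.insert(2, "participant_id", cell.participant_id.to_numpy())
        ba_rows.append(points)
    ba_points = (pd.concat(ba_rows, ignore_index=True)
                 if ba_rows else pd.DataFrame())

    var_rows = []
    for column, analyte in (("na_mg_day", "sodium"), ("cr_mg_day", "creatinine"),
                            ("k_mmol_day", "potassium")):
        dup = duplicate_day_pairs(daily, profiles, column)
        for stratum, sel in {"all": None, "african_american": "african_american",
                             "white": "white"}.items():
            sub = dup if sel is None else dup[dup.race == sel]
            if len(sub) < 2:
                continue
            vc = variance_components(sub.day1, sub.day2,
                                     analyte=analyte, stratum=stratum)
            var_rows.append(vc.__dict__)
    variance = pd.DataFrame(var_rows)
    return {"paired": paired, "bias": bias, "agreement": agreement,
            "ba_points": ba_points, "variance": variance}


def all_strata() -> dict:
    return {**DEFAULT_STRATA, **EXTRA_STRATA}
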