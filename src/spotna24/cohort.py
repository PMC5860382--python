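"""Seeded synthetic cohort generator.

Emulates the validation study's structure: 554 participants aged 45-79 (56%
female, 57.6% African American, 51% hypertensive), each with one 24-hour
urine collection split into ~9 voids, a random third with a duplicate
collection day, stratum-calibrated usual sodium excretion, and within:between
day-to-day variance ratios of 1.5 (African American) / 1.1 (white).

Model: person and day effects are lognormal. For a stratum with configured
raw mean m and SD s, the total log-variance is sigma^2 = ln(1 + (s/m)^2) and
the configured within:between ratio r splits it on the log (modelling) scale
as sigma_w^2 = sigma^2 r/(1+r), sigma_b^2 = sigma^2/(1+r). Day totals are
partitioned over voids by Dirichlet weights modulated by an evening-heavy
diurnal profile; spot creatinine follows a Mage-form expected 24-h creatinine
with lognormal day noise, so the ratio-based equations and the creatinine
completeness filter see a realistic joint structure.

Determinism: every draw flows from one ``numpy.random.Generator``; identical
(config, seed) give byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import CohortConfig, CoefficientLibrary, load_coefficients
from .equations import predicted_creatinine
from .processing import format_clock
from .types import ParticipantProfile

log = logging.getLogger(__name__)


@dataclass
class SimulatedStudy:
    profiles: pd.DataFrame
    voids: pd.DataFrame
    collections: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> dict:
        from . import io
        return io.write_study(self, out_dir)


def solve_log_variances(mean: float, sd: float, ratio: float,
                        noise_scale: float = 1.0) -> tuple[float, float, float]:
    """(mu, sigma_b^2, sigma_w^2) for the lognormal person/day model.

    ``ratio`` is within:between on the log scale; ratio r with total
    log-variance V gives within = V r/(1+r), between = V/(1+r).
    """
    if ratio < 0:
        raise ValueError(f"within:between ratio must be >= 0, got {ratio}")
    cv = sd * noise_scale / mean
    total = float(np.log1p(cv ** 2))
    within = total * ratio / (1.0 + ratio)
    between = total / (1.0 + ratio)
    mu = float(np.log(mean) - total / 2.0)
    return mu, between, within


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_profiles(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw participant demographics/anthropometry/clinical flags."""
    n = config.n_participants
    if n <= 0:
        raise ValueError(f"n_participants must be positive, got {n}")
    ns = config.noise_scale
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    race = np.where(rng.random(n) < config.p_african_american,
                    "african_american", "white")
    age = _truncnorm(rng, config.age_mean, config.age_sd * ns, *config.age_bounds, n)
    bmi = _truncnorm(rng, config.bmi_mean, config.bmi_sd * ns, *config.bmi_bounds, n)
    height = np.array([
        rng.normal(config.height_mean[s], config.height_sd * ns) for s in sex])
    weight = bmi * (height / 100.0) ** 2

    hyper = rng.random(n) < config.p_hypertension
    on_meds = hyper & (rng.random(n) < config.p_meds_given_htn)
    controlled = on_meds & (rng.random(n) < config.p_controlled_given_meds)
    diuretic = on_meds & (rng.random(n) < config.p_diuretic_given_meds)
    # BP consistent with the classification the flags imply
    sbp = np.empty(n)
    dbp = np.empty(n)
    below = ~hyper | controlled
    sbp[below] = _truncnorm(rng, 124, 8, 95, 139.5, int(below.sum()))
    dbp[below] = _truncnorm(rng, 76, 6, 55, 89.5, int(below.sum()))
    above = ~below
    sbp[above] = _truncnorm(rng, 152, 9, 140.6, 200, int(above.sum()))
    dbp[above] = _truncnorm(rng, 88, 8, 60, 120, int(above.sum()))
    egfr = _truncnorm(rng, config.egfr_mean, config.egfr_sd * ns,
                      *config.egfr_bounds, n)

    return pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "sex": sex, "race": race,
        "age_years": np.round(age, 1), "height_cm": np.round(height, 1),
        "weight_kg": np.round(weight, 2),
        "bmi": np.round(bmi, 2),
        "sbp_mmhg": np.round(sbp, 1), "dbp_mmhg": np.round(dbp, 1),
        "on_bp_meds": on_meds.astype(int),
        "diuretic_user": diuretic.astype(int),
        "egfr": np.round(egfr, 1),
    })


def sample_daily_sodium(
    profile_row, config: CohortConfig, rng: np.random.Generator, n_days: int = 1,
) -> tuple[float, np.ndarray]:
    """(latent usual sodium mg/day, per-day true excretions) for one person."""
    mean, sd = config.usual_sodium[(profile_row["race"], profile_row["sex"])]
    ratio = config.wb_ratio[profile_row["race"]]
    mu, vb, vw = solve_log_variances(mean, sd, ratio, config.noise_scale)
    b = rng.normal(0.0, np.sqrt(vb))
    usual = float(np.exp(mu + b))
    days = usual * np.exp(rng.normal(0.0, np.sqrt(vw), size=n_days))
    return usual, days


def sample_stratum_days(
    race: str, sex: str, config: CohortConfig, rng: np.random.Generator,
    n_participants: int, n_days: int = 2,
) -> np.ndarray:
    """Vectorised (n_participants, n_days) true day excretions for one stratum."""
    mean, sd = config.usual_sodium[(race, sex)]
    mu, vb, vw = solve_log_variances(mean, sd, config.wb_ratio[race],
                                     config.noise_scale)
    b = rng.normal(0.0, np.sqrt(vb), size=(n_participants, 1))
    w = rng.normal(0.0, np.sqrt(vw), size=(n_participants, n_days))
    return np.exp(mu + b + w)


def synthetic_pairs_from_moments(
    mean_predicted: float, sd_predicted: float, mean_measured: float,
    sd_measured: float, n: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (predicted, measured) samples with the group means hit exactly.

    Gaussian noise at the given SDs is re-centred to zero mean, so the sample
    means equal the specified group means to float precision while individual
    pairs still vary. Used to exercise group-level bias arithmetic against
    published summary tables, which report exactly these moments.
    """
    e = rng.normal(0.0, sd_predicted, n)
    f = rng.normal(0.0, sd_measured, n)
    return mean_predicted + e - e.mean(), mean_measured + f - f.mean()


def _diurnal_weight(minutes: float, weights: dict) -> float:
    if minutes < 4 * 60:
        return weights["night"]
    if minutes <= 12 * 60 + 30:
        return weights["overnight"]
    if minutes <= 17 * 60 + 30:
        return weights["afternoon"]
    return weights["evening"]


def allocate_voids(
    day_totals: dict[str, float], duration: float, start_minutes: float,
    config: CohortConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    """Partition one day's analyte totals over a realistic void sequence.

    Void count is Poisson around the configured mean, redrawn (and logged)
    outside the 3-23 range. Times avoid a simulated sleep gap; the void
    following the longest inter-void gap is flagged ``first_after_sleep``.
    Amounts are conserved exactly: per analyte the Dirichlet weights sum to 1.
    """
    if day_totals["na_mmol"] <= 0:
        raise ValueError("day sodium total must be positive")
    lo, hi = config.voids_range
    n = int(rng.poisson(config.voids_mean))
    while not lo <= n <= hi:
        log.debug("redrawing void count %d outside [%d, %d]", n, lo, hi)
        n = int(rng.poisson(config.voids_mean))

    # waking span in hours since start; sleep runs from `sleep_at` to `wake_at`
    sleep_clock = rng.normal(23.25, 0.5)
    wake_clock = rng.normal(6.75, 0.5)
    sleep_at = (sleep_clock * 60 - start_minutes) % 1440 / 60.0
    wake_at = (wake_clock * 60 - start_minutes) % 1440 / 60.0
    wake_at = min(wake_at, duration - 0.2)
    times = [rng.uniform(0.0, 0.3), wake_at + rng.uniform(0.05, 0.4)]
    spans = [(0.3, max(sleep_at, 0.5)), (wake_at + 0.4, max(duration, wake_at + 0.5))]
    widths = np.array([max(b - a, 1e-6) for a, b in spans])
    for _ in range(n - 2):
        a, b = spans[rng.choice(2, p=widths / widths.sum())]
        times.append(rng.uniform(a, b))
    times = np.sort(np.clip(np.array(times[:n]), 0.0, duration))
    gaps = np.diff(np.concatenate([[0.0], times]))
    first_after_sleep = np.zeros(n, dtype=int)
    first_after_sleep[int(np.argmax(gaps))] = 1

    clock = (start_minutes + times * 60.0) % 1440
    profile = np.array([_diurnal_weight(c, config.diurnal_weights) for c in clock])
    profile = profile / profile.sum()

    vol_w = rng.dirichlet(np.full(n, config.dirichlet_volume_conc))
    na_w = rng.dirichlet(config.dirichlet_analyte_conc * n * profile)
    k_w = rng.dirichlet(config.dirichlet_analyte_conc * n * profile)
    # creatinine output follows the same diurnal profile as sodium: urine
    # dilution (volume) hits both analytes alike, so Na/Cr stays stable while
    # evening concentrations peak for both
    cr_w = rng.dirichlet(config.dirichlet_creatinine_conc * n * profile)
    volumes = day_totals["volume_ml"] * vol_w

    return pd.DataFrame({
        "hours_since_start": times,
        "clock_time": [format_clock(c) for c in clock],
        "volume_ml": volumes,
        "na_mmol_l": day_totals["na_mmol"] * na_w / (volumes / 1000.0),
        "k_mmol_l": day_totals["k_mmol"] * k_w / (volumes / 1000.0),
        "cr_mg_dl": day_totals["cr_mg"] * cr_w / (volumes / 100.0),
        "first_after_sleep": first_after_sleep,
        "missed_or_spilled": 0,
    })


def generate_study(
    config: CohortConfig | None = None, seed: int = 0,
    lib: CoefficientLibrary | None = None,
) -> SimulatedStudy:
    """Generate the full synthetic study: profiles, voids, collections, truth."""
    config = config or CohortConfig()
    lib = lib or load_coefficients()
    rng = np.random.default_rng(seed)
    profiles = sample_profiles(config, rng)
    ns = config.noise_scale

    second_day = rng.random(len(profiles)) < config.p_second_day
    void_rows, coll_rows, truth_rows = [], [], []
    for i, prow in profiles.iterrows():
        pid = prow["participant_id"]
        n_days = 2 if second_day[i] else 1
        usual, days = sample_daily_sodium(prow, config, rng, n_days=n_days)
        profile = ParticipantProfile(
            id=pid, sex=prow["sex"], race=prow["race"], age=prow["age_years"],
            height=prow["height_cm"], weight=prow["weight_kg"], bmi=prow["bmi"])
        expected_cr = predicted_creatinine(
            profile, lib["mage"].predicted_creatinine)
        # potassium gets its own person/day split, reusing the race's ratio
        k_mu, k_vb, k_vw = solve_log_variances(
            config.potassium_mean_mmol, config.potassium_sd_mmol,
            config.wb_ratio[prow["race"]], ns)
        k_person = float(np.exp(k_mu + rng.normal(0.0, np.sqrt(k_vb))))
        for day in range(1, n_days + 1):
            na_mg = float(days[day - 1])
            k_mmol = k_person * float(np.exp(rng.normal(0.0, np.sqrt(k_vw))))
            cr_mg = expected_cr * float(np.exp(rng.normal(
                -(config.creatinine_day_sigma * ns) ** 2 / 2,
                config.creatinine_day_sigma * ns)))
            volume = config.total_volume_mean * float(np.exp(rng.normal(
                -(config.volume_sigma * ns) ** 2 / 2, config.volume_sigma * ns)))
            duration = float(np.clip(
                rng.normal(config.duration_mean, config.duration_sd * ns),
                *config.duration_bounds)) if ns > 0 else config.duration_mean
            start_minutes = rng.uniform(7.5 * 60, 9.5 * 60)

            voids = allocate_voids(
                {"na_mmol": na_mg / lib.sodium_mg_per_mmol, "k_mmol": k_mmol,
                 "cr_mg": cr_mg, "volume_ml": volume},
                duration, start_minutes, config, rng)
            voids.insert(0, "participant_id", pid)
            voids.insert(1, "day", day)
            void_rows.append(voids)

            menstruating = (prow["sex"] == "female"
                            and rng.random() < config.p_menstruating * min(ns, 1.0))
            missed = int(rng.random() < config.p_missed_void * min(ns, 1.0))
            coll_rows.append({
                "participant_id": pid, "day": day,
                "start_time": format_clock(start_minutes),
                "stop_time": format_clock(start_minutes + duration * 60.0),
                "duration_h": round(duration, 3),
                "menstruating": int(menstruating),
                "reported_missed_voids": missed,
            })
            truth_rows.append({
                "participant_id": pid, "day": day,
                "usual_na_mg_day": usual, "true_na_mg_day": na_mg,
                "true_k_mmol_day": k_mmol, "true_cr_mg_day": cr_mg,
            })

    study = SimulatedStudy(
        profiles=profiles,
        voids=pd.concat(void_rows, ignore_index=True),
        collections=pd.DataFrame(coll_rows),
        truth=pd.DataFrame(truth_rows),
    )
    log.info("generated %d participants, %d with a second day, %d voids",
             len(profiles), int(second_day.sum()), len(study.voids))
    return study
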