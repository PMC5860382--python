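"""Agreement and variability statistics for the equation validation.

Conventions, preserved deliberately:

* Bias is predicted minus measured; the group CI uses the 1.96 normal
  multiplier on the SEM of the differences while the p-value comes from the
  paired t distribution (the two do not exactly agree at small n).
* Relative bias is 100 x (P - M) / ((P + M) / 2); limits of agreement are
  mean +/- 1.96 x sample SD (n-1 denominator).
* Variance components use the balanced two-replicate method of moments:
  within = mean(d_i^2 / 2), between = var(person means) - within/2 floored at
  zero; within-person CV = 100 x sqrt(within) / grand mean.
* ICC variant: one-way random effects, single measure (ICC1); recorded in the
  output metadata because the choice is a convention, not a given.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import AgreementSummary, BiasSummary, VarianceComponents

log = logging.getLogger(__name__)

Z95 = 1.96


def mean_bias(predicted, measured) -> BiasSummary:
    """Group mean bias (predicted - measured) with 1.96xSEM CI and paired-t p."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape:
        raise ValueError("predicted and measured must be paired")
    n = p.size
    if n < 2:
        raise ValueError(f"mean_bias needs at least 2 pairs, got {n}")
    d = p - m
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = Z95 * sd / np.sqrt(n)
    if sd == 0:
        pval = 0.0 if mean != 0 else 1.0
    else:
        pval = float(sps.ttest_rel(p, m).pvalue)
    return BiasSummary(n=n, mean_bias=mean, sd_diff=sd,
                       ci_low=mean - half, ci_high=mean + half, p_value=pval)


def relative_bias(predicted, measured):
    """Percent relative bias: 100 (P - M) / ((P + M) / 2), elementwise.

    Antisymmetric under swapping P and M; bounded in (-200, 200) for positive
    inputs. Pairs with P + M = 0 are returned as NaN with a warning.
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    denom = (p + m) / 2.0
    bad = denom == 0
    if np.any(bad):
        warnings.warn(f"excluding {int(bad.sum())} pair(s) with P + M = 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, 100.0 * (p - m) / denom)
    return out if out.ndim else float(out)


def _icc_oneway(measured: np.ndarray, predicted: np.ndarray) -> float | None:
    """ICC(1,1): one-way random effects, single measurement, k = 2 ratings."""
    x = np.column_stack([measured, predicted])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    ss_between = k * np.sum((row_means - grand) ** 2)
    ss_within = np.sum((x - row_means[:, None]) ** 2)
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return None
    return float((msb - msw) / denom)


def correlations(predicted, measured) -> tuple[float | None, float | None]:
    """(Spearman rho, one-way single-measure ICC) for a paired sample.

    A constant vector makes rho undefined; it is reported as None.
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.size < 3:
        raise ValueError("correlations need at least 3 pairs")
    if np.all(p == p[0]) or np.all(m == m[0]):
        log.warning("constant vector: Spearman rho undefined")
        rho = None
    else:
        rho = float(sps.spearmanr(m, p).statistic)
    return rho, _icc_oneway(m, p)


def bland_altman(predicted, measured) -> tuple[AgreementSummary, pd.DataFrame]:
    """Bland-Altman on the relative-bias scale.

    Returns the agreement summary (mean relative bias, 95% limits of
    agreement, Spearman rho, ICC) and the per-pair plot table
    (x = mean of predicted and measured, y = relative bias %).
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.size < 3:
        raise ValueError(f"bland_altman needs at least 3 pairs, got {p.size}")
    rb = np.asarray(relative_bias(p, m))
    keep = ~np.isnan(rb)
    rb, p, m = rb[keep], p[keep], m[keep]
    mean_rb = float(rb.mean())
    sd_rb = float(rb.std(ddof=1))
    rho, icc = correlations(p, m)
    summary = AgreementSummary(
        n=int(rb.size), mean_relative_bias=mean_rb,
        loa_low=mean_rb - Z95 * sd_rb, loa_high=mean_rb + Z95 * sd_rb,
        spearman_rho=rho, icc=icc)
    points = pd.DataFrame({"pair_mean": (p + m) / 2.0, "relative_bias_pct": rb})
    return summary, points


def variance_components(
    day1, day2, *, analyte: str = "sodium", stratum: str = "all",
) -> VarianceComponents:
    """Within/between-person variance from duplicate collection days.

    Balanced two-replicate decomposition: within = mean(d_i^2/2) over
    participants, between = var(person means, ddof=1) - within/2, floored at
    zero (ratio then reported as missing). Exactly invariant to relabelling
    day 1 and day 2.
    """
    x1 = np.asarray(day1, dtype=float)
    x2 = np.asarray(day2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("day1/day2 must pair participants")
    n = x1.size
    if n < 2:
        raise ValueError(f"variance_components needs >= 2 participants, got {n}")
    d = x1 - x2
    within = float(np.mean(d ** 2 / 2.0))
    means = (x1 + x2) / 2.0
    between = float(means.var(ddof=1) - within / 2.0)
    if between <= 0:
        log.warning("between-person variance floored at 0 (%s, %s)", analyte, stratum)
        between = 0.0
        ratio = None
    else:
        ratio = within / between
    grand = float(np.mean(np.concatenate([x1, x2])))
    cv = 100.0 * np.sqrt(within) / grand
    return VarianceComponents(
        analyte=analyte, stratum=stratum, n_pairs=n, within_var=within,
        between_var=between, ratio=ratio, cv_within=cv, grand_mean=grand)


# ---------------------------------------------------------------------------
# The equation x window x stratum grid
# ---------------------------------------------------------------------------

DEFAULT_STRATA = {
    "all": lambda df: pd.Series(True, index=df.index),
    "african_american_men": lambda df: (df.race == "african_american") & (df.sex == "male"),
    "african_american_women": lambda df: (df.race == "african_american") & (df.sex == "female"),
    "white_men": lambda df: (df.race == "white") & (df.sex == "male"),
    "white_women": lambda df: (df.race == "white") & (df.sex == "female"),
}

EXTRA_STRATA = {
    "hypertensive": lambda df: df.hypertension_class != "normotensive",
    "normotensive": lambda df: df.hypertension_class == "normotensive",
    "diuretic_users": lambda df: df.diuretic_user.astype(bool),
    "no_diuretic": lambda df: ~df.diuretic_user.astype(bool),
    "egfr_le_60": lambda df: df.egfr <= 60,
    "egfr_gt_60": lambda df: df.egfr > 60,
}

MIN_CELL_N = 3


def grid_report(
    paired: pd.DataFrame, lib_windows: dict[str, tuple[str, ...]],
    strata: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bias and agreement tables across equations x windows x strata.

    ``paired`` needs columns participant_id, equation, window,
    predicted_na_mg_day, measured_na_mg_day plus any stratifier columns the
    strata selectors use. Cells outside an equation's window policy are
    marked ``not_applicable``; cells with fewer than 3 pairs are
    ``insufficient_n``.
    """
    strata = strata or DEFAULT_STRATA
    windows = ("overnight", "morning", "afternoon", "evening")
    bias_rows, agree_rows = [], []
    for stratum, selector in strata.items():
        sub = paired[selector(paired)] if len(paired) else paired
        for equation, eq_windows in lib_windows.items():
            for window in windows:
                base = {"stratum": stratum, "equation": equation, "window": window}
                if window not in eq_windows:
                    bias_rows.append({**base, "status": "not_applicable", "n": 0})
                    agree_rows.append({**base, "status": "not_applicable", "n": 0})
                    continue
                cell = sub[(sub.equation == equation) & (sub.window == window)]
                if len(cell) < MIN_CELL_N:
                    bias_rows.append({**base, "status": "insufficient_n", "n": len(cell)})
                    agree_rows.append({**base, "status": "insufficient_n", "n": len(cell)})
                    continue
                b = mean_bias(cell.predicted_na_mg_day, cell.measured_na_mg_day)
                a, _ = bland_altman(cell.predicted_na_mg_day, cell.measured_na_mg_day)
                bias_rows.append({
                    **base, "status": "ok", "n": b.n, "mean_bias": b.mean_bias,
                    "sd_diff": b.sd_diff, "ci_low": b.ci_low, "ci_high": b.ci_high,
                    "p_value": b.p_value,
                    "mean_predicted": float(cell.predicted_na_mg_day.mean()),
                    "mean_measured": float(cell.measured_na_mg_day.mean()),
                })
                agree_rows.append({
                    **base, "status": "ok", "n": a.n,
                    "mean_relative_bias_pct": a.mean_relative_bias,
                    "loa_low_pct": a.loa_low, "loa_high_pct": a.loa_high,
                    "spearman_rho": a.spearman_rho, "icc": a.icc,
                    "icc_variant": a.icc_variant,
                })
    return pd.DataFrame(bias_rows), pd.DataFrame(agree_rows)
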