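#!/usr/bin/env python
"""Validate predictions against measured 24-h excretion.

Produces the bias and agreement grids (equation x window x stratum), the
Bland-Altman point tables and the duplicate-day variance components.
Writes results/validation/.
"""
from pathlib import Path

from spotna24 import io
from spotna24.config import load_coefficients
from spotna24.pipeline import validate_study

ROOT = Path(__file__).resolve().parents[1] / "results"

preds = io.read_table(ROOT / "processed" / "predictions.csv", "predictions")
daily = io.read_table(ROOT / "processed" / "daily.csv", "daily")
profiles = io.read_table(ROOT / "synthetic" / "profiles.csv", "profiles")
lib = load_coefficients()

results = validate_study(preds, daily, profiles, lib)
out = ROOT / "validation"
for name in ("bias", "agreement", "variance", "ba_points"):
    io.write_table(results[name], out / f"{name}.csv")

bias = results["bias"]
ok = bias[(bias.stratum == "all") & (bias.status == "ok")]
least = ok.loc[ok.mean_bias.abs().idxmin()]
worst = ok.loc[ok.mean_bias.abs().idxmax()]
print(f"overall least-biased cell: {least.equation}/{least.window} "
      f"({least.mean_bias:+.0f} mg/day, 95% CI {least.ci_low:.0f}..{least.ci_high:.0f})")
print(f"overall most-biased cell:  {worst.equation}/{worst.window} "
      f"({worst.mean_bias:+.0f} mg/day)")

agree = results["agreement"]
aok = agree[(agree.stratum == "all") & (agree.status == "ok")]
print(f"Spearman rho range: {aok.spearman_rho.min():.2f}"
      f"..{aok.spearman_rho.max():.2f}")

var = results["variance"]
na = var[var.analyte == "sodium"].set_index("stratum")
print("\nwithin:between variance ratio, 24-h sodium "
      "(duplicate-day participants):")
print(na[["n_pairs", "ratio", "cv_within"]].round(2))
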