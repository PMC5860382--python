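#!/usr/bin/env python
"""Run the 4-equation x 4-window prediction grid over the timed specimens.

Kawasaki is restricted to morning specimens (its source specimen was a
second morning void). Writes results/processed/predictions.csv.
"""
from pathlib import Path

from spotna24 import io
from spotna24.config import load_coefficients
from spotna24.equations import predict_all

ROOT = Path(__file__).resolve().parents[1] / "results"

specimens = io.read_table(ROOT / "processed" / "specimens.csv", "specimens")
profiles = io.read_table(ROOT / "synthetic" / "profiles.csv", "profiles")
lib = load_coefficients()

preds = predict_all(specimens, profiles, lib)
io.write_table(preds, ROOT / "processed" / "predictions.csv")

print(f"{len(preds)} prediction records "
      f"({(preds.quality_flag != 'ok').sum()} flagged)")
print("\npredicted 24-h sodium (mg/day) by equation, day-1 records:")
print(preds[preds.day == 1].groupby("equation")
      .predicted_na_mg_day.agg(["count", "mean", "std"]).round(0))
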