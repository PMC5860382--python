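#!/usr/bin/env python
"""Process raw voids into timed spot specimens and QC'd daily excretions.

Applies the collection rules (volume >= 500 mL, duration > 20 h, no
menstruation, at most one missed void) and the measured-to-expected
creatinine ratio filter. Writes results/processed/.
"""
from pathlib import Path

from spotna24 import io
from spotna24.config import load_coefficients
from spotna24.processing import process_study

ROOT = Path(__file__).resolve().parents[1] / "results"
raw = ROOT / "synthetic"

voids = io.read_table(raw / "voids.csv", "voids")
collections = io.read_table(raw / "collections.csv", "collections")
profiles = io.read_table(raw / "profiles.csv", "profiles")
lib = load_coefficients()

specimens, daily = process_study(voids, collections, profiles, lib)
io.write_table(specimens, ROOT / "processed" / "specimens.csv")
io.write_table(daily, ROOT / "processed" / "daily.csv")

print(f"{len(daily)} collections: {daily.complete.mean():.1%} complete; "
      f"reasons among incomplete: "
      f"{daily.loc[~daily.complete.astype(bool), 'reasons'].value_counts().to_dict()}")
print(f"creatinine ratio >= 0.6: {daily.cr_ratio_pass.mean():.1%}")
print(f"specimens per collection: "
      f"{specimens.groupby(['participant_id', 'day']).size().mean():.2f} "
      f"(max 4 windows)")
conc = specimens.groupby("window")[["na_mmol_l", "cr_mg_dl"]].mean().round(1)
print("\nmean spot concentrations by window (evening runs highest):")
print(conc)
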