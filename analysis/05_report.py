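#!/usr/bin/env python
"""Render figures: one Bland-Altman panel per populated equation x window
(13 under the default window policy) and a bias forest per stratum.

Figures land under results/figures/ (regenerable binary output).
"""
from pathlib import Path

import pandas as pd

from spotna24.report import render_report

ROOT = Path(__file__).resolve().parents[1] / "results"
val = ROOT / "validation"

bias = pd.read_csv(val / "bias.csv")
agreement = pd.read_csv(val / "agreement.csv")
ba_points = pd.read_csv(val / "ba_points.csv")

written = render_report({"ba_points": ba_points}, bias, agreement,
                        ROOT / "figures")
print(f"wrote {len(written)} figures to {ROOT / 'figures'}")
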