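"""Figure emission: Bland-Altman panels and subgroup bias forest plots."""
from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def bland_altman_figure(points: pd.DataFrame, summary_row, path: Path) -> Path:
    """One Bland-Altman panel: relative bias vs pair mean with LoA lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(points.pair_mean, points.relative_bias_pct, s=8, alpha=0.5,
               color="#30506d")
    ax.axhline(summary_row["mean_relative_bias_pct"], color="black", lw=1.2)
    for key in ("loa_low_pct", "loa_high_pct"):
        ax.axhline(summary_row[key], color="black", lw=1, ls="--")
    ax.set_xlabel("Mean of predicted and measured 24-h Na (mg/day)")
    ax.set_ylabel("Relative bias (%)")
    ax.set_title(f"{summary_row['equation']} / {summary_row['window']}"
                 f" (n={int(summary_row['n'])})", fontsize=10)
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def bias_forest_figure(bias: pd.DataFrame, stratum: str, path: Path) -> Path:
    """Mean bias with 95% CI per equation x window for one stratum."""
    sub = bias[(bias.stratum == stratum) & (bias.status == "ok")]
    fig, ax = plt.subplots(figsize=(7, 5))
    markers = {"overnight": "D", "morning": "s", "afternoon": "^", "evening": "x"}
    equations = list(dict.fromkeys(sub.equation))
    for i, eq in enumerate(equations):
        for j, (_, row) in enumerate(sub[sub.equation == eq].iterrows()):
            x = i + (j - 1.5) * 0.15
            ax.errorbar(x, row.mean_bias,
                        yerr=[[row.mean_bias - row.ci_low],
                              [row.ci_high - row.mean_bias]],
                        fmt=markers.get(row.window, "o"), color="#30506d",
                        capsize=3, ms=5)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xticks(range(len(equations)), equations)
    ax.set_ylabel("Mean bias, predicted - measured (mg/day)")
    ax.set_title(f"Group mean bias with 95% CI: {stratum}", fontsize=10)
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_report(results: dict, bias: pd.DataFrame, agreement: pd.DataFrame,
                  out_dir: str | Path) -> list[Path]:
    """Emit every Bland-Altman panel (one per populated equation x window)
    and a bias forest per stratum."""
    out = Path(out_dir)
    written = []
    agree_all = agreement[(agreement.stratum == "all") & (agreement.status == "ok")]
    for _, row in agree_all.iterrows():
        pts = results["ba_points"]
        pts = pts[(pts.equation == row.equation) & (pts.window == row.window)]
        if pts.empty:
            continue
        written.append(bland_altman_figure(
            pts, row, out / f"bland_altman_{row.equation}_{row.window}.png"))
    for stratum in bias.stratum.unique():
        written.append(bias_forest_figure(bias, stratum,
                                          out / f"bias_forest_{stratum}.png"))
    return written
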