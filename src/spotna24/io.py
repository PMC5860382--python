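"""CSV schemas, validated readers/writers and the run manifest.

Every table is UTF-8 CSV with dot decimals and HH:MM clock times; flags are
0/1 integers. Readers fail with row-level diagnostics on missing or
non-numeric required columns and warn about (but keep) unknown columns.
"""
from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .types import RunManifest

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table failed schema validation; the message names column and row."""


#: schema name -> {column: kind}, kind in {"str", "num", "int", "flag", "clock"}
SCHEMAS = {
    "profiles": {
        "participant_id": "str", "sex": "str", "race": "str",
        "age_years": "num", "height_cm": "num", "weight_kg": "num",
        "bmi": "num", "sbp_mmhg": "num", "dbp_mmhg": "num",
        "on_bp_meds": "flag", "diuretic_user": "flag", "egfr": "num",
    },
    "voids": {
        "participant_id": "str", "day": "int", "hours_since_start": "num",
        "clock_time": "clock", "volume_ml": "num", "na_mmol_l": "num",
        "k_mmol_l": "num", "cr_mg_dl": "num",
        "first_after_sleep": "flag", "missed_or_spilled": "flag",
    },
    "collections": {
        "participant_id": "str", "day": "int", "start_time": "clock",
        "stop_time": "clock", "duration_h": "num",
        "menstruating": "flag", "reported_missed_voids": "int",
    },
    "truth": {
        "participant_id": "str", "day": "int", "usual_na_mg_day": "num",
        "true_na_mg_day": "num", "true_k_mmol_day": "num",
        "true_cr_mg_day": "num",
    },
    "specimens": {
        "participant_id": "str", "day": "int", "window": "str",
        "clock_time": "clock", "na_mmol_l": "num", "k_mmol_l": "num",
        "cr_mg_dl": "num",
    },
    "daily": {
        "participant_id": "str", "day": "int", "duration_h": "num",
        "total_volume_ml": "num", "adjusted_volume_ml_24h": "num",
        "complete": "flag", "reasons": "str*", "na_mg_day": "num",
        "k_mmol_day": "num", "cr_mg_day": "num", "expected_cr_mg_day": "num",
        "cr_ratio": "num", "cr_ratio_pass": "flag", "hypertension_class": "str",
    },
    "predictions": {
        "participant_id": "str", "day": "int", "equation": "str",
        "window": "str", "predicted_na_mg_day": "num*", "quality_flag": "str",
    },
}


def _check_column(df: pd.DataFrame, name: str, col: str, kind: str) -> None:
    optional_values = kind.endswith("*")
    kind = kind.rstrip("*")
    series = df[col]
    if kind in ("num", "int"):
        coerced = pd.to_numeric(series, errors="coerce")
        bad = coerced.isna() & series.notna()
        if not optional_values:
            bad |= series.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{name}: column {col!r} has a non-numeric or missing value "
                f"at row {row} ({series.loc[row]!r})")
    elif kind == "flag":
        ok = series.isin([0, 1, "0", "1", True, False])
        if not ok.all():
            row = int((~ok).idxmax())
            raise SchemaError(
                f"{name}: column {col!r} must be 0/1, got {series.loc[row]!r} "
                f"at row {row}")
    elif kind == "clock":
        pat = series.astype(str).str.match(r"^\d{2}:\d{2}$")
        if not pat.all():
            row = int((~pat).idxmax())
            raise SchemaError(
                f"{name}: column {col!r} must be HH:MM, got {series.loc[row]!r} "
                f"at row {row}")
    elif kind == "str" and not optional_values:
        if series.isna().any():
            row = int(series.isna().idxmax())
            raise SchemaError(f"{name}: column {col!r} missing at row {row}")


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in cols]
    if unknown:
        log.warning("%s: unknown column(s) %s kept as-is", schema, unknown)
    for col, kind in cols.items():
        _check_column(df, schema, col, kind)
    out = df.copy()
    for col, kind in cols.items():
        base = kind.rstrip("*")
        if base == "num":
            out[col] = pd.to_numeric(out[col], errors="coerce")
        elif base in ("int", "flag"):
            out[col] = pd.to_numeric(out[col], errors="coerce").astype("Int64")
    out["participant_id"] = out["participant_id"].astype(str)
    return out


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_study(study, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    return {
        "profiles": write_table(study.profiles, out / "profiles.csv"),
        "voids": write_table(study.voids, out / "voids.csv"),
        "collections": write_table(study.collections, out / "collections.csv"),
        "truth": write_table(study.truth, out / "truth.csv"),
    }


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path, command: str, *, seed: int | None = None,
    config_hash: str = "", inputs: dict | None = None,
    stage_counts: dict | None = None,
) -> Path:
    from . import __version__
    manifest = RunManifest(
        command=command, seed=seed, config_hash=config_hash,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        input_digests={k: file_digest(v) for k, v in (inputs or {}).items()},
        stage_counts=stage_counts or {},
    )
    path = Path(out_dir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest.__dict__, indent=2) + "\n")
    return path
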