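"""Domain types shared across the pipeline.

Plain dataclasses, not pandas rows: the tabular layer (``spotna24.io``)
converts between these and the CSV schemas, while the numeric layer works
with whichever is more convenient.
"""
from __future__ import annotations

from dataclasses import dataclass, field

SEXES = ("male", "female")
RACES = ("white", "african_american")
WINDOWS = ("overnight", "morning", "afternoon", "evening")
QUALITY_FLAGS = ("ok", "nonphysical", "missing_input")
HTN_CLASSES = ("normotensive", "controlled", "uncontrolled", "untreated_hypertensive")


@dataclass
class ParticipantProfile:
    """Demographics, anthropometry and clinical flags feeding the equations."""

    id: str
    sex: str
    race: str
    age: float            # years
    height: float         # cm
    weight: float         # kg
    bmi: float            # kg/m^2
    hypertensive: bool = False
    on_bp_meds: bool = False
    diuretic_user: bool = False
    egfr: float = 90.0    # mL/min/1.73m^2
    sbp: float | None = None   # mm Hg, average of readings 2 and 3
    dbp: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.race not in RACES:
            raise ValueError(f"unknown race {self.race!r}")


@dataclass
class SpotMeasurement:
    """Analyte concentrations of one timed spot specimen.

    Units: sodium/potassium mmol/L, creatinine mg/dL. ``potassium_conc`` may
    be None; equations that need it flag the record instead of imputing.
    """

    sodium_conc: float
    creatinine_conc: float
    window: str
    potassium_conc: float | None = None

    def __post_init__(self) -> None:
        if self.window not in WINDOWS:
            raise ValueError(f"unknown window {self.window!r}")
        if self.sodium_conc < 0 or self.creatinine_conc < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass
class PredictionRecord:
    """Per-(participant, equation, window) predicted 24-h sodium excretion."""

    participant_id: str
    equation: str
    window: str
    predicted_na: float | None   # mg/day, present iff quality_flag == "ok"
    quality_flag: str = "ok"


@dataclass
class CompletenessCriteria:
    """Thresholds deciding whether a 24-hour collection counts as complete."""

    min_volume: float = 500.0       # mL, inclusive
    min_duration: float = 20.0      # hours, strict (> 20 h passes)
    max_missed_voids: int = 1       # "missing a void more than once" fails
    menstruation_excludes: bool = True
    creatinine_ratio_floor: float = 0.6   # sensitivity filter, inclusive


@dataclass
class BiasSummary:
    n: int
    mean_bias: float       # mg/day, predicted - measured
    sd_diff: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class AgreementSummary:
    n: int
    mean_relative_bias: float   # percent
    loa_low: float              # percent
    loa_high: float
    spearman_rho: float | None
    icc: float | None
    icc_variant: str = "one-way random, single measure (ICC1)"


@dataclass
class VarianceComponents:
    analyte: str
    stratum: str
    n_pairs: int
    within_var: float
    between_var: float
    ratio: float | None         # within / between; None when between floored to 0
    cv_within: float            # percent
    grand_mean: float


@dataclass
class RunManifest:
    """Provenance record emitted next to every pipeline output."""

    command: str
    seed: int | None
    config_hash: str
    package_version: str
    timestamp: str
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
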