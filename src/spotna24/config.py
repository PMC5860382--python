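"""Coefficient library and cohort configuration.

Equation coefficients are never hard-coded: they live in a packaged YAML file
(``spotna24/data/coefficients.yaml``) with one block per equation declaring its
functional form, stratification, unit dialect and named terms, so alternative
published variants can be swapped in via ``load_coefficients(path)``.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

EQUATIONS = ("intersalt", "tanaka", "kawasaki", "mage")

#: multiplicative factors taking a spot creatinine in mg/dL into each dialect
_CR_DIALECTS = {
    "mg_per_dl": 1.0,
    "mg_per_l": 10.0,
    "g_per_l": 0.01,
    # mg/dL -> mg/L -> mmol/L (creatinine molar mass 113.12 g/mol)
    "mmol_per_l": 10.0 / 113.12,
}


def convert_creatinine(conc_mg_dl: float, dialect: str) -> float:
    """Convert a spot creatinine concentration from mg/dL into *dialect*.

    Conversions are explicit and logged; unknown dialects raise rather than
    silently coercing.
    """
    try:
        factor = _CR_DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown creatinine dialect {dialect!r}") from None
    log.debug("creatinine %.4g mg/dL -> %.4g %s", conc_mg_dl, conc_mg_dl * factor, dialect)
    return conc_mg_dl * factor


@dataclass
class CreatinineSpec:
    """Expected (predicted) 24-h creatinine equation: form + stratified terms."""

    form: str                    # "linear" | "mage_power"
    strata_by: tuple[str, ...]   # subset of ("sex", "race")
    terms: dict[str, dict[str, float]]

    def stratum_key(self, sex: str, race: str) -> str:
        parts = {"sex": sex, "race": race}
        if not self.strata_by:
            return "all"
        return "|".join(parts[s] for s in self.strata_by)


@dataclass
class EquationSpec:
    name: str
    form: str                    # "linear" | "power_law" | "ratio_scaling"
    windows: tuple[str, ...]
    unit_dialect: dict[str, str]
    strata_by: tuple[str, ...] = ()
    terms: dict[str, dict[str, float]] = field(default_factory=dict)
    scale: float | None = None
    exponent: float | None = None
    predicted_creatinine: CreatinineSpec | None = None

    def stratum_key(self, sex: str, race: str) -> str:
        parts = {"sex": sex, "race": race}
        if not self.strata_by:
            return "all"
        return "|".join(parts[s] for s in self.strata_by)


@dataclass
class CoefficientLibrary:
    sodium_mg_per_mmol: float
    creatinine_mg_per_mmol: float
    equations: dict[str, EquationSpec]
    source_hash: str = ""

    def __getitem__(self, name: str) -> EquationSpec:
        return self.equations[name]

    def mmol_to_mg(self, mmol_per_day: float) -> float:
        return mmol_per_day * self.sodium_mg_per_mmol

    def mg_to_mmol(self, mg_per_day: float) -> float:
        return mg_per_day / self.sodium_mg_per_mmol


def _parse_creatinine(block: dict) -> CreatinineSpec:
    return CreatinineSpec(
        form=block["form"],
        strata_by=tuple(block.get("strata_by", [])),
        terms={k: dict(v) for k, v in block["terms"].items()},
    )


def load_coefficients(path: str | Path | None = None) -> CoefficientLibrary:
    """Load the packaged default coefficient config, or a user override."""
    if path is None:
        text = resources.files("spotna24.data").joinpath("coefficients.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    eqs: dict[str, EquationSpec] = {}
    for name, block in raw["equations"].items():
        pc = block.get("predicted_creatinine")
        eqs[name] = EquationSpec(
            name=name,
            form=block["form"],
            windows=tuple(block["windows"]),
            unit_dialect=dict(block["unit_dialect"]),
            strata_by=tuple(block.get("strata_by", [])),
            terms={k: dict(v) for k, v in block.get("terms", {}).items()},
            scale=block.get("scale"),
            exponent=block.get("exponent"),
            predicted_creatinine=_parse_creatinine(pc) if pc else None,
        )
    lib = CoefficientLibrary(
        sodium_mg_per_mmol=float(raw["sodium_mg_per_mmol"]),
        creatinine_mg_per_mmol=float(raw["creatinine_mg_per_mmol"]),
        equations=eqs,
        source_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
    )
    missing = set(EQUATIONS) - set(eqs)
    if missing:
        raise ValueError(f"coefficient config missing equations: {sorted(missing)}")
    return lib


# ---------------------------------------------------------------------------
# Synthetic cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Defaults emulate the validation study's printed cohort structure:

    554 participants aged 45-79 (56% female, 57.6% African American, 51%
    hypertensive, 15.9% on diuretics), one third with a second collection day,
    ~9 voids/day, mean total urine volume 1,838 mL, stratum 24-h sodium
    means/SDs of 3,926 (1,623) white men, 2,480 (1,079) white women, 3,454
    (1,651) African-American men and 3,397 (1,641) African-American women, and
    within:between variance ratios of 1.5 (African American) / 1.1 (white).
    """

    n_participants: int = 554
    p_female: float = 0.56
    p_african_american: float = 0.576
    p_hypertension: float = 0.51
    p_meds_given_htn: float = 0.75
    p_controlled_given_meds: float = 0.5
    p_diuretic_given_meds: float = 0.42
    p_second_day: float = 1.0 / 3.0

    age_mean: float = 60.3
    age_sd: float = 9.1
    age_bounds: tuple[float, float] = (45.0, 79.0)
    bmi_mean: float = 30.0
    bmi_sd: float = 6.5
    bmi_bounds: tuple[float, float] = (16.0, 55.0)
    height_mean: dict = field(default_factory=lambda: {"male": 176.0, "female": 162.0})
    height_sd: float = 7.0

    # usual 24-h sodium excretion (mg/day): stratum -> (mean, SD)
    usual_sodium: dict = field(default_factory=lambda: {
        ("white", "male"): (3926.0, 1623.0),
        ("white", "female"): (2480.0, 1079.0),
        ("african_american", "male"): (3454.0, 1651.0),
        ("african_american", "female"): (3397.0, 1641.0),
    })
    # within-person : between-person variance ratio, on the log modelling scale
    wb_ratio: dict = field(default_factory=lambda: {
        "african_american": 1.5,
        "white": 1.1,
    })

    potassium_mean_mmol: float = 60.0
    potassium_sd_mmol: float = 20.0
    creatinine_day_sigma: float = 0.20   # lognormal sigma around expected CER

    voids_mean: float = 9.0
    voids_range: tuple[int, int] = (3, 23)
    total_volume_mean: float = 1838.0
    volume_sigma: float = 0.30           # lognormal sigma of daily volume
    duration_mean: float = 24.0
    duration_sd: float = 0.5
    duration_bounds: tuple[float, float] = (21.0, 26.0)

    # relative diurnal weight of analyte output by time of day; normalised at
    # use. Evening-heavy by default: evening spot concentrations run highest.
    diurnal_weights: dict = field(default_factory=lambda: {
        "night": 0.7,      # 00:00-04:00 and post-23:59
        "overnight": 0.9,  # 04:00-12:30
        "afternoon": 1.0,  # 12:31-17:30
        "evening": 1.3,    # 17:31-23:59
    })
    dirichlet_volume_conc: float = 3.0
    dirichlet_analyte_conc: float = 12.0
    dirichlet_creatinine_conc: float = 24.0

    p_missed_void: float = 0.02
    p_menstruating: float = 0.01
    egfr_mean: float = 85.0
    egfr_sd: float = 16.0
    egfr_bounds: tuple[float, float] = (30.0, 130.0)

    noise_scale: float = 1.0   # global multiplier on every random spread

    def config_hash(self) -> str:
        canon = yaml.safe_dump(
            {k: repr(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
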