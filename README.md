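# spotna24

Validation toolkit for predicting **24-hour urinary sodium excretion** from a
single timed spot urine specimen.

Twenty-four-hour urinary sodium is the gold-standard biomarker of daily salt
intake, but full collections are burdensome, so epidemiological studies often
substitute a single spot specimen pushed through a published estimating
equation. This package implements the four standard equations — INTERSALT
(with potassium), Tanaka, Kawasaki and Mage — together with the machinery
needed to *validate* them against measured 24-hour collections in an older,
racially diverse, largely hypertensive population: collection quality control,
timed-window specimen selection, group and individual agreement statistics,
day-to-day variance decomposition, and a seeded synthetic cohort generator so
the whole pipeline runs without any restricted data.

It is written for nutritional epidemiologists and biostatisticians who need
either the equations themselves or a reproducible harness for studying their
group-level bias.

## The statistics at the core

For participant $i$ with measured excretion $M_i$ and equation prediction
$P_i$ (both mg/day):

* **Group mean bias** $\bar d = \tfrac1n\sum (P_i - M_i)$ with 95% CI
  $\bar d \pm 1.96\,s_d/\sqrt n$ and a paired *t* test.
* **Relative bias** $100\,(P_i-M_i)\big/\tfrac{P_i+M_i}{2}$, plotted
  Bland-Altman style against the pair mean, with 95% limits of agreement
  $\bar r \pm 1.96\,s_r$.
* **Rank agreement**: Spearman $\rho$ and a one-way random-effects,
  single-measure ICC.
* **Day-to-day variability** from duplicate collection days:
  $\hat\sigma^2_w = \tfrac1n\sum d_i^2/2$,
  $\hat\sigma^2_b = \mathrm{Var}(\bar x_i) - \hat\sigma^2_w/2$ (floored at 0),
  within-person CV $= 100\sqrt{\hat\sigma^2_w}/\bar x$, and the
  within:between ratio $\hat\sigma^2_w/\hat\sigma^2_b$.

The four prediction equations are three functional forms — a sex-specific
linear combination of spot concentrations, BMI and age (INTERSALT); power laws
$c\,(\mathrm{Na}/\mathrm{Cr}\cdot \widehat{\mathrm{Cr}}_{24})^{\gamma}$ with
anthropometric expected creatinine (Tanaka: $c=21.98,\gamma=0.392$; Kawasaki:
$c=16.3,\gamma=0.5$); and ratio scaling of spot Na per gram creatinine by
expected creatinine (Mage). All coefficients live in a versioned YAML config
(`src/spotna24/data/coefficients.yaml`), never in code. Kawasaki is applied
to morning specimens only by default (its source specimen was a second
morning void); pass `window_policy="relaxed"` to override.

## Worked example

```python
from spotna24 import load_coefficients, predict
from spotna24.types import ParticipantProfile, SpotMeasurement

lib = load_coefficients()
profile = ParticipantProfile(id="A", sex="male", race="white",
                             age=60, height=170, weight=80, bmi=27.68)
spot = SpotMeasurement(sodium_conc=100.0,      # mmol/L
                       creatinine_conc=100.0,  # mg/dL
                       potassium_conc=55.0,    # mmol/L
                       window="morning")
for eq in ("intersalt", "tanaka", "kawasaki", "mage"):
    rec = predict(spot, profile, eq, lib)
    print(f"{eq:9s} {rec.predicted_na:8.1f} mg/day  [{rec.quality_flag}]")
```

prints

```
intersalt   3889.0 mg/day  [ok]
tanaka      3667.3 mg/day  [ok]
kawasaki    4783.8 mg/day  [ok]
mage        3313.1 mg/day  [ok]
```

The same specimen yields four estimates spanning ~1,500 mg/day — the spread
between equations is exactly what the validation layer quantifies. Kawasaki
runs highest here, consistent with its strong positive group bias; a
non-positive result would come back flagged `nonphysical` with no number, and
a missing potassium value fails INTERSALT rather than imputing zero.

## The analysis pipeline

Numbered drivers under `analysis/` run the full study-shaped analysis on the
synthetic cohort and write tables under `results/`:

```bash
python analysis/01_simulate.py   # 554-participant cohort, ~9 voids/day
python analysis/02_process.py    # timed windows + completeness QC
python analysis/03_predict.py    # 4 equations x 4 windows
python analysis/04_validate.py   # bias/agreement/variance grids
python analysis/05_report.py     # Bland-Altman + forest figures
```

The same stages are exposed as a CLI (`spotna24 simulate|process|predict|
validate|report`), each dropping a `manifest.json` with seed, config hash and
stage counts.

## Layout

```
src/spotna24/        equations, processing, stats, cohort, pipeline, io, cli
src/spotna24/data/   coefficient config (YAML)
analysis/            numbered narrative drivers
scripts/             acceptance.py
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      model/assumption notes
```
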