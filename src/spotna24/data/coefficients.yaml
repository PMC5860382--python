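# Canonical coefficient sets for the four published spot-urine equations that
# estimate 24-hour urinary sodium excretion, plus the anthropometric
# expected-creatinine equations they lean on.
#
# Unit dialects declare the units each equation expects per analyte; spot
# concentrations always arrive as sodium/potassium in mmol/L and creatinine in
# mg/dL, and the loader-side converters translate into the dialect before the
# functional form is evaluated. All equation outputs are mmol/day, converted to
# mg/day with the sodium molar factor below.

sodium_mg_per_mmol: 23.0
creatinine_mg_per_mmol: 113.12

equations:
  intersalt:
    form: linear
    windows: [overnight, morning, afternoon, evening]
    unit_dialect:
      sodium: mmol_per_l
      potassium: mmol_per_l
      creatinine: mmol_per_l
    strata_by: [sex]
    terms:
      male:
        intercept: 25.46
        na: 0.46
        cr: -2.75
        k: -0.13
        bmi: 4.10
        age: 0.26
        age_sq: 0.0
      female:
        intercept: 5.07
        na: 0.34
        cr: -2.16
        k: -0.09
        bmi: 2.39
        age: 2.35
        age_sq: -0.03

  tanaka:
    form: power_law
    windows: [overnight, morning, afternoon, evening]
    scale: 21.98
    exponent: 0.392
    unit_dialect:
      sodium: mmol_per_l
      creatinine: mg_per_l
    predicted_creatinine:
      form: linear
      strata_by: []
      terms:
        all:
          intercept: -2244.45
          age: -2.04
          weight: 14.89
          height: 16.14

  kawasaki:
    form: power_law
    windows: [morning]          # developed for a second-morning-void specimen
    scale: 16.3
    exponent: 0.5
    unit_dialect:
      sodium: mmol_per_l
      creatinine: mg_per_l
    predicted_creatinine:
      form: linear
      strata_by: [sex]
      terms:
        male:
          intercept: -79.90
          age: -12.63
          weight: 15.12
          height: 7.39
        female:
          intercept: -74.95
          age: -4.72
          weight: 8.58
          height: 5.09

  mage:
    form: ratio_scaling
    windows: [overnight, morning, afternoon, evening]
    unit_dialect:
      sodium: mmol_per_l
      creatinine: g_per_l
    predicted_creatinine:
      # CER (mg/day) = k * (140 - age) * weight^1.5 * height^0.5 / 1000
      form: mage_power
      strata_by: [sex, race]
      terms:
        male|white: {k: 1.93}
        male|african_american: {k: 2.04}
        female|white: {k: 1.64}
        female|african_american: {k: 1.74}
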