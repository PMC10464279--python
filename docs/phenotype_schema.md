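# Phenotype CSV schema

One row per subject; `subject_id` (unique, required) plus either the
**raw-field** or the **precomputed** layout.  Bedtime/SOT columns may be
`hh:mm` strings (hours may exceed 23; an hour below 12 is read as
post-midnight and mapped forward by 24) or decimal hours on the
continuous [12, 36) clock.  SOL columns are minutes.

## Raw-field layout

| column               | meaning                                   |
|----------------------|-------------------------------------------|
| `bedtime_weekday_sr` | self-reported weekday bedtime             |
| `bedtime_weekend_sr` | self-reported weekend bedtime             |
| `sol_sr`             | self-reported sleep-onset latency (min)   |
| `bedtime_act`        | actigraphy mean bedtime                   |
| `sol_act`            | actigraphy sleep-onset latency (min)      |
| `bedtime_psg`        | polysomnography "lights-out" time         |
| `sol_psg`            | polysomnography sleep-onset latency (min) |

Derived on load: `bedtime_sr` = (5·weekday + 2·weekend)/7, and
`sot_<m>` = `bedtime_<m>` + `sol_<m>`/60 for each method.

## Precomputed layout

All nine measure columns: `bedtime_sr`, `bedtime_act`, `bedtime_psg`,
`sol_sr`, `sol_act`, `sol_psg`, `sot_sr`, `sot_act`, `sot_psg`.
The identity `sot = bedtime + sol/60` is re-checked to within one
minute; a violation is an error.

## Covariates (either layout)

| column      | meaning                                    |
|-------------|---------------------------------------------|
| `age`       | years                                       |
| `male`      | 1 = male, 0 = otherwise                     |
| `minority`  | 1 = racial/ethnic minority, 0 = otherwise   |
| `bmi_pct`   | BMI percentile, 0–100                       |
| `batch`     | sequencing batch label (categorical)        |

Missing covariates are allowed; the loader adds a boolean
`covariates_complete` column and per-site fits drop incomplete rows
complete-case.  SOL values outside [0, 600) minutes trigger a warning.
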