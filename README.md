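# msofa

Modified SOFA (mSOFA) severity scoring for intensive-care cohorts, with a
full mortality-discrimination analysis pipeline and a synthetic cohort
generator.

## The problem

The Sequential Organ Failure Assessment (SOFA) score grades six organ
systems — respiratory, coagulation, liver, cardiovascular, central nervous
system, renal — each 0 (normal) to 4 (worst), for a total of 0–24. Its
respiratory component needs the PaO2/FiO2 ratio, and PaO2 requires arterial
blood-gas analysis, which is rarely available in resource-limited ICUs. The
**modified SOFA (mSOFA)** replaces PaO2/FiO2 with the pulse-oximetry
surrogate **SpO2/FiO2** (SpO2 in percent, FiO2 as a fraction, so SpO2 90%
on 100% oxygen gives a ratio of 90), banded as

| points | 0 | 1 | 2 | 3 | 4 |
|---|---|---|---|---|---|
| SpO2/FiO2 | >301 | 221–301 | 142–220 | 67–141 | <67 |
| PaO2/FiO2 | >400 | 300–400 | 200–300 | 100–200 | <100 |

with the other five organ criteria unchanged. This package is for
clinical-research engineers and biostatisticians who need a tested,
reproducible implementation of:

* the six organ subscores and the 0–24 total, in both SpO2 and PaO2
  respiratory modes (`msofa.scoring`);
* a cohort pipeline that reads long-format observations, applies the
  eligibility rules (adults >12 years, ICU stay >24 h, known outcome, not
  low-risk monitoring), takes the **worst value of each parameter** in the
  admission window T0 = [0, 24) h and the 48-hour window T48 = [24, 48] h,
  imputes isolated single gaps by the mean of the adjacent values, and
  derives the score family — initial (T0), 48-h (T48), mean = (T0+T48)/2,
  highest = max(T0, T48), delta = T48 − T0, total-sum = T0 + T48
  (`msofa.pipeline`);
* discrimination statistics: survivor/non-survivor comparisons (Welch or
  pooled t, Mann–Whitney, Pearson chi-square), the empirical AUROC via the
  Mann–Whitney concordance (ties count ½), DeLong placement-value
  confidence intervals and the paired DeLong test for comparing two score
  variants on the same patients, 2×2 odds ratios with Woolf intervals, and
  multivariable logistic regression for ICU mortality (`msofa.stats`,
  `msofa.report`);
* a seeded synthetic ICU cohort generator, since no patient-level data are
  publicly available for the motivating cohort: a latent severity variable
  drives all organ physiology through monotone links, mortality follows a
  logistic model calibrated by root-finding to a target death rate
  (default 46.6%), PaO2 is 90% missing by default, and eligibility decoys
  are injected for filter testing (`msofa.simulate`).

## Worked example

```bash
msofa run-all --n-patients 118 --seed 42 --out demo
```

simulates a cohort (170 patients generated: 118 eligible plus 42 low-risk,
9 early-death and 1 outcome-unknown decoys), scores it, and analyzes it.
`demo/scores/eligibility.csv` records the enrolment flow (`analyzed 118`),
and `demo/scores/scores.csv` holds one row per patient:

```
patient_id  t0_total  t48_total  mean_score  highest  delta
     P0001         6          5         5.5        6     -1
     P0002         2          2         2.0        2      0
     P0003         9         10         9.5       10      1
```

This run's cohort has ICU mortality 0.475, admission total mSOFA mean 5.9
(SD 3.4), and mean delta −1.2 in survivors vs +1.2 in non-survivors —
survivors improve by 48 h, non-survivors deteriorate.
`demo/analysis/auc.csv` gives the mortality discrimination of each score
variant with 95% DeLong confidence intervals:

```
variant      auc   ci_low  ci_high ci_method      comparison  comparison_p
initial 0.549683 0.444893 0.654473    delong
    48h 0.734735 0.644218 0.825253    delong
   mean 0.653082 0.554066 0.752098    delong mean_vs_initial      0.000001
highest 0.641129 0.541377 0.740881    delong
  delta 0.748848 0.661346 0.836350    delong
```

At n = 118 the single-seed AUCs are noisy; the stable ordering (48-h and
trajectory-aware variants discriminate better than the admission score) is
a property of the generator's outcome-conditional severity drift.
`comparison_p` is the paired DeLong p-value for mean vs initial. The
library surface gives the same numbers directly:

```python
from msofa import OxygenDelivery, OxygenDevice, estimate_fio2, \
    oxygenation_ratio, respiratory_subscore

fio2 = estimate_fio2(OxygenDelivery(OxygenDevice.NASAL_CANNULA, flow=2))  # 0.27
respiratory_subscore(oxygenation_ratio(90, None, 1.0, "spo2"), "spo2")    # 3
respiratory_subscore(oxygenation_ratio(None, 60, 1.0, "pao2"), "pao2")    # 4
```

The last two lines are the classic limitation of the SpO2 surrogate: the
same hypoxemic patient scores 3 by SpO2/FiO2 but 4 by PaO2/FiO2.

## Input schema

`msofa score` consumes two CSVs: `observations.csv` (long format —
`patient_id, timestamp_h, spo2, pao2, oxygen_device, oxygen_flow, fio2,
map, gcs, platelets, bilirubin, creatinine, urine_output, dopamine,
dobutamine, norepinephrine`) and `patients.csv` (`patient_id, age, sex,
admission_source, admission_type, mechanically_ventilated,
vasopressor_used, low_risk_monitoring, icu_los_days, outcome`). Units and
validity ranges are documented in `msofa/pipeline.py` and enforced by the
reader; violations are reported with line numbers.

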