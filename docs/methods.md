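# Methods

## The score

mSOFA grades six organ systems on integer scales 0–4 and sums them (0–24).
Five criteria are the standard SOFA bands: platelets (10³/mm³), total
bilirubin (mg/dL), cardiovascular status (MAP and vasopressor category),
Glasgow Coma Scale, and renal function (creatinine mg/dL or urine output
mL/day, combined by maximum — the worst applies). The respiratory
criterion is evaluated in one of two modes: the original PaO2/FiO2 ratio
(mmHg over fraction) or the pulse-oximetry surrogate SpO2/FiO2 (percent
over fraction). The SpO2 mode is the package default, since it is the
modification that makes the score computable where blood-gas analysis is
unavailable; the PaO2 mode is retained for comparison.

FiO2 is taken as 0.21 on room air, read directly from the device setting
on face masks and ventilators, and estimated on nasal cannulae as
0.21 + 0.03 × flow (L/min). The estimate is clipped to the physical range
[0.21, 1.0]; the published rule is unbounded, so the cap is this package's
choice.

### Boundary conventions

Published band edges are ambiguous at exact boundary values (e.g.
"142–220" vs "221–301" leaves 220.5 unassigned; ">150" vs "<150" leaves
exactly 150 unassigned). The tables in `msofa/scoring.py`
(`SUBSCORE_BANDS`, `VASOPRESSOR_CATEGORIES`) are the single source of
truth and resolve every edge deterministically:

* SpO2/FiO2: >301 → 0; [221, 301] → 1; [142, 221) → 2; [67, 142) → 3; <67 → 4
* PaO2/FiO2: >400 → 0; [300, 400] → 1; [200, 300) → 2; [100, 200) → 3; <100 → 4
* platelets: >150 → 0; (100, 150] → 1 and downward analogously with ≥ at
  100/50/20 (exactly 150 scores 1, matching the strict ">150" of the
  printed top band)
* bilirubin and creatinine: left-closed ([1.2, 2.0) → 1, etc.); exactly
  12.0 bilirubin and 5.0 creatinine fall in the worst band
* urine output: <200 → 4; [200, 500) → 3; otherwise contributes 0; absent
  urine output contributes nothing
* GCS: 15 → 0; 13–14 → 1; 10–12 → 2; 6–9 → 3; 3–5 → 4
* cardiovascular: without vasopressors MAP ≥ 70 → 0, MAP < 70 → 1;
  dopamine ≤ 5 µg/kg/min or any dobutamine → 2; dopamine (5, 15] or
  norepinephrine ≤ 0.1 → 3; dopamine > 15 or norepinephrine > 0.1 → 4.
  Dobutamine alone never scores above 2. Multiple simultaneous agents are
  scored per drug and combined by maximum, consistent with the
  worst-value philosophy. Epinephrine and other vasoactives are outside
  the score and rejected as invalid input.

SpO2 readings of 100% are scored as-is; no saturation-ceiling correction
is applied. Property tests enumerate the band tables to verify that every
admissible input falls in exactly one band and that each subscore is
monotone in its analyte.

## Cohort pipeline

Eligibility mirrors the intended study population: adults (>12 years)
staying in the ICU more than 24 h with a known outcome, excluding
low-risk-monitoring admissions (an explicit flag in the input — it cannot
be derived from physiology). Each excluded patient carries exactly one
primary reason, resolved in the order age, low-risk flag, early
death/discharge, unknown outcome, and the eligibility report tallies them
so that analyzed = enrolled − excluded always holds.

Scoring windows are T0 = [0, 24) h and T48 = [24, 48] h from ICU
admission, half-open at the seam so the 24-h observation belongs to the
second window and an observation at exactly 48 h still counts. The
published procedure states only "on admission" and "at 48 h" while using
worst-in-24-h values; this is the minimal consistent reading. Within each
window the worst value per parameter is selected: minimum for the
oxygenation ratio, platelets, MAP, GCS and urine output; maximum for
bilirubin, creatinine and vasopressor doses. The respiratory component
uses the minimum per-observation ratio (rather than pairing the worst SpO2
with a non-concurrent FiO2), because a ratio is only meaningful within one
observation.

Single missing values are imputed as the arithmetic mean of the
immediately preceding and following measurements of the same parameter;
leading/trailing gaps and runs of two or more stay missing. Imputation is
applied per parameter across the patient's whole time-ordered series
before window selection. An organ left unscorable after imputation scores
0 and sets a per-patient completeness flag (the common convention when an
organ is presumed normal because it was not measured); `--strict-missing`
excludes such patients instead. Either way the handling is visible in the
output. A window with no observations at all makes the patient unscorable,
with the reason logged and reported.

The derived family is computed from the two totals, so its identities
(delta = T48 − T0, total-sum = 2 × mean, highest = max) hold by
construction; delta is oriented T48 − T0 so that improving survivors have
negative mean delta.

## Statistics

* Continuous group comparisons default to the unequal-variance (Welch)
  t-test — group standard deviations in severity data typically differ —
  with the pooled form behind a flag; `method="auto"` switches to
  Mann–Whitney when a Shapiro–Wilk pre-check rejects normality at
  α = 0.05 in either group (the check and its result are recorded in the
  comparison's note). Categorical comparisons use the Pearson chi-square
  without continuity correction, dropping empty columns with a warning.
* The empirical AUROC (deaths positive) is computed through the
  Mann–Whitney identity with midranks, so ties contribute ½. Its variance
  uses the DeLong structural-components estimator: with placement values
  V10_i (fraction of controls below case i, ties ½) and V01_j (fraction of
  cases above control j), var(AUC) = S10/m + S01/n, where S are sample
  variances and m, n the class sizes. The 95% CI is the normal
  approximation clipped to [0, 1]. A stratified bootstrap (2000 replicates,
  seeded) is available as an alternative CI method. The paired DeLong test
  for two score variants on the same patients uses the paired covariance
  of the placement values and a two-sided normal p-value; identical scores
  give p = 1. The implementation was verified against an independent
  reference implementation to 8 decimal places on a frozen fixture
  (`tests/test_stats.py`).
* Univariate 2×2 odds ratios are ad/bc with Woolf log-scale intervals and
  the Haldane–Anscombe 0.5 correction (flagged) when a cell is zero.
* The multivariable logistic model is fit by maximum likelihood
  (statsmodels Newton/IRLS) with Wald 95% intervals exponentiated to the
  odds-ratio scale. Constant or perfectly collinear covariates are
  rejected up front with offenders named. Perfect or quasi-separation
  (detected via the fitter's diagnostics or a |coefficient| > 15 guard) is
  flagged and suppresses the Wald intervals rather than reporting
  meaningless ones. The published analysis never lists its adjusted
  covariate set, so the default — score variant, age, sex, mechanical
  ventilation, vasopressor use — is a package choice and fully
  configurable; outputs are labeled with the covariates used.
* No multiple-testing correction is applied, matching standard practice
  for this kind of descriptive severity-score validation; the analysis
  tables simply enumerate every test performed.

## Synthetic cohort generator

Patient-level data for the motivating cohort were never released, so the
package ships a minimal latent-variable generator whose purpose is to make
every pipeline stage testable, not to simulate ICU physiology. Baseline
severity z0 ~ N(0, 1) drives all organ values through clipped
linear/log-linear monotone links (the exact link table is in the
`msofa/simulate.py` module docstring); mortality is Bernoulli with
logit P(death) = α + β·z0, where β (`severity_effect`, default 0.9) is the
single knob controlling score–mortality association and α is solved by
Brent root-finding so the cohort's expected mortality equals
`target_mortality` (default 0.466). Severity at 48 h is
z48 = z0 + drift + N(0, 0.5) with outcome-conditional drift (−0.60
survivors, +0.25 non-survivors), which produces falling scores in
survivors, rising scores in non-survivors, and better discrimination for
the 48-h and trajectory-aware score variants — the qualitative pattern the
analysis layer is designed to detect. Setting `severity_effect = 0` and
the drifts to 0 yields an exact null (AUC 0.5).

Default link coefficients were calibrated once against the published
cohort moments (mortality 46.6%, admission total mean ≈ 6.5, SD ≈ 3.7,
per-organ admission means, survivor/non-survivor deltas ≈ −1.7/+1.0) and
then frozen; at n = 3000 the generator reproduces admission organ means
within ≈0.2 points and total 6.5 ± 0.1 (SD 4.4 vs the published 3.7 — the
shared latent factor induces more inter-organ correlation than real
cohorts show). This approximate match is a smoke check, not an acceptance
gate.

Each eligible patient gets six observations (0, 8, 16 h and 28, 38, 48 h),
with small per-observation latent noise. PaO2 is blanked with probability
0.9 by default (emulating near-total blood-gas absence; SpO2, MAP, GCS
3% and urine output 10%, to exercise the imputation path). Decoy patients
are generated on top of `n_patients`: 36% low-risk-monitoring admissions,
8% deaths within 24 h (whose T48 observations are removed), and one
outcome-unknown patient in cohorts of ≥50 — proportions chosen to emulate
a realistic enrolment flow. Ground truth (z0, z48, true death probability,
decoy label) is written to a separate file the pipeline never reads, so
recovery tests (e.g. logistic regression of outcome on z0 recovering β
within 10% at n = 10⁴) can close the loop.

What the generator does **not** emulate: organ-system coupling beyond the
single latent factor, treatment effects, time-varying measurement
schedules, informative missingness, or length-of-stay distributions beyond
what the eligibility filter needs. Passing tests therefore demonstrate
correctness of the scoring and inference machinery under a known
generative model, not clinical validity on real cohorts.

## Numerical and reproducibility choices

* All randomness flows from numpy `default_rng` seeds carried in the
  configuration; identical (config, seed) reproduce every output byte, and
  the CLI echoes its configuration into each output directory.
* Problem sizes in the test suite (e.g. 1000-replicate coverage and
  type-I-error simulations at n = 118, 500 random cohorts for the AUROC
  oracle, n = 10⁴ for parameter recovery) were chosen so the full suite
  runs in well under a minute per file while keeping binomial Monte-Carlo
  error tight (3σ bands).
* The bundled fixture cohort (n = 24 eligible, seed 24001) is committed as
  plain CSV and regenerated byte-identically by a test; analysis outputs
  on it are pinned by golden files as a regression surface.
* Degenerate inputs fail loudly: single-class cohorts, empty groups,
  all-zero contingency tables, DeLong with fewer than two members per
  class (the error recommends the bootstrap), infeasible mortality targets
  (0 or 1), and schema violations (with line numbers) all raise.

## Known limitations

* The boundary conventions above are deterministic choices, not published
  facts; scores at exact band edges may differ from other implementations.
* The missing-organ-scores-0 default biases totals downward for patients
  with unmeasured organs; strict mode trades that bias for cohort
  shrinkage. Completeness flags make the choice auditable.
* DeLong intervals are asymptotic; at very small n or AUC near 1 the
  bootstrap alternative is preferable.
* The generator's single latent factor overstates inter-organ correlation
  (total-score SD runs ~0.7 points above the published cohort's).
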