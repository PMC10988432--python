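# myoquant — deep muscle phenotyping in end-stage liver disease

Sarcopenia assessment in hepatology has traditionally meant one number:
the L3 skeletal muscle index from a single abdominal CT/MRI slice. Yet
muscle loss in end-stage liver disease (ESLD) is not uniform — the
quadriceps, which carry the functional tasks that keep patients
independent, lose mass and quality faster than the trunk muscles that
L3 SMI samples. Quantifying that requires a panel of derived measures
spanning MRI morphometry, muscle architecture, strength testing and
habitual activity.

`myoquant` implements that panel as a reusable, fully tested pipeline:

- **Anthropometry** — mid-arm muscle circumference
  (MAMC = MAC − π·TSF/10), ascites/oedema-graded dry weight, BMI.
- **MRI morphometry** — muscle volume from sparse serial cross-sections
  by truncated-cone (frustum) integration,
  MV = Σ (t/3)·(Aₙ + √(Aₙ·Aₙ₊₁) + Aₙ₊₁); quadriceps volume index
  (MV/height²); L3 SMI; mid-thigh ACSA; two-point Dixon myosteatosis
  IMAT% = 100·SI_fat/(SI_fat+SI_water); VL PCSA = V/L_f and
  PCSA_eff = PCSA·cos θ.
- **Strength & function** — peak-of-trials reduction, five-repetition
  chair-stand time, and specific force
  τ/(ACSA·(1 − IMAT%/100)) — torque per unit *contractile* area.
- **Accelerometry** — wear-time validity rules (≥16 h days, ≥3 valid
  days, 24-h quarter-hour coverage, ≤0.01 g calibration error), average
  acceleration, and daily MVPA minutes (> 100 mg).
- **Statistics** — normality-gated Student's t / exact Mann–Whitney
  comparisons, Cohen's d = |m₁−m₂|/((s₁+s₂)/2), gated
  Pearson/Spearman correlations, percent differences.

Because studies of this kind publish only group summaries, the package
includes a **synthetic cohort generator** (`myoquant.synth`) whose
defaults encode the published two-arm summaries (n = 39 ESLD vs n = 18
HC) with a latent "muscle size" factor inducing the reported
mass–strength correlations. Every derived measure can therefore be
verified end to end against planted ground truth. See
[docs/methods.md](docs/methods.md) for the model and its limits.

## Worked example

```python
import myoquant as mq

cfg = mq.default_config()                      # the study conditions
cohort = mq.generate_cohort(cfg, seed=1)       # 39 ESLD + 18 HC subjects
panel = mq.derive_measures(cohort, cfg)        # per-subject derived panel
report = mq.group_report(panel)                # gated two-arm comparison

cols = ["esld_centre", "hc_centre", "test_used", "p_value", "cohens_d", "percent_diff"]
print(report.loc[["imat_pct", "pennation", "avg_acceleration"], cols].round(3))
```

prints

```
                  esld_centre  hc_centre  test_used    p_value  cohens_d  percent_diff
variable
imat_pct               10.703      4.833  student_t  1.129e-08     2.259       121.458
pennation              12.517     15.978  student_t  5.156e-05     1.168       -21.661
avg_acceleration       17.842     28.492  student_t  1.056e-05     1.330       -37.378
```

i.e. in this simulated cohort the patients carry roughly double the
quadriceps fat infiltration (IMAT 10.7 % vs 4.8 %, a very large effect,
d ≈ 2.3), a shallower VL pennation angle, and markedly lower habitual
activity — the qualitative signature the panel is designed to expose,
while conventional mass measures (MAMC, L3 SMI) show no significant
difference.

The same analysis as a script sequence:

```bash
python analysis/01_simulate_cohort.py --seed 1     # scratch/cohort/
python analysis/02_derive_measures.py              # results/derived_measures.csv
python analysis/03_group_comparison.py             # results/comparisons.csv, report.md
python analysis/04_printed_effect_sizes.py         # results/printed_effect_sizes.csv
```

## Layout

```
src/myoquant/      library (generator, IO, derived measures, statistics)
analysis/          numbered narrative drivers over the library
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance recomputation
docs/methods.md    model, assumptions, numerical choices, limitations
```
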