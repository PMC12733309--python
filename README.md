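# limbrisk

Biomarker-based risk analysis for **lower-limb complications in type 2
diabetes** — peripheral arterial disease (PAD) and diabetic peripheral
neuropathy (DPN).

Routine labs are cheap; hyperinsulinemic clamps and nerve-conduction studies
are not. `limbrisk` implements, as a tested and reusable pipeline, the
analysis workflow used in clinical studies that relate surrogate
insulin-resistance indices and composite inflammation indices to lower-limb
complications: compute the index panel from fasting labs and a blood count,
derive the outcome labels from bedside measurements, compare groups,
run ROC/Youden cut-off analysis, and apply a five-item composite risk score.
It is intended for biostatisticians and clinical researchers who want the
whole chain — from raw CSV to clinical-style report tables — reproducible
and unit-tested, including on synthetic cohorts when patient-level data
cannot be shared.

## What it computes

**Insulin-resistance surrogates** (Ln = natural logarithm; TG, FPG, TC,
HDL-c in mg/dL):

- TyG = Ln(TG · FPG / 2), plus TyG−BMI, TyG−WC, TyG−WHtR (TyG times the
  anthropometric measure)
- CHG = Ln(TC · FPG / (2 · HDL-c)), plus CHG−BMI, CHG−WC, CHG−WHtR
- TG/HDL-c
- METS-IR = Ln(2·FPG + TG) · BMI / Ln(HDL-c)

**Inflammation indices** (counts in 10³ cells/µL):

- NLR = neutrophils / lymphocytes, MLR = monocytes / lymphocytes
- SII = platelets · NLR
- CAR = CRP (mg/L) / albumin (g/L)
- NPAR = neutrophil percentage (%) · 100 / albumin (g/dL)

**Outcome labels**: PAD positive iff ankle–brachial index ≤ 0.90; DPN
positive iff the Toronto clinical score (symptoms + failed sensory tests +
reflex grading) exceeds 6 points.

**Statistics**: Kolmogorov–Smirnov normality routing (mean ± SD + Student's
t for Gaussian pairs, median (IQR) + Mann–Whitney U otherwise; exact
permutation U-test for small samples), Pearson chi-square without continuity
correction for 2×2 tables, nonparametric AUROC (tie-adjusted Mann–Whitney
probability) with Hanley–McNeil SE / 95% CI / p, and Youden-index optimal
cut-offs over midpoint candidate thresholds.

**Composite score**: 1 point per item at or above threshold — DM duration
≥ 4.50 y, TyG−WHtR ≥ 5.78, SII ≥ 334.27, MLR ≥ 80.50, CAR ≥ 0.20 — with
high-risk classification above 2.5 points, evaluated by ROC against both
outcomes. (The MLR and CAR thresholds are kept as published even though they
are unreachable on those indices' natural scales; see
[docs/methods.md](docs/methods.md) for the scale discussion and overrides.)

## Worked example

```python
from limbrisk import (SubjectRecord, compute_full_panel,
                      classify_pad_from_abi, apply_composite_score)

rec = SubjectRecord(
    subject_id="S0001", gender="male", age=64, dm_duration=15,
    weight=81.0, height=1.80, wc=104.0,
    fpg=230.0, hba1c=8.9, tc=176.0, hdl_c=42.0, ldl_c=87.8, tg=171.0,
    neutrophils=4.0, lymphocytes=2.0, monocytes=0.44, platelets=258.0,
    neutrophil_pct=55.0, albumin_g_dl=4.3, crp=0.60, abi=0.82,
)
panel = compute_full_panel(rec)
print(round(panel.tyg, 4), round(panel.tyg_whtr, 4), round(panel.sii, 1))
print(classify_pad_from_abi(rec.abi))
score = apply_composite_score({
    "dm_duration": rec.dm_duration, "tyg_whtr": panel.tyg_whtr,
    "sii": panel.sii, "mlr": panel.mlr, "car": panel.car})
print(score.item_flags, score.total, score.classification)
```

prints

```
9.8866 5.7123 516.0
positive
(1, 0, 1, 0, 0) 2 low-risk
```

TyG is Ln(171·230/2) = 9.8866; multiplied by the waist-to-height ratio
104/180 it gives 5.71, just under the 5.78 score threshold, so only the
duration and SII items fire: 2 of 5 points, below the 2.5 high-risk cut-off.
The ABI of 0.82 classifies the subject PAD-positive.

The same pipeline runs end to end from the shell:

```bash
limbrisk generate --n 110 --seed 7 --out cohort.csv
limbrisk analyze  --input cohort.csv --outdir results/
limbrisk score    --input cohort.csv --out scores.csv
# or in one step, on a synthetic cohort:
limbrisk analyze --synthetic-n 110 --seed 7 --outdir results/
```

`results/report.txt` holds the aligned comparison, ROC and score-evaluation
tables; every table is also written as full-precision CSV, and
`run_log.txt` records the seed, configuration hash and routing decisions so
a run can be reproduced byte-for-byte.

## Synthetic cohorts

Because patient-level data for this kind of study are typically not
deposited, `limbrisk.synthetic` generates cohorts with the published
statistical structure: n = 110 with 28/82 PAD−/PAD+ and 18/92 DPN−/DPN+
splits, right-skewed labs modelled lognormal from median/IQR targets,
outcome labels drawn from a latent-risk construction so that diabetes
duration separates both outcomes strongly, and ABI/Toronto fields generated
consistently with the assigned labels. Derived indices are never sampled —
they are always recomputed from the raw fields.

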