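# Methods

## Scope and data model

`limbrisk` analyses one cross-sectional cohort of adults with type 2
diabetes evaluated for lower-limb complications. A subject record carries
demographics (gender, age, diabetes duration in years), anthropometrics
(weight kg, height m, waist circumference cm), fasting labs (FPG, TC, HDL-c,
LDL-c, TG in mg/dL; HbA1c %), a blood count (neutrophils, lymphocytes,
monocytes, platelets in 10³ cells/µL; neutrophil percentage), inflammation
assays (CRP mg/L, albumin g/dL, ESR mm/hr, fibrinogen mg/dL, ferritin ng/mL,
TNFα, IL-6, FGF1, MMP1 pg/mL) and two bedside evaluations (ankle–brachial
index; Toronto score components). Height is stored once, in meters (a read
option converts cm), so BMI and the waist-to-height ratio always share the
same measurement. Missing values propagate as missing: a subject is dropped
per-analysis, never imputed, mirroring how incomplete participants are
excluded at enrollment. Albumin is stored in g/dL (the unit NPAR uses) and
converted to g/L explicitly inside CAR, so the two indices cannot silently
mix units.

## Outcome definitions

PAD is positive when ABI ≤ 0.90, inclusive at the boundary. No separate
high-ABI (incompressible-artery) category is modelled. DPN is positive when
the Toronto score exceeds 6 points, strictly: 1 point per symptom present,
1 per failed sensory test (10 g monofilament, TipTherm, pin-prick, tuning
fork, proprioception), and reflex points graded 0/1/2
(normal/diminished/abolished). By default the patellar and Achilles reflexes
are graded separately and summed (maximum 4 reflex points), which is the
only additive reading of per-reflex 0/1/2 grading; a `n_reflexes=1` switch
encodes a single overall reflex grade instead. Which encoding the original
bedside protocol used is not derivable from the published description, so
both are supported and the per-reflex default is an interpretation, not a
claim.

## Biomarker panel

The 17 indices and their formulas are listed in the README. Numerical
choices: natural logarithm wherever "Ln" appears; no rounding inside the
panel (reports round at display time — 2 decimals for summaries, 3 for
AUROC/p); SII stays on the 10³ cells/µL scale of its inputs (values ~300–500
in this population). METS-IR requires HDL-c > 1 mg/dL since Ln(HDL-c) is its
denominator; TyG and CHG require strictly positive lipid/glucose inputs. A
present-but-invalid input raises a domain error naming the field; a missing
input silently leaves only its dependent indices missing.

### A note on the published CAR and MLR scales

With CAR defined as CRP (mg/L) / albumin (g/L), cohorts with CRP medians
near 0.5 mg/L and normal albumin (~43 g/L) produce CAR values near 0.013.
Published CAR medians in this setting (0.08–0.16) are 10-fold higher —
consistent with albumin entered in g/dL, not g/L. Similarly, the published
composite-score threshold for MLR (80.50) is unreachable on the
monocyte-to-lymphocyte count-ratio scale, where values cluster near 0.2.
`limbrisk` implements the definitions as printed and keeps the printed
thresholds as defaults for fidelity; consequently the MLR and CAR score
items contribute 0 points for every realistic subject, which a regression
test documents. The score accepts per-item overrides (e.g. `mlr_threshold=
0.805`) for users who adopt the plausible rescaled readings; neither reading
is asserted as the original intent.

## Statistical workflow

Continuous variables are routed by a one-sample Kolmogorov–Smirnov test
against a normal law with the sample's estimated mean and SD (the classical
variant; Lilliefors correction available via `normality_method=
"lilliefors"` — which variant the original SPSS workflow used is unstated,
so both are exposed). Gaussian in both groups (KS p ≥ 0.05 each) → mean ± SD
summaries and a two-sided pooled-variance Student's t test; otherwise →
median (IQR width Q3 − Q1) and a two-sided Mann–Whitney U test. The U-test
p-value is an exact full enumeration of the permutation distribution (valid
with ties, via midranks) when the combined sample size is ≤ 12, and the
tie-corrected normal approximation above that. Quartiles default to linear
interpolation between order statistics, with the (n+1)-based
weighted-average convention as an option; again the original convention is
unstated. Categorical 2×2 tables use Pearson chi-square, df = 1, without
continuity correction — this is the variant that reproduces the published
gender-by-PAD p of 0.231 (Yates correction gives ≈ 0.33). No
multiple-testing correction is applied, matching the exploratory design.

## ROC and Youden analysis

AUROC is the tie-adjusted Mann–Whitney probability (computed through
midranks, equivalent to pairwise counting with half credit for ties).
Candidate thresholds are midpoints between consecutive distinct scores plus
sentinels half a unit beyond the extremes, with positivity as score ≥
threshold — for integer-valued scores (diabetes duration in whole years,
the 0–5 composite total) this produces the half-integer cut-offs familiar
from clinical tables. Every biomarker here is elevated in the affected
group, so "higher is positive" is the default direction, with a per-variable
flag for markers oriented the other way. The Youden cut-off maximizes
J = sensitivity + specificity − 1; ties are broken toward the smallest
threshold, maximizing sensitivity at equal J (no published rule exists). The
scan ranks J in exact integer arithmetic (TP·n₋ + TN·n₊) so floating-point
noise cannot break genuine ties.

Inference uses the Hanley–McNeil exponential approximation,
SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)]/(n₊n₋) with Q₁ = A/(2−A),
Q₂ = 2A²/(1+A); the 95% CI is A ± 1.96·SE truncated to [0, 1] and the
p-value tests A = 0.5 with a two-sided z-test. Exact SE agreement with SPSS
output is not expected (SPSS uses a related but distinct nonparametric
variant); a perfect-separation AUROC of 1.0 yields SE 0 and is flagged
degenerate rather than assigned a p-value of 0 silently.

## Composite score

Five one-point items (DM duration ≥ 4.50, TyG−WHtR ≥ 5.78, SII ≥ 334.27,
MLR ≥ 80.50, CAR ≥ 0.20; thresholds inclusive), total 0–5, high-risk above
2.5 points — i.e. at 3+ points, which operationalizes the printed 2.50
cut-off on an integer score. Evaluation delegates to the ROC machinery on
the integer totals. The definition serializes to JSON so modified item sets
round-trip through the CLI.

## Synthetic cohort generator

The generator exists because individual-level data for this population are
not deposited; it emulates the *published group structure*, not any real
patient. Defaults: n = 110 with exact 82/110 PAD-positive and 92/110
DPN-positive splits. Right-skewed labs are lognormal with parameters solved
in closed form from a target median m and IQR width w (σ = asinh(w/2m)/z₀.₇₅,
µ = ln m); symmetric variables (age, height, albumin, neutrophil
percentage) are normal. Targets describe the complication-positive group;
the negative group is scaled by the published negative/positive median ratio
(multiplicative for lognormal, additive for normal), each variable driven by
the outcome with which it is most associated (glycemic/lipid variables,
IL-6, platelets and age by PAD; TNFα, CRP and monocytes by DPN). Weight is
derived from a lognormal BMI target and normal height so that BMI lands on
its target scale.

Outcome labels use a latent-risk construction: a standard-normal duration
latent z, per-outcome risk w·z + √(1−w²)·ε with independent noise ε, and the
top round(n·prevalence) risks labelled positive. Duration itself is the
monotone lognormal transform of z (µ = 2.42, σ = 0.90, rounded to whole
years, giving positive-group medians near 15 y and negative near 4 y). The
default weights w = 0.80 (PAD) and 0.97 (DPN) reproduce strong and
near-perfect duration separation respectively. ABI is drawn uniformly inside
the label-consistent interval ([0.40, 0.89] positive, [0.95, 1.30]
negative) and Toronto components are drawn to sum to a label-consistent
total (7–15 positive, 0–6 negative), so re-deriving labels from the
generated clinical fields reproduces them exactly. Gender is Bernoulli with
PAD-group-specific male rates (0.512 positive, 0.643 negative). Labs share a
Gaussian copula with correlation 0.3 inside the glycemic/lipid block —
between-biomarker correlations are not published, so this weak-positive
default is an assumption, documented here. All randomness flows from one
NumPy PCG64 stream, so a seed fixes the cohort across platforms.

`null_effects=True` removes every between-group shift and sets both latent
weights to zero, giving cohorts in which labels are independent of all labs
— used to verify that comparison p-values are uniform under the null.

**What the generator does not emulate**: within-subject coherence between
the neutrophil percentage and the absolute counts; medication effects;
age–duration correlation; the real joint distribution beyond the stated
marginals and single-latent label mechanism; any record-level resemblance to
actual patients. Passing tests on synthetic cohorts therefore demonstrate
the *correctness of the computational pipeline* under the published
population structure, not clinical validity of the score on new data.

## Problem sizes used in the test and acceptance runs

Marginal calibration is checked at n = 10 000; null p-value uniformity pools
roughly 270 comparisons from six cohorts of n = 1000; binormal AUROC
recovery uses 5000 subjects per class against the closed-form value
Φ(1/√2) ≈ 0.7602; oracle-equivalence suites use 300–500 random instances
with n ≤ 50 plus exhaustive enumeration for small-sample exact tests. These
sizes make every Monte-Carlo tolerance comfortably larger than its sampling
error while keeping the default suite fast.

## Known limitations

- Cohort-dependent published quantities (per-biomarker AUROCs, sensitivities,
  specificities, the 0.822/0.848 composite-score AUROCs) require the
  original patient-level data and are not reproduction targets; the
  pipeline reports its own values on whatever cohort it is given.
- Multivariable regression and regression-derived item weights are out of
  scope by design (the source analysis deemed them unreliable at this
  sample structure), as are DeLong AUC comparisons, partial AUC, survival
  analysis, and EHR input formats.
- The composite score is applied and evaluated, not internally validated;
  no calibration analysis is provided.
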