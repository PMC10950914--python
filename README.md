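# inflammadx

Explainable two-step classification of inflammatory conditions from 18
routine blood parameters.

## The problem

Patients presenting with inflammatory signs need different treatments
depending on the cause: bacterial infections call for antibiotics, viral
infections do not respond to them, and autoimmune disease or
graft-versus-host disease (GVHD) after allogeneic stem-cell transplantation
may require immunosuppression that is contraindicated in infection. All of
this has to be decided quickly, from tests a routine laboratory can return
within about two hours.

`inflammadx` implements a white-box decision-support pipeline over 18 such
parameters — CRP, eleven hemogram values (WBC, hemoglobin, platelets, and
the percentage and absolute counts of neutrophils, eosinophils, basophils
and monocytes), and the relative MFI of three myeloid activation markers
(CD64, CD169/Siglec-1, HLA-DR) measured by flow cytometry on monocytes and
neutrophils against a lymphocyte negative population. Every prediction is
traceable to human-readable rules and arithmetic threshold tests, so a
physician can audit exactly which parameters drove a call. It is intended
for methods researchers and laboratory data scientists building or
stress-testing interpretable diagnostic classifiers; it is not a medical
device.

## The model

The classifier mirrors the physician's two-step reasoning:

**Step 1 — inflammation or not.** A gain-ratio decision tree (C4.5/C5.0
family) is grown on control-vs-inflammatory labels and converted to
conjunctive rules with training coverage counts. A computed ABC analysis
of the coverage counts — partitioning them along the cumulative-share
(Lorenz-like) curve into the "important few" (A), break-even (B) and
"trivial many" (C) — keeps at most the two most important rules for the
inflammatory superclass. A sample is called inflammatory iff any selected
rule fires; otherwise it falls through to control.

**Step 2 — which inflammation.** The three inflammatory diagnoses are
separated by a *bivariate binary decision tree*: each internal node
thresholds a basic arithmetic combination of at most two features
(`x_i`, `x_i + x_j`, `x_i − x_j`, `x_i · x_j`, or `x_i / x_j`), chosen by
exhaustive search to minimize the case-weighted Simpson impurity
`1 − Σ_k p_k²` of the two children (numerically identical to Gini
impurity). Before training this step, each diagnosis class is extended
fourfold with SMOTE (k = 5 nearest neighbours, synthetic cases interpolated
on parent–neighbour segments).

Model evaluation follows the conventions of the underlying study:
stratified 30-fold cross-validation, per-class report metrics, exact
Clopper-Pearson binomial confidence intervals, and permutation variable
importance via the adjusted Rand index, with the relative difference

```
R = 0.5 · (x − y) / (x + y) · 100      (percent, in [−200, 200])
```

between the baseline agreement `x` (ARI of prior labels vs predictions)
and the agreement `y` after permuting one feature's column 200 times
without refitting.

No patient-level data ship with the package. A synthetic cohort generator
reproduces the published per-class means and 95% confidence intervals of
the 12 CRP/hemogram features (class sizes 30/26/24/38) and adds documented
synthetic effect sizes for the six MFI features; all pipeline guarantees
are demonstrated on these cohorts.

## Worked example

```python
import inflammadx as ix
from inflammadx.metrics import report_markdown

table = ix.generate_cohort(ix.default_config(), seed=1)   # 118 synthetic cases
model = ix.fit_two_step(table, seed=1)
for r in model.step1.rules.rules:
    print(r.describe())

report = ix.cross_validate(table, k=30, seed=1)
print(report_markdown(report.pooled))
lo, hi = report.overall_ci_pct
print(f"overall accuracy {report.overall_accuracy_pct:.2f}% (95%CI {lo:.2f} - {hi:.2f}%)")
```

prints

```
IF CD64_Mono > 3.25056 THEN inflammatory [78/78]
| true class | pred_bacterial | pred_viral | pred_aid_gvhd | pred_control | accuracy_pct | sensitivity_pct | specificity_pct |
|---|---|---|---|---|---|---|---|
| bacterial | 30 | 0 | 0 | 0 | 96.88 | 93.75 | 100 |
| viral | 0 | 25 | 1 | 0 | 99.46 | 100 | 98.92 |
| aid_gvhd | 2 | 0 | 19 | 3 | 94.95 | 95 | 94.9 |
| control | 0 | 0 | 0 | 38 | 96.34 | 92.68 | 100 |
overall accuracy 94.92% (95%CI 89.26 - 98.11%)
```

The single step-1 rule says that on this synthetic cohort an elevated
CD64 signal on monocytes (relative MFI above ≈3.3) covered all 78
inflammatory training cases with no false positive — CD64 is the planted
control-vs-inflammation discriminator, so this is the expected recovery.
The confusion matrix pools the 30 held-out folds; rows are true classes,
columns predictions, and the three percentage columns are the report
conventions (column-wise sensitivity/specificity and their mean; the
row-wise textbook values are available as `recall` and
`true_negative_rate`). Per-case explanations list the fired rules and the
step-2 decision path:

```python
print(model.explain(table.features.iloc[0]))
# step1: fired rule 'IF CD64_Mono > 3.25056 THEN inflammatory [78/78]'
# step2 path: CD169_Mono + HLADR_Mono <= 10.5664 ; CRP > 28.5899  ->  bacterial
```

The same workflow is available from the shell:

```bash
inflammadx simulate --seed 1 --out cohort.csv
inflammadx fit --data cohort.csv --seed 1 --out model.json
inflammadx cv --data cohort.csv --k 30 --seed 1
inflammadx explain --model model.json --data cohort.csv --rows 3
inflammadx importance --model model.json --data cohort.csv --out-prefix imp
```

## Layout

- `src/inflammadx/datamodel.py` — 18-feature schema (shipped as YAML), cohort container, CSV I/O
- `src/inflammadx/synthetic.py` — per-class cohort generator and planted-structure variants
- `src/inflammadx/rule_induction.py` — gain-ratio tree, rule extraction and simplification
- `src/inflammadx/abc_pruning.py` — computed ABC analysis, step-1 rule selection
- `src/inflammadx/smote.py` — SMOTE oversampling
- `src/inflammadx/bivariate.py` — Simpson-impurity bivariate tree (step 2)
- `src/inflammadx/metrics.py` — confusion matrices, report metrics, Clopper-Pearson CIs
- `src/inflammadx/importance.py` — ARI permutation importance, mirrored-density export
- `src/inflammadx/pipeline.py` — two-step model, stratified 30-fold CV, kNN/Bayes baselines
- `src/inflammadx/cli.py` — `inflammadx` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
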