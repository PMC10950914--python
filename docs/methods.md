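# Methods

This note records the modelling choices behind `inflammadx`: what each
stage computes, the defaults and why, what the synthetic cohorts do and do
not emulate, and the numerical conventions that make results reproducible
bit for bit.

## Cohort model

A cohort is `n` patients × 18 numeric features plus a four-level diagnosis
(`bacterial`, `viral`, `aid_gvhd`, `control`); the three disease labels
form the *inflammatory* superclass. The canonical feature names, units and
groups ship as a YAML schema (`src/inflammadx/data/feature_schema.yaml`)
and CSV inputs must match them exactly — silent unit or column confusion is
the main failure mode of multi-laboratory blood data. Validation rejects
missing, non-finite and negative values and percentages outside [0, 100];
nothing is imputed, because filling cells would silently move rule
thresholds. Relative MFI is taken as given input; how it was derived from
the lymphocyte negative population (ratio vs subtraction) is upstream of
this package. One unit oddity is preserved deliberately: hemoglobin is
listed under g/dL but its reference summary values run ≈100–118, which
suggests g/L; the generator reproduces the printed numbers verbatim and
leaves the unit question to the schema consumer.

## Synthetic cohorts

Because no patient-level data are available, a generator emulates the
study conditions.

* **CRP + hemogram (12 features):** parameterized by the published
  per-class mean and 95% CI, class sizes 30/26/24/38. The printed
  intervals are treated as normal-theory CIs of the mean, so the
  per-patient SD is `half_width/1.96 · √n`, with `n` fixed at the
  published class size (`ci_n`) even when a larger cohort is drawn.
* **MFI (6 features):** only graphical summaries exist, so per-class
  means/SDs are free parameters. The defaults encode the reported
  qualitative ordering — CD64 elevated in all inflammatory classes,
  CD169 on monocytes highest in viral infection, HLA-DR on monocytes
  elevated in AID/GVHD, and near-identical CD169/HLA-DR distributions on
  PMN (designed noise). The CD64 gap between AID/GVHD and controls is set
  moderate on purpose so the step-1 boundary overlaps a little; with a
  perfectly separated marker the rule stage degenerates to one rule on
  every seed. These numbers are synthetic, not published values.
* **Distribution families:** default is a truncated normal bounded at 0
  (and at 100 for percentage features); the pre-truncation location is
  moment-matched by root search so the post-truncation mean equals the
  configured mean (the SD is not re-matched — a documented simplification).
  A lognormal family is available for the right-skewed features; the
  percentage features stay truncated-normal under it so range invariants
  hold.
* **Independence:** features are drawn independently within a class. Real
  hemograms are strongly dependent (PMN% and PMN absolute are mechanically
  linked through WBC); passing tests on these cohorts therefore
  demonstrates algorithmic correctness and recovery of *planted* structure,
  not clinical performance.
* **Planted ratio:** for recovery benchmarks, one feature pair (default
  `Monocytes_abs` / `CD169_Mono`) is rewritten as
  `numerator = level_class · denominator · e^ε`, with the denominator
  redrawn from one shared broad lognormal (log-SD 1.0) and ε small
  (SD 0.08). The shared denominator spread dwarfs the level gaps, so
  neither marginal separates classes — only the ratio does. Levels
  (4.0/1.8/1.2) are all above 1 so that no sign test on the difference
  can shortcut the ratio; the ratio is then the unique clean separator a
  bivariate split search should find.

## Step 1: rules with ABC pruning

A gain-ratio tree (binary numeric splits, thresholds at midpoints of
consecutive distinct values, the classic mean-gain guard before taking the
ratio, ties to the lowest feature index then lowest threshold) is grown on
control-vs-inflammatory labels, then converted to one rule per leaf.
Conditions on the same feature and operator are merged to the tightest
bound, and a greedy pass drops any condition whose removal does not reduce
the rule's training precision; coverage/correct counts are recomputed
after simplification. The commercial C5.0 extras (pessimistic pruning,
winnowing, boosting) are intentionally absent: the pipeline consumes only
tree → rules → coverage counts.

Rule importance is the coverage count (correct-count and precision
orderings are selectable). The computed ABC analysis sorts values in
descending order and walks the cumulative-share curve:

* A|B boundary — the curve point closest (Euclidean) to the ideal point
  (0, 1), capped at the first break-even position (first point whose next
  item's value is at or below the mean). The cap makes a flat vector give
  an empty A set, which the pure distance rule would not.
* B|C boundary — the first point at/after A|B whose next segment's slope
  is strictly below 1; beyond it each item yields less than its effort.
  With all values equal, the slope is exactly 1 everywhere, so everything
  is break-even (B), nothing "trivial".

The A-set rules for the inflammatory class, ranked by coverage and padded
from B if needed, are truncated to two — the two-Boolean-rule structure of
the first diagnostic step. Any fired rule ⇒ inflammatory (disjunction);
no fired rule ⇒ control. "Class 1" is read as the inflammatory
superclass; the selection is logged and recorded in model metadata.

## Step 2: bivariate Simpson tree

Candidate node tests are every raw feature and every pairwise `+`, `−`,
`·`, `/` combination (`+`/`·` once per unordered pair, `−`/`/` in both
orders — 936 expressions over 18 features), each thresholded at midpoints
between consecutive distinct transformed values. The split minimizing the
case-weighted mean Simpson impurity of the two children is chosen;
recursion stops at pure nodes, `min_leaf` (default 5), `max_depth`
(default 6), or when no candidate strictly reduces impurity. The defaults
are chosen so a ~320-case SMOTE-extended training set yields trees of the
shallow, readable depth the two-step design calls for; both are exposed.

Determinism: candidates are enumerated in a fixed order (raw features by
index, then pairs by `(i, j, op)` with op order `+ − · /`), and ties in
weighted impurity resolve to the earliest candidate, then the lowest
threshold. Division candidates are invalid at a node whenever any routed
case has |denominator| < 1e-9 (absolute counts such as eosinophils can be
exactly 0); at prediction time a guarded denominator is substituted by
±1e-9 so the case still routes, and the explanation flags the guard.
Simpson impurity `1 − Σ p²` is identical to Gini impurity; the ecological
name is kept because the evenness reading motivates its use here.

## SMOTE

Each selected class of size `m` grows to `factor · m` (default 4): for
every original, `factor − 1` synthetics `x + u(z − x)` with `u ~ U(0,1)`
and `z` one of the k = 5 same-class nearest neighbours, chosen uniformly.
Neighbour search runs on per-class z-scored features by default because
the 18 parameters span four orders of magnitude; synthetics are generated
in the original space. Whether the original procedure standardized before
the neighbour search is unstated, hence the `standardize` toggle. `k` is
clipped to `m − 1` with a warning; classes of one member are an error.
Only the three inflammatory diagnoses are extended by default — step 1
always trains on original data.

## Evaluation conventions

Per-class "sensitivity", "specificity" and "accuracy" follow the report
conventions that reproduce the reference tables cell for cell:
sensitivity of class c = TP / (column total of predictions c) — a
predictive value — and specificity = TN / (all cases not predicted c),
with accuracy their arithmetic mean. The row-wise textbook quantities are
returned alongside as `recall` and `true_negative_rate` to keep the
discrepancy explicit. Output rounding is half-up to two decimals.

Binomial CIs are exact Clopper-Pearson via Beta quantiles — the
construction whose digits match the published intervals (Wilson's do not).

Cross-validation uses k = 30 stratified folds built by a round-robin deal
of shuffled class members with a fold cursor carried across classes: fold
sizes differ by at most one even when a class (24 members) is smaller
than k, a regime where off-the-shelf stratified splitters refuse to run.
Because the published procedure augments before splitting — which leaks
synthetic neighbours of test cases into training — the default here is
fold-internal augmentation; `paper_mode=True` replicates the leaky
ordering (one global augmentation, every fold trains on all synthetics,
evaluation on original cases only). Overall accuracy is reported both as
the pooled-confusion trace rate and the mean of fold accuracies; the two
differ in general and neither is forced to match the other. Baselines
(k-NN on z-scored features, Gaussian naive Bayes) run on identical folds.

## Permutation importance

Baseline `x` = ARI between prior labels and model predictions on the
unpermuted table. Per feature, 200 whole-column permutations (no refit),
each giving `y` and `R = 0.5(x−y)/(x+y)·100`, clamped to [−200, 200];
trials with `x + y = 0` are recorded as missing rather than fabricated,
since the formula is singular there. The ARI is the pair-counting
Hubert-Arabie form, with the usual convention that a pair-identical
clustering scores 1. `scope="inflammatory"` restricts rows and prior
labels to the three diagnoses and reuses the fitted model without
refitting — the analysis that shows CD64 mattering only for step 1. The
density export uses a Gaussian KDE (Silverman bandwidth) on a shared grid
rather than a parameter-free Pareto density estimate; raw R values are
always exported so any density method can be applied downstream.

## Problem sizes in the shipped checks

The test suite and the acceptance script exercise cohorts of 118 cases
(the published class sizes), 30-fold cross-validation, 20-seed
planted-ratio recovery, 200-trial importance runs, moment-recovery draws
of 30,000 cases, and exhaustive brute-force oracles on instances of up to
~10 cases and 3 features; these sizes make every check a few seconds to a
few tens of seconds on one CPU while keeping the brute-force comparisons
genuinely exhaustive.

## Known limitations

* Synthetic cohorts are feature-independent within class and cannot stand
  in for patient data; cohort-specific published results (e.g. an overall
  cross-validated accuracy near 81%) are not reproduction targets.
* The ABC boundary rules are one operationalization of the computed ABC
  idea ("important few" by distance to the ideal point, break-even by
  unit slope); other published variants may place boundaries slightly
  differently on near-flat curves.
* The rule stage approximates the C5.0 family rather than replicating its
  proprietary heuristics; rule sets can differ from C5.0's on the same
  data even though the structure (rules + coverage counts) is the same.
* The bivariate search is exhaustive over two-feature expressions only;
  three-feature interactions are out of scope by design.
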