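# Methods

This note documents the models, rules and numerical choices behind
`ckdtriage`, the defaults and why they were chosen, and what the synthetic
cohorts can and cannot show about real clinical data.

## Problem setting and model

The system classifies advanced chronic kidney disease (CKD, stages 3–5,
stage 3 split into 3a/3b) from a single routine laboratory panel, stages
confirmed cases, and converts sub-threshold gate probabilities into an
interpretable risk signal. Labels are ordinal in {non-CKD, 3a, 3b, 4, 5};
"CKD" always means stages 3–5. Early stages (1–2) are out of scope: their
diagnosis rests on albuminuria and longitudinal evidence that routine
panels do not carry, which is exactly why the sub-threshold risk path
exists.

### Binary gate

A probabilistic classifier (default XGBoost, library defaults, fixed seed,
single thread) on features chosen by recursive feature elimination
(one feature removed per round; default k = 26). The decision rule is
`p(CKD) ≥ τ` with τ tuned on the validation split by maximising balanced
accuracy over the 81-point grid 0.10–0.90 in steps of 0.01, breaking ties
toward the smallest maximiser. The inclusive boundary and small-τ
tie-break both favour sensitivity at the first decision point, the
clinically conservative direction for a screening gate; both choices are
explicit so boundary behaviour is testable. τ is tuned once and frozen in
the serialized head — test-time retuning is structurally impossible.

### Stage head

A feed-forward network (hidden widths 128 and 64, iteration cap 700,
fixed seed) trained only on CKD-labelled training rows, on the 22
top-scoring features by ANOVA F statistic. Stages are decided by maximum
probability; exact probability ties break toward the more severe stage
(clinical conservatism; an arbitrary but documented rule for a
measure-zero event). Stage classes absent from training are tolerated
with a warning and reported with probability zero.

### Risk score

With P0 / P1 the training gate probabilities of non-CKD / CKD rows, the
anchors are `p0 = Q_0.95(P0)` and `p1 = Q_0.05(P1)`; quantiles use linear
interpolation between order statistics, and the convention is stored with
the serialized anchors. The map is 0 below p0, 100 above p1 and **linear**
between — the minimal monotone form satisfying both endpoint identities;
the functional form between the anchors is a design choice of this
package. Degenerate anchors (p0 ≥ p1, possible on tiny or poorly
separated training sets) raise an error naming both values rather than
silently collapsing the ramp; a configurable minimum ramp width (intended
for robustness harnesses, default off) can floor `p1` at `p0 + ε`. Band
edges (20, 50) for low/moderate/high are illustrative working values,
inclusive at both moderate boundaries, and configurable — they are not
calibrated clinical rules and deliberately so, since the score is
cohort-relative.

### CKD-like cutpoints

Per feature, the disease direction is the sign of (CKD median − non-CKD
median); an exact tie excludes the feature from flagging. The default
derivation rule ("balanced") scans all observed values on the disease
side of the non-CKD median and maximises the balanced separation of the
one-dimensional rule (mean of sensitivity and specificity); in fully
separable cases ties resolve to the extreme observed disease-class value
nearest the gap, so the cutpoint sits on the disease side. Two quantile
rules are selectable (disease-class tail; non-CKD tail), and every stored
cutpoint records its rule and parameters. A single tail-quantile rule
cannot reproduce all published cutpoint patterns at once (some coincide
with the control tail, others sit far beyond it), so the derivation rule
is intentionally pluggable and auditable, and cutpoints re-load verbatim
from JSON so externally published thresholds can be applied unchanged.
Flagging is boundary-inclusive, and flags on imputed entries are annotated
as such. Note the deliberate dissociation: reference ranges (non-CKD
Q5–Q95) describe the cohort baseline; cutpoints describe similarity to the
disease population. A value can be outside the range yet unflagged, or
inside yet flagged. Under the balanced rule with strongly overlapping
classes the threshold settles between the class centres, so near-baseline
values can legitimately flag — the rule measures resemblance, not
abnormality.

### Shapley explanations

Local attributions for tree gates are computed by an exact path-dependent
tree-Shapley algorithm implemented in this package in float64: the value
of a feature coalition is the cover-weighted conditional expectation of
each tree (follow the record where the split feature is in the coalition,
average branches by training cover otherwise), and the attribution is the
exact Shapley value of that game computed in a single polynomial-time
traversal per tree. Attributions live on the margin (log-odds) scale,
where additivity is exact: baseline + Σ contributions = ensemble margin.
Probability-scale display is a presentation transform (the logistic of
the margin), never an attribution scale — margin attributions are not
additive in probability space. Two independent cross-checks are kept in
the test suite: exhaustive coalition enumeration on small trees (agreement
to 1e-9) and the booster's native contribution predictor (agreement to
float32 precision). Threshold comparisons in the parsed ensemble mirror
the booster's float32 semantics so forward passes agree exactly. The
additive intercept is recovered from a probe prediction rather than from
the serialized base-score field, which is version-dependent.

Global weights are mean absolute attributions over a seeded training
subsample (default 200 rows), normalised to sum to one; they are computed
through the booster's native batch predictor, which evaluates the same
tree game. For non-tree gates a permutation-sampling attribution is
available behind an explicit flag; each sampled permutation telescopes, so
its contributions are exactly additive around the sampled baseline.

### Explanation policy

Driver reports exist only on the non-CKD path: primary drivers are
features with positive attribution that also crossed their CKD-like
cutpoint, sorted by attribution share; flagged features that do not
qualify appear as additional signals. Impact labels derive from a
feature's share of the record's total absolute attribution — High ≥ 25%,
Moderate ≥ 10%, else Low. The quantity is principled; the edges are this
package's defaults and configurable. The output policy is total and
exclusive: every request yields exactly one of {CKD decision + stage},
{non-CKD + p(CKD) + risk (+ drivers iff risk > 0)}, {validation error}.

## Preprocessing and leakage control

- **Sparse filter**: features missing in strictly more than 70% of rows
  are dropped (a column at exactly 70% survives); the kept/dropped lists
  are serialized and replayed at inference.
- **Splits**: patient-level, stratified on the full 5-class label so the
  binary and stage partitions stay aligned; default hold-out 70/15/15.
  Cross-validation uses stratified outer folds with an inner validation
  split (default fraction 0.176, mirroring the 15/85 proportion of the
  hold-out design) carved from each outer-train for threshold tuning;
  the outer test fold touches nothing fitted. CV is evaluation-only —
  the deployable bundle always comes from the single hold-out run.
- **Imputation**: scikit-learn's chained-equation imputer
  (`IterativeImputer`), 10 iterations, default Bayesian-ridge conditional
  models, seeded. The iteration count and conditional family are this
  package's choices. Features whose observed training values are negative
  in at most 0.5% of cases are treated as physiologically non-negative
  (the tolerance is configurable; the underlying notion — "negligible
  negatives" — needed a number). The non-negativity clamp applies only to
  imputed entries; observed measurements are never altered, verified
  against the observed mask. Features with no observed training values
  are excluded from the imputation model, reported, and constant-filled.
- **Scaling**: two independent MinMax scalers to [0, 1] — one fitted on
  all training rows (binary head), one on CKD training rows only (stage
  head) — so the tasks never couple through normalisation. Out-of-range
  inference values pass through the affine map unclipped: clipping would
  silently flatten extreme pathology onto the boundary. Constant features
  map to 0.
- **Leakage guards** are tested end-to-end: permuting all test-split
  feature values before training changes no fitted state (byte-compared
  serializations), no selection, no τ and no anchors.

## Synthetic cohorts: what they emulate and what they do not

The generator emulates the structure of a single-centre renal-clinic
dataset: one row per patient; 39 routinely ordered demographic and
laboratory features plus 21 rarely ordered ones (default 80% missing, so
the sparse filter has real work); five ordinal classes with a
dialysis-clinic-skewed default mix (0.35, 0.15, 0.15, 0.15, 0.20);
class-conditional Gaussian features with signed mean shifts scaled by a
strictly increasing stage-severity profile (0, 1, 1.5, 2, 2.8) and a
global `separation` multiplier; truncated re-draw (100 attempts, then
clamp) for physiological lower bounds; completely-at-random missingness
at stated per-feature rates, with a per-class multiplier hook for
label-dependent-missingness stress tests. Binary demographics
(sex, comorbidities) are modelled as continuous propensities for
simplicity.

It does **not** model inter-marker covariance (e.g. the
creatinine–urea–hemoglobin correlation structure), measurement error
heterogeneity, informative missingness, or longitudinal dynamics.
Consequently, passing the synthetic-recovery suite shows that the
pipeline correctly extracts class structure it was given and that the
machinery is leak-free and reproducible — it does not certify clinical
performance on real cohorts, where class overlap, covariance and
missingness mechanisms are less benign.

## Problem sizes and defaults used in the test and acceptance suites

The synthetic-recovery suite uses 500-patient cohorts over 10 seeds, with
separation 3 for the recovery bounds (gate balanced accuracy ≥ 0.95,
stage macro-F1 ≥ 0.80 on the untouched test split) and separation 0 for
the chance check, judged on the mean validation AUC across the same seeds
(a single 75-record split has Monte-Carlo spread of roughly ±0.07, so the
mean is the stable estimand). Cross-validation tests run at k = 3–5 on
300–400 patients with reduced head sizes. These sizes are the package's
study conditions for desk-scale verification; all are configurable.

## Known limitations

- The stage head is not explained by default (the gate is the explained
  model); the sampling attribution behind the flag is unbiased but
  stochastic.
- The balanced cutpoint rule is one defensible choice among several; on
  strongly overlapping features its thresholds flag liberally. Loading
  externally derived cutpoints is the intended path when a vetted set
  exists.
- The risk score is cohort-relative by construction; its band edges and
  its anchors do not transfer across populations without refitting.
- Determinism guarantees (bit-identical bundles, replayed inference) hold
  for fixed seeds on a fixed software stack; they are not cross-platform
  floating-point guarantees.
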