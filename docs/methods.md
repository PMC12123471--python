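# Methods

`fairadmit` studies a question about algorithmic fairness in clinical risk
prediction: when a model that predicts emergency-department (ED) admission is
debiased with respect to *marginal* patient groups (each protected attribute
taken separately), how much of that fairness transfers to *intersectional*
groups (cells of the joint attribute product)?  A model can be well
calibrated for women and for Asian patients overall while remaining badly
calibrated for Asian women — the phenomenon known as fairness
gerrymandering.  The package provides the full experimental machinery:
a synthetic cohort generator with a known ground truth, two debiasing
algorithms (multicalibration postprocessing and worst-case-FNR
multiobjective training), subgroup evaluation metrics, and a paired
statistical comparison harness.

## Synthetic cohorts

Real ED datasets of this kind are credentialed or private, so the generator
produces visit-level tables whose statistical structure reproduces what
makes the problem hard:

* **Protected attributes.** Categorical attributes drawn from a joint
  probability vector over the cell product.  The shipped preset uses an
  ethnoracial attribute (5 levels) crossed with gender (2 levels), with
  marginal prevalences taken from a published adult-ED cohort summary; the
  smallest cell (American Indian or Alaska Native men) holds ~0.11% of
  visits, matching the smallest group such studies analyze, and the largest
  (White women) ~34%.
* **Features.** Normal, lognormal, and ordinal-categorical families cover
  the shapes of age, vitals-like measurements, visit-history counts, and
  5-level triage acuity.  No attempt is made to model real vital-sign
  physiology, within-patient correlation across visits, or free-text/lab
  features; visits are independent rows.
* **Outcome.** Admission is Bernoulli with a logistic linear predictor:
  intercept + feature terms + per-level main-effect log-odds offsets + per
  intersectional-cell interaction offsets.  The logistic probability is
  emitted as a `true_risk` column, giving every experiment a calibration
  oracle.

One integer seed drives three independent substreams (attributes, features,
outcomes), so regenerating with a different `n_visits` does not reshuffle
earlier draws and identical configurations are byte-identical.

**The planted bias.**  The preset's interaction offsets are the load-bearing
design choice.  They are *sign-mixed within marginal groups*: the two
largest ethnoracial groups carry an XOR pattern across gender (White men
+0.5, White women −0.5, Black men −0.5, Black women +0.5 on the log-odds
scale), the Asian group carries a cancelling ±0.9 pair, and the small
groups carry one-sided offsets (American Indian or Alaska Native men +1.2,
Hispanic or Latino women −0.8).  A risk model built from main effects only
— which is exactly what the reference learner uses — cannot represent any
of the XOR component at any sample size, and a debiaser that only sees
marginal groups cannot repair it, because the residuals cancel inside every
marginal group.  Intersectional debiasing can.  The offsets are large
enough that the base-vs-intersectional comparison has essentially full
power at the package's reference scale (20 000 visits, 20 paired trials).
The intercept (−1.57) was calibrated once so the expected admission rate is
~29.5%, the adult cohort's overall rate.

What passing tests on this generator do *not* show: that the same gains
appear on real data, where interactions are weaker and confounded with
feature distributions, visits are correlated within patients, and
demographics are partially missing.  The generator is a power tool for
verifying the machinery, not a claim about effect sizes in the wild.

## Group collections

A debiasing scenario names the collection `C` of subgroups: `base` (none),
`single:<attr>` (one attribute's levels), `marginal` (all attributes'
levels), `intersectional` (observed cells of the product; unobserved cells
are omitted because they could never pass the prevalence cutoff and would
break rate denominators).  Groups are labelled canonically
(`attr=level; attr=level`, attribute-sorted) so that every sweep and every
export is deterministic.  A prevalence cutoff γ (default 0.001, i.e. 0.1%
of records) drops groups too small to estimate.

## Metrics

* **ECE** — count-weighted mean over 10 equal-width prediction bins
  (right-open except the last) of |mean outcome − mean prediction|.
  Max-over-bins is available as a sensitivity variant.  10 bins matches the
  binning the debiasing constraint itself uses; both are configurable.
* **FNR / FPR** — a record is predicted admitted iff score ≥ threshold;
  FNR is the fraction of truly admitted visits below it.  A group with no
  positives has *undefined* FNR, reported as NaN and excluded from
  mean/max summaries — never an exception, never a 0/0 masquerading as 0.
* **Balanced accuracy** — (sensitivity + specificity)/2.
* **AUROC / AUPRC** — tie-aware pair probability and precision-weighted
  recall increments (via scikit-learn; brute-force enumerations serve as
  test oracles).
* **Multicalibration audit** — enumerate every (group × bin) cell; a score
  vector is (α, γ)-multicalibrated when no cell holding ≥ γ of *all*
  records has |mean outcome − mean prediction| > α.  Cell prevalence is
  measured against the full evaluation set, the same semantics as the
  group-level γ.

## Multicalibration postprocessing

Sweeps run over groups in canonical label order and bins in ascending
order (a seeded random order is available; the fixed order is the default
for determinism).  In each visited cell, recomputed on *current* scores, a
residual Δ = mean(y) − mean(s) with |Δ| > α and prevalence ≥ γ triggers an
additive update: every member's score += step·Δ, clipped to [0, 1]
(step = 1 by default; a logit-space variant was considered and rejected for
v1 — the additive form matches the residual definition exactly and keeps
the replay contract trivial).  Fitting stops when a full sweep makes no
update (converged — the fit-set audit is then violation-free by
construction, which the fitted object stores as a certificate) or after
`max_sweeps` (default 100) with a warning.

Updates are recorded in order and replayed on held-out predictions: each
update applies to records *currently* in its (group ∩ bin), so a record
moved out of a bin by an earlier update is not touched by a later update
targeting the old bin.  Fit and replay share one code path for the score
arithmetic, making replay on the fit data bit-identical — a property the
tests assert exactly.  Updates are learned on the training half and
replayed on test by default; fitting on a separate calibration split is
possible by passing that split to `fit_multicalibration` directly.

At small fit sizes the γ cutoff admits cells of only ~10 members whose
residuals are mostly noise; repairs to such cells generalize poorly.  This
is a real property of the algorithm at desk scale, visible in the
experiments as shrinking test-side gains for the smallest groups.

## Worst-case-FNR multiobjective training

The trainer searches over per-group sample-weight multipliers (one gene
per group in the debiasing collection, box-constrained to [0.1, 10];
records in several groups multiply their multipliers, records in none keep
weight 1).  Each genome is scored by fitting the base learner with those
weights on 75% of the training half and evaluating on the remaining 25%
(stratified): objective 1 is 1 − balanced accuracy, objective 2 the
maximum FNR over the *intersectional* collection — always intersectional,
whatever collection indexes the weights, because transfer to
intersections is the measurement axis of the whole experiment.

Inside the fairness objective, group FNRs are shrunk with a
Beta(c·π, c·(1−π)) prior — estimate (FN + c·π)/(P + c) with c = 2 and π =
training admission rate.  Without it, a 0.1%-prevalence group contributes
~2 validation positives, its raw FNR is 0/half/1-valued, and the worst case
can sit at a flat 1.0 for every genome, collapsing the search; mild
shrinkage keeps the objective informative while leaving all *reported*
metrics unsmoothed.

The search itself is a seeded elitist evolutionary loop: fast nondominated
sorting with crowding-distance diversity, binary tournaments, simulated
binary crossover (η = 15) and polynomial mutation (η = 20, rate 1/genes),
population 50 × 50 generations by default.  The all-ones genome (the
unweighted base learner) is always injected into the initial population,
so the returned front can never be worse than the baseline on the fairness
axis — an invariant the tests assert.  Identical seeds give identical
fronts; genome evaluations are cached by value.

Two selection policies are shipped.  `min_fairness` (default) takes the
front's best fairness objective, ties broken by error — the choice aligned
with a worst-case objective, but the one most exposed to validation-split
overfitting (on unlucky seeds it can give back up to ~0.03 test AUROC).
`knee` takes the solution nearest the ideal point after min-max
normalization — safer on accuracy, but it can select a near-no-op.
Neither is claimed to be what any particular study used.  The selected
genome is refitted on the full training half before test scoring.

## Experiment harness

Each trial: a seeded 50/50 row split (degenerate single-class splits are
retried on a documented offset stream); base-learner hyperparameters tuned
on train by successive-halving grid search (3-fold stratified CV, balanced
accuracy; logistic grid: lasso/ridge × C ∈ {0.01, 0.1, 1, 10}; the random
forest preset — 100 trees, depth 4 — has no grid and fits directly); the
scenario's debiasing applied; metrics computed on the untouched test half
over the intersectional collection, whose group list is fixed by applying
γ on the full dataset before splitting so it is identical across trials
and scenarios.  Trial *t* of every scenario shares split seed
`base_seed + t`, so scenario comparisons are paired trial-for-trial.
Tuning is repeated per trial (conservative); pass a single-point grid to
freeze it.

The preset comparison uses a classification threshold of 0.3 — near the
cohort's admission prevalence, where sensitivity and specificity are
comparable — because at 0.5 most true positives of a ~30%-prevalence,
well-calibrated score sit below threshold and small-group FNRs saturate
at 1.  The metric functions themselves default to 0.5.

Paired per-trial summaries (mean-over-intersectional-groups ECE or FNR)
are compared with two-sided Wilcoxon signed-rank tests: zeros dropped,
midranks for ties, statistic min(W⁺, W⁻); the null distribution is exact
for n ≤ 25 (dynamic programming over doubled ranks, so midranks stay
integral) and a tie- and continuity-corrected normal approximation beyond.
Holm–Bonferroni is applied across all pairs within one report (the
correction family is per report by design; widen it by putting more pairs
in one call).  Significance is read at adjusted p ≤ 0.05.

## Reference problem sizes

The shipped experiments use cohorts of 20 000 visits, 20 paired trials for
the calibration comparison, and a 50 × 50 evolutionary budget for the FNR
task — sizes at which every planted effect is detectable with the paired
design while a full run stays in the minutes range on one CPU.  All are
plain arguments; scaling any of them up changes nothing structural.

## Known limitations

* Row-level splits assume independent visits; with repeated patients a
  patient-level split would be needed (the generator emits independent
  visits, so splits are exact here).
* The worst-case test FNR over groups that include 0.1%-prevalence cells
  is an inherently high-variance statistic at these sizes; single-trial
  improvements on it should be read with that noise floor in mind.
* Proportional multicalibration (residuals relative to outcome rate) and
  FNR-parity objectives are deliberately out of scope; the trainer
  minimizes the worst case rather than equalizing groups.
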