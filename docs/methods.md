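# Methods

## Problem and model

`cpirank` predicts therapeutic indications for small molecules from their
*chemical–protein interactome* (CPI) profile: the vector of in-silico docking
scores (predicted binding free energies, kcal/mol; more negative = stronger
predicted binding) of the molecule against a fixed panel of protein
structures. The premise is that therapeutic effects are mediated by protein
binding, so molecules with similar binding profiles tend to share
indications — and a supervised model per disease can learn which targets
matter for that disease.

Each *endpoint* is one binary task: "is drug *d* indicated for disease code
*e*?", with diseases encoded as ICD-9 codes at two hierarchy levels — the
individual code (e.g. 250.10) and its 3-digit family (250, obtained by
truncating at the decimal point). A drug is positive for a family iff it is
positive for at least one member code (the rollup is a union). Before
training, endpoints are filtered: codes with numeric family in 780–999
(symptoms, injuries, poisoning) are removed, as are endpoints with fewer
than five positive drugs. V- and E-codes are excluded by default because the
range rule presumes numeric families; `keep_ve=True` retains them. The
exclusion interval is inclusive at both ends and is tested against the
family integer, so 785.1 is excluded via family 785.

Per endpoint, the classifier is logistic regression with an L2 penalty
(inverse penalty `reg_strength`, default 1.0) on per-target z-scored
features. Standardization is fitted on each training split: docking scores
share units but differ in location per target pocket, and a penalized model
needs comparable feature scales. A target with zero variance in the training
split keeps an sd sentinel of 1 and necessarily receives weight 0. The
optimizer runs to tolerance 1e-8 with at most 1000 iterations (L-BFGS), so
fits are deterministic given identical input.

## Cross-validation and metrics

Evaluation is repeated k-fold cross-validation (default k = 10). Per repeat,
**one** random drug-level partition (fold sizes differing by at most one) is
shared by all endpoints; each endpoint model is trained on k−1 folds and
scored on the held-out fold. The shared partition is what makes the pooled
"global" metrics well defined: every (drug, endpoint) cell of a repeat is an
out-of-fold score from a model that never saw that drug. When a training
split has fewer than two positives or two negatives for some endpoint — 
unavoidable for 5-positive endpoints under 10-fold CV — that fold's model
degrades to a constant predicting the training prevalence, and the event is
logged. Optional per-endpoint stratification spreads one endpoint's
positives evenly over folds; the default is unstratified, uniform folds.

Three aggregation protocols:

* **global** — pool every (drug, disease) score into one vector and compute
  each metric once;
* **drug-centric** — per-drug metrics, then an unweighted mean ± sd over drugs;
* **disease-centric** — the same per disease.

AUROC is the Mann–Whitney statistic `P(s_pos > s_neg) + 0.5 P(tie)`; AUPR is
average precision (step-wise, because trapezoidal PR interpolation is
optimistically biased). Binary metrics use the threshold that maximizes the
F-score on the pooled out-of-fold scores of the repeat, with prediction
positive iff score ≥ threshold (inclusive), candidates at midpoints between
consecutive distinct scores plus sentinels below the minimum and above the
maximum, and F ties broken toward the smaller threshold (higher
sensitivity). A per-endpoint threshold mode exists but the global threshold
is the default. Per-entity metrics undefined for single-class entities are
skipped and counted, never imputed. Entity sds are population sds
(divisor n). Repeated-CV summaries report mean ± population sd over repeats.

The pooled out-of-fold AUROC carries a small finite-sample bias away from
0.5 on null data (a fold's score location shifts with its training
prevalence, which anticorrelates with the test fold's prevalence). The bias
shrinks with the drug count and is ≈0.003 at the default 300-drug scale but
can reach 0.08 at 100–200 drugs; calibration checks therefore run at the
default scale.

## Empirical-Bayes score normalization

Raw per-endpoint scores of one drug are not comparable across endpoints
(each model has its own prevalence and scale). To rank indications within a
drug, the diseases a drug treats form Group 1 and the rest Group 0, and the
reported confidence for score *y* is the posterior

P(G1 | y) = P(y | G1) P(G1) / ( P(y | G1) P(G1) + P(y | G0) P(G0) ),

with priors the empirical group proportions and likelihoods density
estimates of each group's training scores. Densities are Gaussian KDEs with
Silverman bandwidth; a group with fewer than five samples (per-drug Group-1
sets are often tiny) falls back to a single Gaussian at the group mean whose
scale is a Silverman bandwidth computed from both groups pooled (floored at
1e-3 against degenerate samples). Densities are floored at 1e-12 before the
ratio; when both land on the floor the posterior collapses to the prior,
with a warning. Scores outside the fitted support are evaluated through the
estimator tails, never clipped. Distributions may be fitted per training
drug or pooled over all training (drug, disease) pairs split by label;
pooled is the default and the only option for molecules not present in
training.

## Ranked reports

Prediction for a new profile runs two independent model tiers — individual
disease codes and 3-digit families. A family's confidence comes from the
family-tier model, never from aggregating its members; the two can
legitimately disagree (a family model may score above every member), and the
report carries both without reconciliation. Families are ordered by
family-tier confidence descending, ties broken by ascending code; members
within a family likewise. By default the report keeps families with
confidence above a floor (0.5) or, when `top_n` is given, the best `top_n`.
Serialization fixes key order and prints floats with six decimals, so equal
reports are byte-identical.

## Similarity leakage filter

Structural near-duplicates between training and validation sets inflate
apparent generalization. Given binary fingerprints (any family — ECFP,
MACCS, …; the filter is fingerprint-agnostic), a validation drug is removed
iff its maximum Tanimoto similarity |A∩B|/|A∪B| over the training set is
*strictly* greater than the cutoff (default 0.7); a drug exactly at the
cutoff is retained. Two empty fingerprints compare as 0.0 (the conservative
"not similar"), with a warning.

## Synthetic data generator

The generator emulates a docking-score matrix with known planted structure,
so every pipeline stage is testable without external data. Per target *t*, a
baseline binding energy μ_t ~ Uniform(−9, −5) kcal/mol; per (drug, target),
a nonnegative binding boost b ~ |Normal(0, 1)| that subtracts from the score
(docking-energy convention), plus observation noise ε ~ Normal(0, σ). Each
disease receives `causal_per_disease` (default 3) causal targets, and labels
are Bernoulli with

P(y = 1) = logistic( α_j + β · mean over causal targets of z ),

where z is the boost z-scored to mean 0, sd 1 — β (default 3) is therefore a
log-odds slope per standard unit of binding strength — and α_j is solved by
bisection on the empirical drug sample so realized prevalence matches the
target (default 0.1) to 1e-4. β = 0 is a built-in null: labels independent
of scores by construction. `permute_labels` provides the complementary null,
redrawing each endpoint's positive drugs uniformly while preserving counts.

Default conditions are 300 drugs × 50 targets × 20 diseases. The noise
default is σ = 0.1: small relative to the unit-scale boosts, so the latent
binding signal is nearly fully observable in the emitted score and the
strong-signal benchmark probes the classifier's estimation loss rather than
compounding two noise sources. Under these conditions the full CV pipeline
attains global AUROC ≈ 0.75–0.78 depending on the generated dataset, and the
causal targets out-weight non-causal ones (mean |coefficient|) in
essentially all diseases. Disease codes are synthetic ICD-9-style strings
spread over families 100–699 (two member codes per family by default, so
family rollup is exercised); an optional decoy block plants endpoints in the
excluded 780–999 range to exercise the range filter.

What the generator does *not* emulate: docking physics, correlated binding
pockets (targets are independent), promiscuous-binder drugs, hierarchical
label noise, or class-prevalence heterogeneity across diseases. Passing
tests demonstrate that the machinery is correct and calibrated, not that any
particular real-world performance level will be reached.

## Numerical and design choices

* Missing docking scores are a hard error by default; `impute="target_mean"`
  fills with column means. Scores are stored file-faithful (negative =
  favorable); sign handling lives entirely in standardization/weights.
* All randomness flows from one integer seed; cross-validation derives one
  child seed per repeat (seed sequence spawning with the repeat index), so
  results are reproducible and repeats independent.
* Floats serialize with six decimals, '.' separator, no locale; writers are
  deterministic so identical inputs give byte-identical files.
* CLI exit codes: 0 success, 2 validation error, 3 computation error.
* Problem sizes in the shipped checks and the reproduction script (300
  drugs, 5–20 CV repeats) are chosen so the whole suite runs in minutes on
  one CPU while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* Real CPI matrices have correlated targets and batch structure the
  generator does not model; the EB normalizer assumes training scores are
  representative of the query drug's score distribution.
* The per-drug EB mode requires the drug to have at least one positive and
  one negative training disease; drugs with no positives must use pooled
  mode.
* The pooled-CV null bias noted above means global AUROC on very small drug
  panels (< ~200) should be compared against a permutation baseline, not
  against 0.5.
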