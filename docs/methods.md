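# Methods

## Problem and model

`graphonc` predicts the primary site of a cancer from coded clinical history:
given a patient's genetic test results (gene symbols), lab tests (LOINC codes
with numeric values and reference ranges), diagnoses (ICD-9), medications
(RxNorm), family history (ICD-9) and demographics, a classifier assigns one of
nine ICD-9 primary-cancer codes.  Two feature representations are combined:

**Bag of features.**  Each distinct coded item becomes a binary indicator; a
patient's indicator is 1 iff they have at least one matching record.  Lab
results are discretized against their per-record reference range into
*Null* / *Normal* / *Abnormal* and keyed `code=category`.  Age enters as raw
years and sex as indicator columns.  Indicators are ranked by information gain
— I(F;Y) = H(Y) − H(Y|F) in bits — and the top *d* (default 100) are kept,
recomputed inside every training fold so selection never sees held-out labels.

**Graph embedding.**  The cohort is converted to RDF triples by two rules:
every string-typed coded value becomes an entity node, and every value is
attached to its patient by a property named for its family (`hasGenetic`,
`hasCondition`, `hasLab`, `hasMedication`, `hasFamilyHistory`,
`hasDemographic`).  Merging all patients yields an undirected, unweighted,
deduplicated network with 7 node types in which every edge joins a patient to
a value node — the graph is bipartite by construction.  Node2vec is
implemented from scratch: second-order random walks biased by the return
parameter p and in-out parameter q (weight 1/p to revisit the previous node, 1
for a neighbor of the previous node, 1/q otherwise; because the graph is
bipartite the two walk endpoints are never adjacent, so in practice each step
chooses between returning at 1/p and exploring at 1/q), followed by skip-gram
with negative sampling.  Patient-node vectors become the embedding features.
The hybrid ("fused") representation concatenates selected indicators with the
embedding columns; the spelled-out linear-combination reading is dimensionally
impossible for unequal widths, so concatenation is the implemented and
standard interpretation.

Classifiers follow conventional settings: random forest with 500 trees (the
default and best performer), Gaussian naive Bayes with defaults,
L2-regularized logistic regression, and a C-classification SVM with linear
kernel whose scores are Platt-calibrated so every algorithm emits class
probabilities.  Columns that are constant in a training set are excluded from
the fit (they carry no information and would only perturb the estimator's RNG
stream); the feature manifest still records them.

## Evaluation

10-fold cross-validation with a random partition into near-equal folds
(stratified fallback with a warning when a class has fewer members than k).
Each patient is scored exactly once by a model that never saw it; one-vs-rest
AUROC (midrank Mann–Whitney form) and AUPRC (average precision) are computed
per class from the pooled held-out scores, and the macro value is their
unweighted mean.  Pooling over folds, rather than averaging per-fold AUROCs,
is the package's reporting convention; per-fold values are retained for paired
comparison.  Two models are compared with a two-sided Wilcoxon signed-rank
test on paired fold scores: the exact null distribution (subset-sum dynamic
programming over rank assignments) when there are no zeros or tied magnitudes
and n ≤ 25, otherwise a normal approximation with Pratt's treatment of zeros,
tie correction and continuity correction.

**Look-back ablation.**  The time filter removes diagnosis, medication and lab
records dated after `diagnosis_date − months_before`, with a month equal to
30.44 days; genetics, family history and demographics are retained at every
horizon, reflecting that a genetic report, once on file, remains available.

**Unknown-primary evaluation.**  A model trained once on the labelled cohort
scores a held-out cohort whose site-specific signal is suppressed; per-class
one-vs-rest AUROC is computed among the held-out patients only.  Classes
unseen in training, or lacking both polarities in the held-out set, are
skipped with a warning.

**Attribution.**  Shapley values of the class probability.  The value of a
feature coalition replaces out-of-coalition features with draws from a
background distribution (default: 100 samples from the training set's
per-feature marginals).  Exact enumeration over all 2^F coalitions is used for
F ≤ 16, satisfying efficiency (Σφ = f(x) − E_bg[f]) to float precision;
otherwise an unbiased permutation-sampling estimator with one background draw
per permutation.  Per-class rankings average contributions over a sample of
in-class patients and sort by absolute value.

## Embedding: transductive use and leakage

Embeddings are trained on the graph over *all* patients (training and
held-out) without any use of labels, and the learned patient vectors are fixed
before fold-wise classifier training.  This transductive convention means a
held-out patient's record structure — never its label — influences the
representation; the leakage-sensitive steps (feature selection, classifier
fitting) remain strictly inside training folds, and a test verifies that
flipping a held-out patient's label cannot change the score it receives.

## Numerical and implementation choices

* Skip-gram optimizer: sequential SGD (numba-compiled inner loop), 5 negative
  samples from the unigram distribution raised to 3/4, initial learning rate
  0.025 with linear decay to 1e-4 of its start, 5 epochs by default, input
  vectors initialized uniformly in [−0.5/d, 0.5/d], output vectors at zero,
  scores clamped to ±10 before the sigmoid.  Walks with p = q = 1 reduce to
  first-order random walks and take a vectorized sampling path; the general
  second-order sampler draws from the normalized bias weights.
* Default embedding operating point: γ=10 walks per node, length t=80, window
  w=10, dimension d=50, p=q=1 — the middle of the standard grid (γ∈{10,40},
  p,q∈{0.5,1,2}, d∈{10..100}, w∈{5,10}, t∈{40,80}), which
  `graphonc.pipeline.embedding_grid` enumerates for grid search.
* Information-gain ties are broken by lexical feature name, making selections
  deterministic and nested in d.
* Normal lab results do form graph entities (`code=Normal`); Null results emit
  no edge — absence of a measurement carries no association.  A switch
  (`include_normal_labs`) exposes the stricter abnormal-only reading.
* Age is binned into decades for graph nodes but kept as raw years in the
  indicator block; both grain choices are recorded in feature names.
* Dates are calendar dates; a "month" is a 30.44-day interval anchored at the
  diagnosis date.
* Target-record stripping removes exactly the nine target cancer codes from
  condition records (the narrow reading); widening the removal set is a
  parameter.

## Synthetic cohort generator

No public cohort with linked genetic reports and EHR records exists, so the
generator is a first-class module that emulates the statistical structure the
pipeline assumes.  Defaults: 9 classes × 100 patients; marker prevalence
θ_signal = 0.6 in class versus θ_background = 0.05 elsewhere; vocabulary of
300 genes, 200 labs, 400 diagnoses, 300 medications, 100 family-history codes;
background items at realistic prevalences echoing published oncology-cohort
frequency tables (TP53 0.547, KRAS 0.289, near-universal CBC labs, …).

Class signal mirrors classic tumor-marker knowledge: PSA + testosterone + male
sex → prostate; CA 15-3 + female → breast; CA-125 + female → ovary; CA 19-9 +
lipase → pancreas; AFP + ALT → liver; thyroglobulin antibody + *TERT* →
thyroid; *EGFR* → lung; *APC* → colon; *NF1* → soft tissue; each class also
gets one site-specific symptom diagnosis (GI bleed, breast lump, BPH, …).
Four sites are deliberately gene-anchored so that removing the genetics family
costs measurable accuracy, expressing the qualitative value of genetic data.

Record timing: every dated record draws a whole month 0–36 before the
patient's diagnosis date.  Phenotype markers get `marker_visits` = 4
independent dated chances, each present with probability
θ_signal·exp(−0.08·months) — repeat encounters with signal that decays with
distance from diagnosis.  One presence draw per marker would cap a class's
achievable one-vs-rest AUROC near 0.78 (a single binary feature at 0.6 vs 0.05
prevalence), which no published EHR cohort resembles; the multi-visit design
restores realistic longitudinal redundancy while keeping the per-record decay
law exact, so the look-back ablation degrades smoothly.  Genetic observations
are drawn once with a report date at the diagnostic workup and do not decay
with horizon — genetic testing happens once, near diagnosis — which is what
makes genetics increasingly valuable at long horizons.  Each patient also
carries its own cancer code as a condition at the diagnosis date, which the
preprocessing strip must remove.

The unknown-primary variant interpolates marker gene/lab prevalence toward
background by the suppression fraction s (θ_b + (θ_s−θ_b)(1−s)) and thins
site-specific marker diagnoses by (1−s): at s=0 it is distributionally
identical to the standard generator, at s=1 site diagnoses are absent and
marker prevalence equals background.  Sex and demographics are untouched — an
unknown-primary patient still has a sex — so a fully suppressed cohort retains
the (real) demographic signal for the sex-linked cancers.

What the generator does **not** emulate: care-pathway correlations between
codes, visit clustering, code hierarchies (ICD-9 families), lab value
autocorrelation, missing-not-at-random patterns, or inter-marker biological
correlation.  Passing tests therefore show the pipeline recovers planted
conditional-independence structure at realistic prevalences; they do not
certify performance on real EHR data.

## Problem sizes used in tests and the acceptance script

Study-scale runs use the default 9×100 cohort with 10-fold CV, random forest
(500 trees), d=100 selected indicators, and an embedding operating point of
γ=10, t=40, w=5, d=50, 3 epochs — chosen so a full fused cross-validated run
completes in about a minute on one CPU while preserving the embedding's
behavior (the package default of t=80, w=10, 5 epochs is used where a single
embedding is trained).  Unit tests use miniature cohorts (tens of patients)
and small forests.  The unknown-primary evaluation uses 9×30 held-out
patients.  Attribution checks use 15 in-class explicands, 30 sampled
permutations each, against a 100-sample marginal background.

## Known limitations

* The Wilcoxon exact path requires untied magnitudes; tied fold scores fall
  back to the corrected normal approximation even at small n.
* Embedding training is sequential SGD; results are exactly reproducible for
  a fixed seed but, like word2vec, not invariant to changing the number of
  epochs or corpus order.
* The adjacency matrix is dense (|V|² bytes); it is an export for downstream
  consumers, not used internally.
* Platt calibration for the linear SVM runs an internal cross-validation and
  is the slowest of the four classifiers on wide matrices.
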