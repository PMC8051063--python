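# Methods

This note describes the models and procedures the package implements, the
design choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## The harmonization problem

Standardized child-behavior instruments (ADI-R, ADOS-2, BASC-3, BRIEF2,
CBCL, Conners 3, SRS-2, VADRS) probe heavily overlapping behavioral
concepts with incompatible item sets and answer scales. A clinical dataset
assembled from several sources therefore looks like a block-missing
patchwork: each child has completed one or two instrument versions and
nothing else, and no column is shared across the cohort. The package
implements a semantic crosswalk that fuses such data onto a single bank of
harmonized ordinal questions, and the downstream machine-learning pipeline
that the fused representation enables.

## Semantic hierarchy

Behavioral concepts are organized in a tree with three top-level domains —
Cognitive, Motor, Somatic — refined into subgroups and ultimately into 57
leaf categories (e.g. `Cognitive/Behavioral/Emotional/Adaptability`).
Every harmonized question hangs on exactly one leaf. Node identifiers are
full slash-delimited paths because several subgroups own a catch-all leaf
that repeats the subgroup's own name (`Social/Social`); plain labels would
be ambiguous.

The packaged default tree gives the Emotional, Sensory, Executive
Functioning and Somatic subgroups a catch-all leaf that is counted inside
their nominal breakdowns (7, 2, 14 and 8 leaves); the question bank folds
each subgroup's smallest singleton topic (paranoia, disturbed-by-stimuli,
arithmetic, weight) into its catch-all. Gross motor carries two
generically named leaves (`Coordination`, `Locomotion`). The Generation-1
question manifest allocates 209 placeholder question identifiers across
the 57 leaves; two residual questions beyond the per-leaf topic counts are
assigned to the Social catch-all, the broadest residual category.

## Crosswalk and answer-scale consolidation

A crosswalk holds four sections: the instrument-version registry, the
items (one per source question, identified by a short subject label), the
harmonized question bank, and the mappings. Mapping is many-to-one: every
item maps to exactly one question, and each of its ordinal answer choices
maps to one of the question's answer codes (1 = least severe).

Two rules govern the consolidated scales:

* **Code count = minimum mapped scale size.** If a question receives items
  from instruments with 4, 4, 3, 3 and 4 answer choices, it gets 3 codes:
  a child assessed only with a three-choice instrument must still be able
  to populate every code, and a coarser response cannot be refined into a
  finer one after the fact.
* **Severe-end collapse.** A k-choice source scale maps onto m ≤ k codes
  by sending the m−1 least severe choices one-to-one and collapsing the
  k−m+1 most severe choices onto the top code (so a 4-choice scale maps
  `[1, 2, 3, 3]` onto 3 codes). No default map exists for k < m; an
  explicit map must be supplied. Every map must be monotone
  non-decreasing, and surjective whenever k ≥ m.

Quality-of-behavior scales (clinician protocols) and Likert frequency
scales are both treated as ordinal, ordered least to most severe.

Translation turns a long response table (`child_id, instrument, version,
item, raw`) into a children x questions matrix of codes. When several of a
child's items feed one question, the cell aggregates them under a
configurable policy — maximum severity (default; deterministic, no
fractional codes, preserves the clinical signal), rounded mean, or first
observed. Cells with no contributing item are missing. Translation is
deterministic and invariant to response-row order.

Two reports summarize a crosswalk: a per-leaf fusion table (distinct
instruments, mapped items, resulting questions — instruments counted at
instrument level, not version level) and an instrument-overlap matrix
whose off-diagonal (i, j) counts questions fed by both instruments and
whose diagonal counts questions fed by that instrument alone. Reports are
plain TSV; a heat map can be rendered from the overlap TSV but rendering
is deliberately out of scope.

## Synthetic cohort model

Real multi-source clinical data cannot be redistributed, so the package
ships a generative stand-in with the same structure:

* Each child has a condition label — autism, ADHD or neither — with
  default desk-scale counts 588 / 69 / 89 (n = 750), preserving the
  roughly 8.6 : 1 : 1.3 class imbalance of a realistic referral cohort at
  about one fifth of its size.
* The condition shifts a per-leaf latent severity:
  `theta[i, leaf] = effect[condition, leaf] + Normal(0, noise_sd²)` with
  `noise_sd = 1`. Default effects: autism shifts the social, sensory and
  language/communication leaves by 2.0 latent SD (plus a 0.3 cross-loading
  on the executive-functioning attention leaves); ADHD shifts attention,
  hyperactivity, impulsivity and working-memory leaves by 2.0; the neither
  class is all zeros. The 2.0-SD contrast is deliberately strong: the
  latent classes are nearly separable, so any loss observed downstream is
  attributable to discretization, harmonization and missingness rather
  than to an ambiguous signal.
* Each child is assigned 1–2 instrument versions (weighted sampling
  without replacement), reproducing the little-overlap regime.
* An assigned item with a k-point scale yields
  `raw = 1 + #{cutpoints < theta + Normal(0, item_noise_sd²)}` with
  `item_noise_sd = 0.5` and k−1 equally spaced cut-points over the latent
  interval [0, 3]. Placing the cut-point range above the unaffected
  baseline makes typical children concentrate in the least-severe codes,
  matching the right skew of symptom scales in general-population samples;
  a range symmetric about zero would park half the unaffected children at
  the scale ceiling, an artifact no real instrument shows.

Severity draws, version assignments and response noise come from three
independent streams spawned from one seed, so changing the assignment
settings never perturbs the latent severities. Cohorts are bit-identical
for identical (config, seed).

What the simulator does **not** model: instrument norms and T-scores, real
symptom prevalence, demographic covariates, informant disagreement,
correlated leaf severities beyond the condition effects, or non-random
instrument assignment. Passing tests on this generator demonstrate that
the pipeline machinery recovers a strong planted signal through
harmonization, imputation and classification — not that any particular
clinical accuracy would be achieved on real data.

The synthetic complete crosswalk used by the pipeline spans the packaged
15-version registry with 26 questions over 18 leaves; each question
receives one item from roughly 60% of versions, so instruments overlap
heavily on the bank — the regime the harmonization exists to create.

## Ensemble imputation under coverage constraints

For each question with missing codes, an ensemble of random forests is
grown. Every ensemble member draws a random subset of candidate predictor
features (default subset size uniform on [3, min(20, p−1)]) and uses only
rows with 100% coverage of that subset *in the original observed mask* —
for training (rows that also observe the target feature) and for
inference. Because predictors are always originally observed values,
imputed values never feed later predictions; this avoids the cascading
errors of chained multiple imputation. A draw is discarded when any
labeled class contributes fewer than `min_class_samples` training rows
(default 50), so no imputation is extrapolated from a pool in which a
class is essentially absent. Draws repeat until every target row has
accumulated at least `min_predictions` predictions (default 10); the
accumulated predictions are averaged and clamped to the question's code
range. Rows that never reach the minimum are flagged `failed` and stay
missing.

Design choices worth noting:

* **Anchored draws.** The loop is specified to repeat until every sample
  reaches the prediction minimum, which uniform subset sampling cannot
  guarantee under block missingness: a row with a rare instrument-version
  pattern is almost never fully covered by a uniformly drawn subset. Each
  draw therefore anchors on a row still short of predictions and samples
  the candidate subset from that row's observed features. The training
  rules are unchanged; anchoring only directs the search toward subsets
  that can serve under-covered rows. A per-feature draw cap (default 200)
  still bounds the loop; rows it cannot serve are flagged failed.
* **Regression forests by default.** Final values are means of ensemble
  predictions, so continuous aggregation is natural; classification
  forests (majority-vote codes) are available behind a config flag, and
  rounding of the final mean is optional.
* **Scaling the guard.** The class-size guard of 50 presumes cohorts of
  thousands. Desk-scale runs use proportionally smaller guards (15 for the
  750-child pipeline, 8 for the ~220-child test fixtures); the component
  default remains 50.

Observed cells pass through bit-identical, with per-cell provenance
(observed / imputed / failed) and prediction counts reported alongside the
values.

## Two-stage classification with iterative pruning

Stage 1 (the *gate*) is a gradient-boosted decision-tree classifier for
"any target condition present" (autism or ADHD vs neither); stage 2 (the
*discriminator*) separates autism from ADHD and is trained on the truly
condition-positive rows only. At prediction time the discriminator is
consulted only for rows whose gate probability reaches the threshold
(default 0.5); everything else is labelled neither. Boosting defaults:
depth 3, 200 rounds, learning rate 0.1, histogram tree method, single
thread. Failed-imputation cells remain NaN and are handled natively by
the boosted trees' default-direction splits.

Feature and row selection uses an iterative pruning loop. Each iteration
scores every feature by `1 − normalized_importance × coverage` (importance
averaged over the two stages from a fit on the current state; coverage =
fraction of valid cells after imputation) and every row by its fraction of
failed cells; the single candidate with the highest badness is removed
(ties favour the feature, and a row is never removed if that would break
class stratification). After each removal the objective — by default the
mean of the two stages' pooled cross-validated AUCs — is recomputed; the
loop stops after `prune_patience` non-improving steps (default 3) or when
fewer than two features would remain, and returns the best-scoring state
seen. The recorded trace allows the selection to be audited.

Cross-validation stratifies on the three-way label (default 20 folds;
desk-scale configurations use 5). The gate AUC pools out-of-fold gate
probabilities over all rows; the discriminator AUC pools out-of-fold
discriminator probabilities over the truly positive rows.

## Pipeline and reproducibility

`run_pipeline` chains simulate → translate → impute → prune/cross-validate
→ report, writing every stage artifact (CSV/TSV/JSON) plus a summary. A
single global seed fans out to per-stage seeds via `SeedSequence`
spawning; identical (config, seed) gives byte-identical artifacts. All
randomness flows through `numpy.random.Generator`; forests and boosters
receive integer seeds derived from the stage streams.

Desk-scale problem sizes used by the test suite: the full-pipeline check
runs the 750-child default cohort with 5-fold cross-validation (about half
a minute on one CPU); accuracy and null-distribution properties use
~220-child cohorts over 20 seeds; pruning selectivity uses 160-row
matrices with 5 planted informative and 20 noise features over 20 seeds.

## Known limitations

* The packaged question manifest carries placeholder question identifiers;
  the full harmonized question wordings are an expert product and only a
  30-question case-study list and one worked leaf (adaptability) are
  materialized with subjects.
* Imputation provides no uncertainty intervals; the ensemble spread is
  discarded after averaging.
* The pruning objective recomputes a full cross-validation per removal,
  which is quadratic-ish in matrix size; for matrices beyond a few hundred
  columns a staged or batched removal would be needed.
* Class imbalance is handled implicitly by the rank-based evaluation, not
  by reweighting; gate probabilities are not calibrated.
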