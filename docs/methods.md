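# Methods

This note documents the models, procedures and design choices behind
`vacoder`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the numerical
conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A verbal autopsy (VA) record is a free-text narrative describing the
circumstances of an uncertified death, together with the deceased's age.
The task is twofold: assign each record a cause-of-death (CoD) category
(individual level), and estimate the distribution of causes in the
population (population level). Gold labels come from physician coding of
the same narratives; since physicians themselves disagree on a
substantial fraction of records, no classifier should be expected to
reach perfect agreement, and low-confidence predictions are intended to
be routed to human review rather than accepted blindly.

Records are stratified by age: adult (15–69 years), child (29 days–14
years), neonate (< 29 days). Adults and children share a 15-category
scheme; neonates use a separate 5-category scheme. Ages above 69 years
are outside the study design and are excluded with a warning
(configurable). ICD-10 codes are mapped to categories by longest code
prefix (so a mapping entry `I5` covers `I50.9`), with an exact-match mode
available; an unmapped code raises an explicit error rather than being
silently binned — we deliberately do not guess a fallback category such
as "Ill-defined", because mapping gaps should surface as data problems.

## Preprocessing

The pipeline is: spelling correction → stopword removal → stemming, over
tokens produced by lowercasing and detaching punctuation. Case is folded
*before* correction (the published order corrects first); because lexicon
lookup is case-insensitive the output is unaffected, and it halves the
lexicon. Digit-bearing tokens (dates, doses) are kept whole and never
corrected.

**Spelling correction.** An out-of-lexicon alphabetic token is replaced
by the nearest lexicon entry under optimal-string-alignment (Damerau)
distance, which counts an adjacent transposition as a single edit —
transpositions are a dominant class of transcription errors, and plain
Levenshtein mis-corrects them (`hte` is one OSA edit from `the` but two
Levenshtein edits, closer to `he`). The maximum distance is 2, reduced
to 1 for tokens of at most 4 characters (short tokens admit too many
spurious candidates at distance 2); single characters are never
corrected. Ties are broken by corpus frequency of the candidate, then
lexicographically. Every substitution is logged; a token with no
candidate passes through flagged. The lexicon is a plain text resource
(general English + a hand-written medical term list seeded with common
VA narrative vocabulary) and is intended to be extended with
corpus-specific terms.

**Stopwords.** A fixed 160-entry function-word list, shipped as a
replaceable resource. The published stopword list is not available; ours
is an ordinary English function-word list of the same size.

**Stemming.** A Porter suffix-stripper implemented from the original
algorithm, applied to a fixed point. A single Porter pass is not
idempotent (it maps `houses → hous` and, applied again, `hous → hou`),
which would make repeated preprocessing unstable; iterating to
convergence (≤ 3 passes in practice, capped at 6) makes stemming a
projection. Reference single-pass results like `crying → cry` and
`injuries → injuri` are already fixed points and unchanged.

## Features and selection

Records are represented by raw integer word-frequency counts over a
vocabulary built from training data only, ordered by document frequency
then lexicographically (deterministic rebuilds). No tf·idf and no
scaling by default: counts are what the classifiers consume; an optional
normalization exists for margin/gradient models but is off by default.
The age group enters as one logical feature encoded as three one-hot
columns (no ordinal relation), always retained by selection.

Features are ranked by the one-way ANOVA F statistic

F = [Σ_g n_g (x̄_g − x̄)² / (G−1)] / [Σ_g Σ_i (x_{gi} − x̄_g)² / (n−G)],

computed per column over the CoD categories. Degenerate conventions: zero
within-class variance with differing class means → F = +∞ (a perfect
separator, ranked first); an all-constant column → F = 0 (ranked last).
Ties prefer the lower column index. `select_top_k` keeps the k−1
highest-F vocabulary columns plus the age block. The per-family defaults
(200 / 414 / 378 / 398 features) are the published optimized values; on
corpora with fewer columns than k, everything is kept with a warning.

## Classifiers

All four families expose per-record confidence vectors that are
non-negative and sum to one; ties in the argmax resolve to the lower
category index. Feature selection happens inside `train`, on training
data only, and the fitted model records the selected column names so
prediction can never silently misalign columns.

* **Naive Bayes** — multinomial event model with add-one smoothing
  (counts as features). On a two-feature toy with 90/10 versus 10/90
  counts the posterior is 91/102 ≈ 0.892, which the tests verify against
  the hand computation.
* **Random forest** — 26 trees (the published optimum), unlimited depth,
  √V feature subsampling, seeded bootstrap.
* **SVM** — an aggregate of one-vs-rest linear-kernel SVMs; confidence is
  a softmax over the one-vs-rest decision values (the study does not
  state its procedure; softmax preserves the decision ranking, so top-1
  predictions are unaffected by this choice).
* **Feed-forward network** — one hidden layer of 297 ReLU units, softmax
  output, cross-entropy loss, first-order mini-batch optimization with
  early stopping on a 10% validation slice, fixed seed. If a training
  set contains a singleton class the stratified early-stopping split is
  impossible and early stopping is disabled for that fit (logged).

Hyperparameter search is a seeded random search with a fixed budget
(default 100 evaluations, matching the published protocol) over the
feature count and one family parameter each (NB smoothing, tree count,
SVM C, hidden width), scored by support-weighted validation sensitivity;
failed trials score −∞ and remain in the trial log.

## Metrics

Individual level: precision, sensitivity and F1 are computed from the
confusion table; the default aggregation is support-weighted (macro and
micro available, and per-category values are always reported). Top-k
concordance is the fraction of records whose true category is in the
top-k ranking; PCCC = (C − k/N)/(1 − k/N) with k = 1 by default, since a
single CoD is assigned per death.

Population level: CSMF accuracy as defined in the README. The degenerate
case of a truth concentrated on a single category (denominator zero) is
defined as 1 when the prediction is identical and is an error otherwise.

**Chance correction.** CCCSMFA = (CSMFA − c)/(1 − c). Two Monte-Carlo
nulls for c are provided because they answer different questions:

* `dataset_null` (default for scoring runs): each evaluated record is
  assigned a category uniformly at random; CSMFA is scored against the
  fixed observed truth; c is the mean over iterations. This is the
  "random assignment on this dataset" chance level and depends on the
  test-set size and its CoD distribution.
* `dirichlet_null`: the true CSMF is drawn uniformly from the simplex
  and scored against the uniform prediction; as the number of causes
  grows the mean approaches 1 − 1/e ≈ 0.632 (the acceptance script
  verifies 0.632 ± 0.005 with 1000 causes and 10,000 iterations).

An important caveat, demonstrated in the test suite: CCCSMFA is zero for
a *uniform random assigner*, not for every uninformative classifier. A
model fitted to label-shuffled data still learns the label marginal; one
that spreads predictions like the training prior scores CSMFA near the
prior-matching level (well above the uniform-assignment chance mean,
hence CCCSMFA > 0), while one that collapses to the majority class
scores far below it. Individual-level metrics (PCCC) are the reliable
no-information check; population-level chance correction rewards
prior-matching by construction.

## Cross-validation harness

Folds are drawn uniformly at random within each age group (no
stratification by CoD; a deliberately unbalanced test set would not be a
rigorous evaluation, and rare categories make re-balancing impractical).
Adult and child training folds are augmented with *all* records of the
other two age groups — including neonates, whose labels come from the
other scheme; at prediction time the ranking is restricted to the test
age group's scheme categories and renormalized, so out-of-scheme
confidence mass is discarded. Vocabulary and ANOVA selection are fitted
per fold on training records only (the leakage-guard tests verify that
deleting test-fold records changes nothing in the trained model);
preprocessing resources are global constants, since lexicons and
stopword lists are not label-derived. When a category is absent from a
training fold the model cannot predict it; the report footnotes such
folds instead of resampling. Every reported mean is the arithmetic mean
of exactly k fold values; chance baselines are recomputed per fold from
the fold's true labels.

## Synthetic corpora

The generator emulates the structural properties of transcribed VA
narratives: short English free text in a small set of
category-independent templates; content words drawn from a
class-conditional symptom lexicon mixed with background vocabulary
(mixture weight λ); per-token misspelling injection at rate ρ by one
random edit (substitute/delete/insert/transpose, uniform over types);
three age strata with skewed CoD distributions (default largest adult
category 0.30, smallest 0.015; neonatal largest 0.35); narrative length
Poisson-distributed content (mean 9 tokens, clipped to [4, 25]) plus the
template. Defaults: λ = 0.3, ρ = 0.05, 1000/200/100 records per
adult/child/neonate stratum. Everything is seeded and the manifest
suffices to regenerate a corpus bit-identically.

What it does *not* emulate: translation artifacts, grammatical
inconsistency beyond templating, multi-cause deaths, narrative length
correlated with cause, chronology and negation, or respondent-reported
cause guesses. Consequently, passing tests on synthetic corpora show
that the pipeline recovers vocabulary-borne signal under controlled
noise — they say nothing about accuracy on real narratives, whose signal
structure is far messier. The separable-recovery tests use
pairwise-disjoint pseudo-word lexicons (disjoint also after stemming) so
that perfect recovery is guaranteed by construction; the realistic
default lexicons deliberately overlap across related causes.

## Problem sizes and numerical conventions

The test suite and acceptance checks run on one CPU with deliberately
modest sizes, chosen as the smallest scales at which the tested
properties are stable: the cross-validated recovery check uses 2000
adult records with 10-fold cross-validation and all four families;
Monte-Carlo chance means use 10,000 iterations; ANOVA oracle checks use
random matrices up to 10×10 at 1e-10 relative tolerance; confidence
normalization is asserted to 1e-9. Floating-point guards: within-class
sums of squares are clamped at zero against cancellation, and the
zero-variance conventions above avoid 0/0. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; derived seeds
stay below 2³¹.

## Known limitations

* The stopword list and medical lexicon are stand-ins of the documented
  size and kind, not the original (unpublished) resources.
* The ICD-10 → category mapping table must be user-supplied; only the
  category lists ship built-in.
* SVM confidences are softmax-rescaled margins, not calibrated
  probabilities; treat review-queue thresholds on them as ordinal.
* The feed-forward network is the most seed- and size-sensitive family
  on small corpora, and is the slowest to train.
* Population-level chance correction has the prior-matching caveat
  described above; report PCCC alongside CCCSMFA.
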