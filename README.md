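# vacoder

Cause-of-death coding from verbal-autopsy free-text narratives.

Two-thirds of the world's deaths occur without medical certification. A
verbal autopsy (VA) — a structured interview with a family member,
including a free-text narrative of the events preceding the death — is the
standard instrument for estimating what people die of in such settings.
Narratives are usually coded by pairs of physicians; `vacoder` implements
an automated alternative that assigns a cause-of-death (CoD) category to
each record using *only* the narrative, plus the machinery needed to
evaluate such a system the way the VA literature does. It is intended for
researchers in epidemiology and global health who want to train, evaluate,
or stress-test narrative-based CoD classifiers.

## What it does

* **Preprocessing** — spelling correction against an English + custom
  medical lexicon (edit distance ≤ 2, transposition counted as one edit),
  lowercasing and punctuation separation, removal of a 160-word stopword
  list, and Porter stemming (`crying → cry`).
* **Features** — raw word-frequency counts over a training-set vocabulary
  plus an age-group indicator (adult 15–69 y / child 29 d–14 y / neonate
  < 29 d), ranked by the one-way ANOVA F statistic; only the top-k
  features are kept.
* **Classifiers** — four families with per-category confidences: naive
  Bayes (200 features), random forest (414 features, 26 trees),
  one-vs-rest linear SVM (378 features), and a one-hidden-layer ReLU
  feed-forward network (297 units, 398 features); plus a seeded 100-trial
  random search over family parameters and the feature count.
* **Metrics** — individual level: precision, sensitivity, F1 and partial
  chance-corrected concordance,

      PCCC = (C − k/N) / (1 − k/N),

  with C the top-k concordance and N the number of categories; population
  level: cause-specific mortality fractions (CSMF), CSMF accuracy

      CSMFA = 1 − Σⱼ |predⱼ − trueⱼ| / (2 (1 − minⱼ trueⱼ)),

  and chance-corrected CSMF accuracy

      CCCSMFA = (CSMFA − c) / (1 − c),

  where the chance mean c is estimated by Monte Carlo (10,000 iterations);
  under the uniform-simplex null c → 1 − 1/e ≈ 0.632 as the number of
  causes grows.
* **Evaluation harness** — 10-fold cross-validation with the VA-specific
  training augmentation (adult and child training folds receive all
  records of the other two age groups; neonates train alone because they
  use a separate 5-category scheme), fold-fitted vocabulary and feature
  selection, and per-age-group reporting.
* **Synthetic corpora** — a seeded generator of VA-like narratives with
  class-conditional symptom vocabularies, background vocabulary,
  misspelling injection and skewed CoD distributions, standing in for the
  physician-coded corpora, which are not publicly available.

The built-in category scheme has 15 adult/child categories and 5 neonatal
categories; ICD-10 → category mapping tables are supplied by the user as
two-column CSV files and matched by longest code prefix.

## Worked example

```python
import vacoder as vc

for n_causes in (5, 15, 1000):
    b = vc.chance_csmfa("dirichlet_null", n_categories=n_causes,
                        iterations=10_000, seed=1)
    print(f"{n_causes:>4} causes: mean chance CSMFA = {b.mean:.3f}")
print(f"adult RF: CCCSMFA = {vc.cccsmfa(0.948, 0.643):+.3f}")
```

prints

```
   5 causes: mean chance CSMFA = 0.661
  15 causes: mean chance CSMFA = 0.644
1000 causes: mean chance CSMFA = 0.632
adult RF: CCCSMFA = +0.854
```

A predictor that assigns causes at random still reaches CSMF accuracy
around 0.63–0.66 — which is why population-level scores must be chance
corrected: a CSMF accuracy of 0.948 against an adult chance mean of 0.643
corresponds to a chance-corrected score of 0.854, on a scale where 0 is
chance and 1 is perfect agreement.

The `examples/` directory contains one short script per capability:
`preprocess_narrative.py`, `generate_synthetic_corpus.py`,
`evaluate_classifiers.py`, `chance_baselines.py`, `review_queue.py`; each
prints what it computes and what the numbers mean. A thin CLI (`vacoder
preprocess|simulate|train|evaluate|chance`) wraps the same library calls.

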