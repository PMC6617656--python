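"""10-fold cross-validated evaluation with age-group training augmentation.

Folds are drawn uniformly at random within each age group (no stratification
by cause — matching a study design that declined distribution re-balancing).
For adult and child test folds the training set is augmented with *all*
records of the other two age groups; neonatal models are trained on
neonatal records only, because neonates use a different category scheme.

Per fold, the vocabulary and the ANOVA feature ranking are fitted on the
training records only (no test-set leakage); preprocessing resources
(lexicon, stopwords) are global constants.  Reported scores are arithmetic
means over the k fold values, per age group and per classifier family.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import metrics as vm
from .features import build_feature_matrix, build_vocabulary
from .models import FAMILIES, ModelConfig, TrainedClassifier, train
from .records import AGE_GROUPS, CoDScheme, VARecord, split_by_age_group
from .textprep import Lexicon, StopwordList, preprocess_corpus, resources_hash

logger = logging.getLogger(__name__)

METRIC_NAMES = ("precision", "sensitivity", "f1", "pccc", "csmfa", "cccsmfa")


@dataclass
class FoldPlan:
    """Disjoint per-age-group test-set partitions for k-fold cross-validation."""

    k: int
    seed: int
    test_ids: dict[str, list[set[str]]]  # age_group -> k disjoint id sets

    def test_set(self, age_group: str, fold: int) -> set[str]:
        return self.test_ids[age_group][fold]


def make_folds(
    records: Sequence[VARecord], k: int = 10, seed: int = 0
) -> FoldPlan:
    """Uniform random partition of each age group into k folds.

    Fold sizes within a group differ by at most one.  An age group with
    fewer than k records (but more than zero) is an error; absent groups
    are simply skipped.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    by_group = split_by_age_group(records)
    test_ids: dict[str, list[set[str]]] = {}
    for group in AGE_GROUPS:
        members = [r.record_id for r in by_group[group]]
        if not members:
            continue
        if len(members) < k:
            raise ValueError(
                f"age group {group!r} has {len(members)} records, fewer than "
                f"k={k}; use a smaller k"
            )
        order = rng.permutation(len(members))
        folds = np.array_split(order, k)
        test_ids[group] = [set(members[i] for i in f) for f in folds]
    return FoldPlan(k=k, seed=seed, test_ids=test_ids)


def assemble_training(
    plan: FoldPlan,
    fold: int,
    age_group: str,
    records: Sequence[VARecord],
) -> list[VARecord]:
    """Training records for one fold of one age group.

    Adult/child: own-group non-test records plus all records of the other
    two age groups.  Neonate: own-group non-test records only.  The test
    set is never touched.
    """
    test = plan.test_set(age_group, fold)
    out: list[VARecord] = []
    for r in records:
        if r.record_id in test:
            continue
        if r.age_group == age_group:
            out.append(r)
        elif age_group in ("adult", "child"):
            out.append(r)
    return out


@dataclass
class EvalReport:
    """Cross-validated scores per age group and classifier family.

    ``folds[group][family]`` is a list of k per-fold metric dicts; the
    reported mean of any metric is the arithmetic mean of exactly those k
    values.  ``notes`` records folds whose training set lacked a scheme
    category (such folds cannot predict that category).
    """

    k: int
    seed: int
    families: tuple[str, ...]
    folds: dict[str, dict[str, list[dict[str, float]]]]
    chance_means: dict[str, list[float]]
    resource_hash: str
    notes: list[str] = field(default_factory=list)

    @property
    def age_groups(self) -> tuple[str, ...]:
        return tuple(self.folds)

    def fold_values(self, age_group: str, family: str, metric: str) -> list[float]:
        return [f[metric] for f in self.folds[age_group][family]]

    def mean(self, age_group: str, family: str, metric: str) -> float:
        return float(np.mean(self.fold_values(age_group, family, metric)))

    def sd(self, age_group: str, family: str, metric: str) -> float:
        return float(np.std(self.fold_values(age_group, family, metric), ddof=1))

    def summary(self) -> dict:
        """Table-shaped grid: age group x family x metric -> mean and sd."""
        return {
            group: {
                family: {
                    m: {
                        "mean": self.mean(group, family, m),
                        "sd": self.sd(group, family, m),
                    }
                    for m in METRIC_NAMES
                }
                for family in self.families
            }
            for group in self.age_groups
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "schema_version": 1,
                    "k": self.k,
                    "seed": self.seed,
                    "families": list(self.families),
                    "summary": self.summary(),
                    "folds": self.folds,
                    "chance_means": self.chance_means,
                    "resource_hash": self.resource_hash,
                    "notes": self.notes,
                },
                indent=1,
            )
        )


def _restricted_ranking(
    model: TrainedClassifier, matrix, categories: Sequence[str]
) -> list[list[tuple[str, float]]]:
    """Rank only the test age group's scheme categories, renormalized.

    Augmented training sets can contain out-of-scheme labels (e.g. neonatal
    categories in an adult training set); confidence mass on those is
    dropped and the remainder renormalized.
    """
    proba = model.confidence_matrix(matrix)
    cols = [
        (j, c) for j, c in enumerate(model.categories) if c in set(categories)
    ]
    if not cols:
        raise ValueError("model shares no categories with the evaluation scheme")
    idx = [j for j, _ in cols]
    names = [c for _, c in cols]
    sub = proba[:, idx]
    sub = sub / np.maximum(sub.sum(axis=1, keepdims=True), 1e-300)
    out = []
    for row in sub:
        order = np.argsort(-row, kind="stable")
        out.append([(names[j], float(row[j])) for j in order])
    return out


def run_experiment(
    records: Sequence[VARecord],
    scheme: CoDScheme,
    families: Sequence[str] = FAMILIES,
    k: int = 10,
    seed: int = 0,
    model_configs: Mapping[str, ModelConfig] | None = None,
    lexicon: Lexicon | None = None,
    stopwords: StopwordList | None = None,
    chance_mode: str = "dataset_null",
    chance_iterations: int = 10_000,
    min_df: int = 1,
) -> EvalReport:
    """Cross-validated evaluation of the requested classifier families.

    Every record must carry a gold category valid for its age group.
    Deterministic for fixed seeds and resources.
    """
    records = list(records)
    for r in records:
        if r.category is None:
            raise ValueError(f"record {r.record_id!r} has no gold category")
        if r.category not in scheme.categories(r.age_group):
            raise ValueError(
                f"record {r.record_id!r}: category {r.category!r} not in the "
                f"{r.age_group} scheme"
            )
    families = tuple(families)
    for f in families:
        if f not in FAMILIES:
            raise ValueError(f"unknown family {f!r}")

    lexicon = lexicon or Lexicon.default()
    stopwords = stopwords or StopwordList.default()
    res_hash = resources_hash(lexicon, stopwords)

    docs = preprocess_corpus(records, lexicon, stopwords)
    doc_of = {d.record_id: d for d in docs}
    rec_of = {r.record_id: r for r in records}

    plan = make_folds(records, k=k, seed=seed)
    folds: dict[str, dict[str, list[dict[str, float]]]] = {
        g: {f: [] for f in families} for g in plan.test_ids
    }
    chance_means: dict[str, list[float]] = {g: [] for g in plan.test_ids}
    notes: list[str] = []

    for group in plan.test_ids:
        categories = scheme.categories(group)
        for fold in range(k):
            test_ids = sorted(plan.test_set(group, fold))
            train_records = assemble_training(plan, fold, group, records)
            train_docs = [doc_of[r.record_id] for r in train_records]
            vocab = build_vocabulary(train_docs, min_df=min_df)
            X_train = build_feature_matrix(
                train_docs, vocab, [r.age_group for r in train_records]
            )
            y_train = [r.category for r in train_records]
            test_docs = [doc_of[i] for i in test_ids]
            X_test = build_feature_matrix(
                test_docs, vocab, [rec_of[i].age_group for i in test_ids]
            )
            y_test = [rec_of[i].category for i in test_ids]

            missing = sorted(set(categories) - set(y_train))
            if missing:
                notes.append(
                    f"{group} fold {fold}: categories absent from training: {missing}"
                )

            baseline = vm.chance_csmfa(
                mode=chance_mode,
                true_labels=y_test,
                categories=categories,
                n_categories=len(categories),
                iterations=chance_iterations,
                seed=seed * 1009 + fold,
            )
            chance_means[group].append(baseline.mean)
            true_csmf = vm.csmf(y_test, categories)

            for family in families:
                if model_configs and family in model_configs:
                    config = model_configs[family]
                else:
                    config = ModelConfig(family=family, seed=seed)
                model = train(config, X_train, y_train)
                ranked = _restricted_ranking(model, X_test, categories)
                y_pred = [r[0][0] for r in ranked]
                table = vm.confusion_table(y_test, y_pred, categories)
                precision, sensitivity, f1 = vm.prf(table, averaging="weighted")
                conc = vm.concordance(y_test, [[c for c, _ in r] for r in ranked], k=1)
                pccc_val = vm.pccc(conc, len(categories), k=1)
                csmfa_val = vm.csmf_accuracy(true_csmf, vm.csmf(y_pred, categories))
                folds[group][family].append(
                    {
                        "precision": precision,
                        "sensitivity": sensitivity,
                        "f1": f1,
                        "concordance": conc,
                        "pccc": pccc_val,
                        "csmfa": csmfa_val,
                        "cccsmfa": vm.cccsmfa(csmfa_val, baseline.mean),
                        "n_test": len(y_test),
                    }
                )
            logger.info("%s fold %d/%d scored (n_test=%d)", group, fold + 1, k, len(test_ids))

    return EvalReport(
        k=k,
        seed=seed,
        families=families,
        folds=folds,
        chance_means=chance_means,
        resource_hash=res_hash,
        notes=notes,
    )


def flag_low_confidence(
    predictions: Sequence[tuple[str, Sequence[tuple[str, float]]]],
    threshold: float,
) -> list[tuple[str, str, float]]:
    """Records whose top-1 confidence falls below ``threshold``.

    ``predictions`` holds (record_id, ranked (category, confidence) list)
    pairs.  Returns (record_id, top category, confidence) triples sorted by
    ascending confidence — the review queue, least certain first.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    flagged = []
    for record_id, ranked in predictions:
        if not ranked:
            raise ValueError(f"record {record_id!r} has no ranked predictions")
        top_cat, top_conf = ranked[0]
        if top_conf < threshold:
            flagged.append((record_id, top_cat, float(top_conf)))
    flagged.sort(key=lambda item: item[2])
    return flagged
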