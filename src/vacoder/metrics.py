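"""Individual- and population-level evaluation metrics for VA cause-of-death coding.

Individual level: precision, sensitivity (recall), F1, top-k concordance
and partial chance-corrected concordance (PCCC).  Population level:
cause-specific mortality fractions (CSMF), CSMF accuracy, and
chance-corrected CSMF accuracy (CCCSMFA).

CSMF accuracy is one minus the total absolute CSMF error normalized by its
maximum possible value::

    CSMFA = 1 - sum_j |pred_j - true_j| / (2 (1 - min_j true_j))

Random category assignment already yields CSMFA well above zero, so
CCCSMFA rescales it against the mean chance value c::

    CCCSMFA = (CSMFA - c) / (1 - c)

giving 0 at chance and negative values below chance.  The chance mean c is
estimated by Monte Carlo under one of two nulls (see :func:`chance_csmfa`);
the asymptotic value under the uninformative-simplex null is
1 - 1/e ~ 0.632.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionTable",
    "confusion_table",
    "prf",
    "concordance",
    "pccc",
    "csmf",
    "csmf_accuracy",
    "ChanceBaseline",
    "chance_csmfa",
    "cccsmfa",
]


@dataclass
class ConfusionTable:
    """Square category-by-category count matrix; rows = true, columns = predicted."""

    counts: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.categories)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts must be {n}x{n} for {n} categories, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_table(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    categories: Sequence[str],
) -> ConfusionTable:
    """Tally a confusion table over a fixed ordered category list."""
    categories = tuple(categories)
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels, strict=True):
        if t not in index:
            raise ValueError(f"true label {t!r} outside the category list")
        if p not in index:
            raise ValueError(f"predicted label {p!r} outside the category list")
        counts[index[t], index[p]] += 1
    return ConfusionTable(counts=counts, categories=categories)


def prf(
    table: ConfusionTable, averaging: str = "weighted"
) -> tuple[float, float, float]:
    """Aggregate precision, sensitivity and F1 from a confusion table.

    Per category: precision = TP/(TP+FP), sensitivity = TP/(TP+FN),
    F1 = 2PR/(P+R).  ``averaging`` is ``weighted`` (by true support, the
    default), ``macro`` (unweighted mean) or ``micro`` (pooled counts).
    Categories with zero support contribute 0 and trigger a warning.
    """
    if table.total == 0:
        raise ValueError("empty confusion table")
    C = table.counts.astype(float)
    tp = np.diag(C)
    support = C.sum(axis=1)  # true counts per category (TP+FN)
    predicted = C.sum(axis=0)  # predicted counts per category (TP+FP)
    if (support == 0).any():
        missing = [c for c, s in zip(table.categories, support) if s == 0]
        warnings.warn(f"categories with zero support: {missing}")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        sensitivity = np.where(support > 0, tp / support, 0.0)
        denom = precision + sensitivity
        f1 = np.where(denom > 0, 2 * precision * sensitivity / denom, 0.0)
    if averaging == "micro":
        p = r = float(tp.sum() / C.sum())
        return p, r, p
    if averaging == "macro":
        weights = np.full(len(tp), 1.0 / len(tp))
    elif averaging == "weighted":
        weights = support / support.sum()
    else:
        raise ValueError(f"averaging must be weighted|macro|micro, got {averaging!r}")
    return (
        float(precision @ weights),
        float(sensitivity @ weights),
        float(f1 @ weights),
    )


def per_category_prf(table: ConfusionTable) -> dict[str, dict[str, float]]:
    """Per-category precision/sensitivity/F1, keyed by category name."""
    C = table.counts.astype(float)
    tp = np.diag(C)
    support = C.sum(axis=1)
    predicted = C.sum(axis=0)
    out: dict[str, dict[str, float]] = {}
    for i, cat in enumerate(table.categories):
        p = tp[i] / predicted[i] if predicted[i] else 0.0
        r = tp[i] / support[i] if support[i] else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        out[cat] = {
            "precision": float(p),
            "sensitivity": float(r),
            "f1": float(f),
            "support": int(support[i]),
        }
    return out


def concordance(
    true_labels: Sequence[str],
    ranked_predictions: Sequence[Sequence[str]],
    k: int = 1,
) -> float:
    """Fraction of records whose true category is among the top-k predictions."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    hits = 0
    for t, ranking in zip(true_labels, ranked_predictions, strict=True):
        if len(ranking) < k:
            raise ValueError(
                f"record has only {len(ranking)} ranked predictions, need {k}"
            )
        if t in list(ranking)[:k]:
            hits += 1
    return hits / len(true_labels)


def pccc(C: float, n_categories: int, k: int = 1) -> float:
    """Partial chance-corrected concordance: (C - k/N) / (1 - k/N).

    Rescales top-k concordance so that uniform random guessing scores 0;
    may be negative for below-chance performance.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n_categories <= k:
        raise ValueError(f"need more categories ({n_categories}) than k ({k})")
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"concordance must be in [0,1], got {C}")
    chance = k / n_categories
    return (C - chance) / (1.0 - chance)


def csmf(labels: Sequence[str], categories: Sequence[str]) -> np.ndarray:
    """Cause-specific mortality fractions over the full ordered category list."""
    if len(labels) == 0:
        raise ValueError("need at least one label")
    categories = tuple(categories)
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros(len(categories), dtype=float)
    for lab in labels:
        if lab not in index:
            raise ValueError(f"label {lab!r} outside the category list")
        counts[index[lab]] += 1
    return counts / counts.sum()


def csmf_accuracy(true_csmf: np.ndarray, pred_csmf: np.ndarray) -> float:
    """CSMF accuracy: 1 - sum|pred - true| / (2 (1 - min true)).

    Requires aligned category vectors.  The degenerate case min(true) = 1
    (a single observed category) is defined as 1.0 when the prediction is
    identical and is an error otherwise.
    """
    t = np.asarray(true_csmf, dtype=float)
    p = np.asarray(pred_csmf, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"mismatched category lists: {t.shape} vs {p.shape}")
    for name, v in (("true", t), ("pred", p)):
        if (v < -1e-9).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} CSMF must be a probability vector")
    denom = 2.0 * (1.0 - t.min())
    if denom <= 0:
        if np.allclose(t, p, atol=1e-12):
            warnings.warn("degenerate CSMF comparison: single observed category")
            return 1.0
        raise ValueError(
            "CSMF accuracy undefined: true distribution concentrated on one "
            "category but prediction differs"
        )
    return float(1.0 - np.abs(p - t).sum() / denom)


@dataclass
class ChanceBaseline:
    """A Monte-Carlo estimate of the mean chance-level CSMF accuracy.

    ``dataset_null`` assigns each evaluated record a category uniformly at
    random and scores against the fixed observed true distribution — the
    "randomly assigning CoD categories" null, specific to a dataset.
    ``dirichlet_null`` draws the true CSMF uniformly from the probability
    simplex and scores the uniform prediction — the distribution-free null
    whose mean approaches 1 - 1/e ~ 0.632 as the number of causes grows.
    """

    mode: str
    n_categories: int
    iterations: int
    seed: int
    mean: float


def chance_csmfa(
    mode: str = "dataset_null",
    true_labels: Sequence[str] | None = None,
    categories: Sequence[str] | None = None,
    n_categories: int | None = None,
    iterations: int = 10_000,
    seed: int = 0,
) -> ChanceBaseline:
    """Estimate the mean chance CSMF accuracy by Monte Carlo.

    ``dataset_null`` requires ``true_labels`` and ``categories``;
    ``dirichlet_null`` requires only ``n_categories``.  Both are seeded and
    reproducible.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "dataset_null":
        if true_labels is None or categories is None:
            raise ValueError("dataset_null requires true_labels and categories")
        categories = tuple(categories)
        N = len(categories)
        if N < 2:
            raise ValueError("need at least 2 categories")
        t = csmf(true_labels, categories)
        n = len(true_labels)
        denom = 2.0 * (1.0 - t.min())
        # per iteration: uniform random assignment of each record
        draws = rng.multinomial(n, np.full(N, 1.0 / N), size=iterations) / n
        accs = 1.0 - np.abs(draws - t).sum(axis=1) / denom
        mean = float(accs.mean())
    elif mode == "dirichlet_null":
        if n_categories is None:
            raise ValueError("dirichlet_null requires n_categories")
        N = int(n_categories)
        if N < 2:
            raise ValueError("need at least 2 categories")
        t = rng.dirichlet(np.ones(N), size=iterations)
        p = np.full(N, 1.0 / N)
        denom = 2.0 * (1.0 - t.min(axis=1))
        accs = 1.0 - np.abs(p[None, :] - t).sum(axis=1) / denom
        mean = float(accs.mean())
    else:
        raise ValueError(f"mode must be dataset_null|dirichlet_null, got {mode!r}")
    if not 0.0 < mean < 1.0:
        raise RuntimeError(f"estimated chance mean {mean} outside (0,1)")
    return ChanceBaseline(
        mode=mode, n_categories=N, iterations=iterations, seed=seed, mean=mean
    )


def cccsmfa(csmfa: float, c: float) -> float:
    """Chance-corrected CSMF accuracy: (CSMFA - c) / (1 - c)."""
    if not 0.0 < c < 1.0:
        raise ValueError(f"chance mean must be in (0,1), got {c}")
    return (csmfa - c) / (1.0 - c)
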