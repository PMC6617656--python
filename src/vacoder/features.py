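"""Bag-of-words features with an age-group indicator, and ANOVA feature selection.

Each record is represented by raw word-frequency counts over a vocabulary
built from training data, plus one logical age feature (one-hot over
adult/child/neonate, so no ordinal relation is imposed).  Features are
ranked by the one-way ANOVA F statistic — the ratio of between-category to
within-category variance of the feature — and only the top-k are kept,
which in the study reduced >4000 stems to a few hundred columns.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .records import AGE_GROUPS
from .textprep import TokenizedNarrative

logger = logging.getLogger(__name__)

#: Column names of the always-retained age-indicator block.
AGE_COLUMNS = tuple(f"__age_{g}__" for g in AGE_GROUPS)


@dataclass
class Vocabulary:
    """Ordered stem list with dense column indices, built from training data only.

    Ordering is (document frequency descending, then lexicographic), which
    makes vocabulary construction deterministic.
    """

    stems: tuple[str, ...]
    doc_freq: dict[str, int]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.stems)}

    def __len__(self) -> int:
        return len(self.stems)

    def __contains__(self, stem: str) -> bool:
        return stem in self.index


def build_vocabulary(
    corpus: Sequence[TokenizedNarrative], min_df: int = 1
) -> Vocabulary:
    """Collect unique stems with document frequency >= ``min_df``."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    df: Counter[str] = Counter()
    for doc in corpus:
        df.update(set(doc.tokens))
    kept = [(s, n) for s, n in df.items() if n >= min_df]
    kept.sort(key=lambda item: (-item[1], item[0]))
    vocab = Vocabulary(stems=tuple(s for s, _ in kept), doc_freq=dict(kept))
    logger.info("vocabulary: %d stems (min_df=%d)", len(vocab), min_df)
    return vocab


@dataclass
class FeatureMatrix:
    """Records x (vocabulary counts + age one-hot) with aligned row ids.

    ``X`` is a sparse CSR matrix of non-negative integers; the final three
    columns are the age indicator (see :data:`AGE_COLUMNS`).
    """

    X: sp.csr_matrix
    record_ids: tuple[str, ...]
    column_names: tuple[str, ...]
    vocabulary: Vocabulary

    @property
    def n_vocab_columns(self) -> int:
        return len(self.column_names) - len(AGE_COLUMNS)

    def subset(self, column_indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(column_indices, dtype=int)
        return FeatureMatrix(
            X=self.X[:, idx].tocsr(),
            record_ids=self.record_ids,
            column_names=tuple(self.column_names[i] for i in idx),
            vocabulary=self.vocabulary,
        )


def count_features(
    doc: TokenizedNarrative, vocab: Vocabulary, age_group: str
) -> np.ndarray:
    """Dense feature row for one record: stem counts + age one-hot.

    Out-of-vocabulary stems are ignored.
    """
    row = np.zeros(len(vocab) + len(AGE_COLUMNS), dtype=np.int64)
    for token in doc.tokens:
        j = vocab.index.get(token)
        if j is not None:
            row[j] += 1
    row[len(vocab) + AGE_GROUPS.index(age_group)] = 1
    return row


def build_feature_matrix(
    corpus: Sequence[TokenizedNarrative],
    vocab: Vocabulary,
    age_groups: Sequence[str],
) -> FeatureMatrix:
    """Assemble the sparse records-by-features matrix in corpus order."""
    if len(corpus) != len(age_groups):
        raise ValueError("corpus and age_groups must align")
    V = len(vocab)
    rows, cols, vals = [], [], []
    for i, (doc, group) in enumerate(zip(corpus, age_groups)):
        counts = Counter(doc.tokens)
        for token, n in counts.items():
            j = vocab.index.get(token)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(n)
        rows.append(i)
        cols.append(V + AGE_GROUPS.index(group))
        vals.append(1)
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(corpus), V + len(AGE_COLUMNS)), dtype=np.int64
    )
    return FeatureMatrix(
        X=X,
        record_ids=tuple(d.record_id for d in corpus),
        column_names=tuple(vocab.stems) + AGE_COLUMNS,
        vocabulary=vocab,
    )


def anova_f(X, labels: Sequence) -> np.ndarray:
    """One-way ANOVA F statistic per column.

    F = [sum_g n_g (xbar_g - xbar)^2 / (G-1)] / [sum_g sum_i (x_gi - xbar_g)^2 / (n-G)]

    Degenerate cases: zero within-group variance with differing group means
    gives ``+inf`` (such a column separates categories perfectly and ranks
    first); an all-constant column gives 0 (ranks last).
    """
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    G = len(classes)
    n = len(labels)
    if G < 2:
        raise ValueError("ANOVA requires at least 2 categories")
    X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), y)), shape=(n, G)
    )  # n x G membership
    n_g = np.asarray(Z.sum(axis=0)).ravel()  # per-class sizes
    if sp.issparse(X):
        sum_g = np.asarray((Z.T @ X).todense(), dtype=float)  # G x V
        sumsq_g = np.asarray((Z.T @ X.multiply(X)).todense(), dtype=float)
    else:
        sum_g = Z.T @ X
        sumsq_g = Z.T @ (X * X)
    mean_g = sum_g / n_g[:, None]
    grand_mean = sum_g.sum(axis=0) / n
    ss_between = (n_g[:, None] * (mean_g - grand_mean) ** 2).sum(axis=0)
    ss_within = (sumsq_g - n_g[:, None] * mean_g**2).sum(axis=0)
    ss_within = np.maximum(ss_within, 0.0)  # guard FP cancellation

    scale = np.maximum(sumsq_g.sum(axis=0), 1.0)
    tiny = 1e-12 * scale
    ms_between = ss_between / (G - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_within = ss_within / (n - G)  # n == G leaves zero within-group df
        F = ms_between / ms_within
    F = np.where(ss_within <= tiny, np.where(ss_between > tiny, np.inf, 0.0), F)
    return np.asarray(F, dtype=float)


def top_k_columns(f_values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` highest F values, ties toward the lower index."""
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    f_values = np.asarray(f_values, dtype=float)
    order = np.argsort(-f_values, kind="stable")
    return np.sort(order[: min(k, len(f_values))])


@dataclass
class FeatureRanking:
    """Per-column F values and the selected column index set."""

    f_values: np.ndarray
    selected: tuple[int, ...]
    selected_names: tuple[str, ...]


def select_top_k(
    matrix: FeatureMatrix, labels: Sequence, k: int
) -> tuple[FeatureRanking, FeatureMatrix]:
    """Keep the ``k`` logical features with the highest F values.

    The age one-hot block counts as one logical feature and is always
    retained, so the top ``k - 1`` vocabulary columns are selected.  Ties
    are broken toward the lower column index.  ``k`` larger than the number
    of available features keeps everything (with a warning).
    """
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    V = matrix.n_vocab_columns
    F = anova_f(matrix.X, labels)
    n_vocab_keep = k - 1
    if n_vocab_keep >= V:
        if n_vocab_keep > V:
            warnings.warn(
                f"k={k} exceeds the {V + 1} available logical features; keeping all"
            )
        vocab_idx = np.arange(V)
    elif n_vocab_keep <= 0:
        vocab_idx = np.array([], dtype=int)
    else:
        vocab_idx = top_k_columns(F[:V], n_vocab_keep)
    age_idx = np.arange(V, V + len(AGE_COLUMNS))
    selected = tuple(int(i) for i in np.concatenate([vocab_idx, age_idx]))
    ranking = FeatureRanking(
        f_values=F,
        selected=selected,
        selected_names=tuple(matrix.column_names[i] for i in selected),
    )
    return ranking, matrix.subset(selected)
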