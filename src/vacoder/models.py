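"""The four classifier families with the study's optimized configurations.

Families and their defaults (number of ANOVA-selected features, family
parameters):

* ``naive_bayes`` — multinomial naive Bayes with add-one smoothing; 200 features.
* ``random_forest`` — 26 trees, unlimited depth, sqrt-feature subsampling; 414 features.
* ``svm_ovr_linear`` — aggregate of one-vs-rest linear-kernel SVMs; 378 features.
  Per-category confidence is a softmax over the one-vs-rest decision values.
* ``ffnn`` — feed-forward network, one hidden layer of 297 ReLU units,
  softmax output, cross-entropy loss, early stopping on a 10% validation
  slice; 398 features.

Feature selection (ANOVA top-k) is part of :func:`train` and is fitted on
the training data only; the fitted model records the exact selected column
indices so that prediction applies the same subset.  A seeded random
search with a fixed evaluation budget (default 100) tunes the family
parameters and the number of features.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy.special import softmax
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import MultinomialNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .features import FeatureMatrix, FeatureRanking, select_top_k

logger = logging.getLogger(__name__)

FAMILIES = ("naive_bayes", "random_forest", "svm_ovr_linear", "ffnn")

#: Study-optimized number of selected features per family.
DEFAULT_N_FEATURES = {
    "naive_bayes": 200,
    "random_forest": 414,
    "svm_ovr_linear": 378,
    "ffnn": 398,
}


@dataclass
class ModelConfig:
    """Configuration of one classifier family.

    ``params`` holds family-specific settings; unspecified entries fall
    back to the study defaults (trees=26, hidden_units=297,
    activation="relu", nb alpha=1.0, svm C=1.0).
    """

    family: str
    n_features: int | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.n_features is None:
            self.n_features = DEFAULT_N_FEATURES[self.family]
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


def _make_estimator(config: ModelConfig):
    p = config.params
    if config.family == "naive_bayes":
        return MultinomialNB(alpha=p.get("alpha", 1.0))
    if config.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.get("trees", 26),
            max_depth=p.get("max_depth", None),
            max_features="sqrt",
            random_state=config.seed,
            n_jobs=1,
        )
    if config.family == "svm_ovr_linear":
        # LinearSVC is one-vs-rest for multiclass problems
        return LinearSVC(
            C=p.get("C", 1.0),
            dual=False,
            random_state=config.seed,
        )
    if config.family == "ffnn":
        return MLPClassifier(
            hidden_layer_sizes=(p.get("hidden_units", 297),),
            activation=p.get("activation", "relu"),
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=10,
            max_iter=p.get("max_iter", 200),
            random_state=config.seed,
        )
    raise AssertionError(config.family)


@dataclass
class TrainedClassifier:
    """A fitted model of one family, exposing per-category confidence.

    Predicts only categories seen in training; confidences are
    non-negative and sum to 1 per record.
    """

    config: ModelConfig
    estimator: object
    categories: tuple[str, ...]
    ranking: FeatureRanking
    selected_columns: tuple[int, ...]
    selected_names: tuple[str, ...]

    def confidence_matrix(self, matrix: FeatureMatrix) -> np.ndarray:
        """Records x categories confidence array (rows sum to 1)."""
        missing = [
            name
            for name in self.selected_names
            if name not in matrix.column_names
        ]
        if missing:
            raise ValueError(
                f"feature matrix lacks {len(missing)} columns required by the "
                f"model, e.g. {missing[:5]}"
            )
        col_of = {name: j for j, name in enumerate(matrix.column_names)}
        idx = [col_of[name] for name in self.selected_names]
        X = matrix.X[:, idx]
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
        else:  # LinearSVC: softmax over one-vs-rest decision values
            scores = est.decision_function(X)
            if scores.ndim == 1:  # binary case: single margin column
                scores = np.column_stack([-scores, scores])
            proba = softmax(scores, axis=1)
        proba = np.clip(proba, 0.0, None)
        proba = proba / proba.sum(axis=1, keepdims=True)
        return proba

    def predict_with_confidence(
        self, matrix: FeatureMatrix
    ) -> list[list[tuple[str, float]]]:
        """Per record: full (category, confidence) ranking, best first.

        Ties in confidence are broken toward the lower category index.
        """
        proba = self.confidence_matrix(matrix)
        out = []
        for row in proba:
            order = np.argsort(-row, kind="stable")
            out.append([(self.categories[j], float(row[j])) for j in order])
        return out

    def predict(self, matrix: FeatureMatrix) -> list[str]:
        """Top-1 category per record."""
        return [ranked[0][0] for ranked in self.predict_with_confidence(matrix)]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(
                {
                    "config": dataclasses.asdict(self.config),
                    "categories": list(self.categories),
                    "selected_columns": list(self.selected_columns),
                    "selected_names": list(self.selected_names),
                },
                indent=1,
            )
        )
        joblib.dump(self.estimator, directory / "estimator.joblib")
        joblib.dump(self.ranking, directory / "ranking.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        return cls(
            config=ModelConfig(**meta["config"]),
            estimator=joblib.load(directory / "estimator.joblib"),
            categories=tuple(meta["categories"]),
            ranking=joblib.load(directory / "ranking.joblib"),
            selected_columns=tuple(meta["selected_columns"]),
            selected_names=tuple(meta["selected_names"]),
        )


def train(
    config: ModelConfig, matrix: FeatureMatrix, labels: Sequence[str]
) -> TrainedClassifier:
    """Select features by ANOVA and fit the configured classifier.

    Deterministic given ``config.seed``.  Raises on single-category labels
    or non-finite feature values.
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("training labels must contain at least 2 categories")
    if not np.isfinite(matrix.X.data if hasattr(matrix.X, "data") else matrix.X).all():
        raise ValueError("feature matrix contains non-finite values")
    ranking, reduced = select_top_k(matrix, labels, config.n_features)
    est = _make_estimator(config)
    X = reduced.X
    if config.family == "ffnn":
        X = X.astype(np.float64)
        counts = np.unique(labels, return_counts=True)[1]
        if counts.min() < 2:
            # stratified early-stopping split impossible with singleton classes
            est.set_params(early_stopping=False)
            logger.info("ffnn: singleton class present, early stopping disabled")
    est.fit(X, labels)
    categories = tuple(str(c) for c in est.classes_)
    logger.info(
        "trained %s on %d records, %d categories, %d columns",
        config.family,
        X.shape[0],
        len(categories),
        X.shape[1],
    )
    return TrainedClassifier(
        config=config,
        estimator=est,
        categories=categories,
        ranking=ranking,
        selected_columns=ranking.selected,
        selected_names=ranking.selected_names,
    )


@dataclass
class SearchSpec:
    """Budgeted random-search specification for one family.

    The objective is mean validation sensitivity (support-weighted
    recall).  Exactly ``budget`` candidates are evaluated; failed trials
    score -inf and are kept in the log.
    """

    family: str
    budget: int = 100
    n_features_range: tuple[int, int] = (50, 600)
    seed: int = 0


_PARAM_SAMPLERS = {
    "naive_bayes": lambda rng: {"alpha": float(10 ** rng.uniform(-2, 0.5))},
    "random_forest": lambda rng: {"trees": int(rng.integers(5, 101))},
    "svm_ovr_linear": lambda rng: {"C": float(10 ** rng.uniform(-2, 2))},
    "ffnn": lambda rng: {"hidden_units": int(rng.integers(50, 401))},
}


def optimize(
    spec: SearchSpec,
    train_matrix: FeatureMatrix,
    train_labels: Sequence[str],
    val_matrix: FeatureMatrix,
    val_labels: Sequence[str],
) -> tuple[ModelConfig, list[dict]]:
    """Seeded random search over family parameters and the feature count.

    Returns the best configuration by validation sensitivity together with
    the full trial log.
    """
    if spec.budget < 1:
        raise ValueError("budget must be >= 1")
    from .metrics import confusion_table, prf  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    max_feats = train_matrix.n_vocab_columns + 1
    lo, hi = spec.n_features_range
    hi = min(hi, max_feats)
    lo = min(lo, hi)
    trials: list[dict] = []
    best: tuple[float, int, ModelConfig] | None = None
    for i in range(spec.budget):
        candidate = ModelConfig(
            family=spec.family,
            n_features=int(rng.integers(lo, hi + 1)),
            params=_PARAM_SAMPLERS[spec.family](rng),
            seed=spec.seed,
        )
        try:
            model = train(candidate, train_matrix, train_labels)
            preds = model.predict(val_matrix)
            cats = sorted(set(val_labels) | set(preds))
            _, sensitivity, _ = prf(confusion_table(val_labels, preds, cats))
            score = float(sensitivity)
        except Exception as exc:  # failed trial: logged, scored -inf
            logger.warning("trial %d failed: %s", i, exc)
            score = float("-inf")
        trials.append(
            {
                "trial": i,
                "n_features": candidate.n_features,
                "params": dict(candidate.params),
                "score": score,
            }
        )
        if best is None or score > best[0]:
            best = (score, i, candidate)
    assert best is not None
    logger.info(
        "%s search: best trial %d, validation sensitivity %.3f",
        spec.family,
        best[1],
        best[0],
    )
    return best[2], trials
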