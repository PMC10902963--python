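"""Binary-relevance multilabel diagnosis of dento-maxillofacial deformities.

The Q = 6 deformity labels (per-jaw over/under-development and deviation)
are modelled as six independent binary classification problems over the
cephalometric/demographic feature vector (binary relevance).  Each per-label
classifier — gradient-boosted trees by default, logistic regression as a
pluggable alternative — is fitted on a feature subset chosen by forward
sequential selection: features are ranked by importance from a full-feature
fit and admitted in rank order iff they strictly improve cross-validated
accuracy (the top-ranked feature is always admitted, so the subset is never
empty).

The model front end follows the fit/results pattern:

>>> model = DiagnosisModel(cohort.data)        # doctest: +SKIP
>>> results = model.fit(seed=0)                # doctest: +SKIP
>>> print(results.summary())                   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold

from .cohort import largest_remainder
from .registry import LABELS

__all__ = [
    "DiagnosisError",
    "DiagnosisConfig",
    "ConfusionCounts",
    "MetricsReport",
    "BRModel",
    "DiagnosisModel",
    "DiagnosisResults",
    "split_dataset",
    "forward_select",
    "fit_br",
    "predict",
    "resolve_diagnosis",
    "compute_metrics",
    "roc_auc",
    "tune_hyperparams",
]


class DiagnosisError(ValueError):
    """Invalid dataset, label, or configuration."""


@dataclass(frozen=True)
class DiagnosisConfig:
    """Base-learner settings.

    ``learner`` is ``"xgboost"`` (gradient-boosted trees, the default) or
    ``"logistic"`` (L2 logistic regression).  Tree settings follow the usual
    small-cohort regime: shallow trees, moderate ensemble size.
    """

    learner: str = "xgboost"
    n_estimators: int = 80
    max_depth: int = 3
    learning_rate: float = 0.3
    selection_folds: int = 3
    threshold: float = 0.5

    def __post_init__(self):
        if self.learner not in ("xgboost", "logistic"):
            raise DiagnosisError("learner must be 'xgboost' or 'logistic'")
        if self.selection_folds < 2:
            raise DiagnosisError("selection_folds must be >= 2")


def _make_learner(config: DiagnosisConfig, seed: int):
    if config.learner == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            learning_rate=config.learning_rate,
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            importance_type="gain",
            eval_metric="logloss",
            verbosity=0,
        )
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))


def _importances(clf, n_features: int) -> np.ndarray:
    if hasattr(clf, "feature_importances_"):
        return np.asarray(clf.feature_importances_, dtype=float)
    # pipeline ending in a linear model: rank by |coefficient|
    final = clf[-1] if hasattr(clf, "__getitem__") else clf
    return np.abs(np.asarray(final.coef_, dtype=float)).ravel()[:n_features]


def split_dataset(
    data: pd.DataFrame, seed: int, ratios: tuple[int, int, int] = (7, 3, 1)
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/validation/test split in the given ratio.

    Sizes follow largest-remainder apportionment of the ratio, so the three
    parts always partition the data exactly; reproducible from ``seed``.
    """
    n = len(data)
    if n < sum(ratios):
        raise DiagnosisError(f"need at least {sum(ratios)} records, got {n}")
    sizes = largest_remainder(n, ratios)
    order = np.random.default_rng(seed).permutation(n)
    edges = np.cumsum(sizes)[:-1]
    parts = np.split(order, edges)
    return tuple(data.iloc[idx].reset_index(drop=True) for idx in parts)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, config, folds: int, seed: int) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in cv.split(X, y):
        clf = _make_learner(config, seed)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def forward_select(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 3,
    seed: int = 0,
    config: DiagnosisConfig | None = None,
) -> list[str]:
    """Forward sequential feature selection for one label.

    Features are ranked by importance from a full-feature fit, then traversed
    in rank order; a feature is retained iff it strictly improves the
    cross-validated accuracy of the growing subset.  The top-ranked feature
    is always admitted.
    """
    config = config if config is not None else DiagnosisConfig()
    if folds < 2:
        raise DiagnosisError("need at least 2 folds")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DiagnosisError("label has a single class in the training data")

    full = _make_learner(config, seed)
    full.fit(X.to_numpy(dtype=float), y)
    imp = _importances(full, X.shape[1])
    ranked = [X.columns[i] for i in np.argsort(-imp, kind="stable")]

    subset: list[str] = []
    best_acc = -np.inf
    for feat in ranked:
        candidate = subset + [feat]
        acc = _cv_accuracy(X[candidate].to_numpy(dtype=float), y, config, folds, seed)
        if not subset or acc > best_acc:
            subset = candidate
            best_acc = acc
    return subset


@dataclass(frozen=True)
class ConfusionCounts:
    """A 2x2 confusion table."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DiagnosisError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        if t.shape != p.shape:
            raise DiagnosisError("length mismatch between truth and prediction")
        return cls(
            tp=int(np.sum((t == 1) & (p == 1))),
            fp=int(np.sum((t == 0) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
            fn=int(np.sum((t == 1) & (p == 0))),
        )


@dataclass(frozen=True)
class MetricsReport:
    """The classification metric battery.

    ``degenerate`` names metrics whose defining denominator was zero and
    which were reported as 0 by convention.
    """

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float | None = None
    degenerate: tuple[str, ...] = ()


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, specificity and F1 from a confusion table.

    Zero-denominator metrics are reported as 0 and flagged in ``degenerate``.
    AUC needs scores, not counts — see :func:`roc_auc`.
    """
    if counts.total == 0:
        raise DiagnosisError("empty confusion table")
    degenerate: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = ratio(counts.tn, counts.fp + counts.tn, "specificity")
    if precision + recall == 0:
        degenerate.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        degenerate=tuple(degenerate),
    )


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve (equals the tie-corrected rank-sum /
    pair-counting statistic).  Requires both classes present."""
    t = np.asarray(y_true, dtype=int)
    if len(np.unique(t)) < 2:
        raise DiagnosisError("AUC undefined with a single class")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def tune_hyperparams(
    X: pd.DataFrame,
    y,
    space: Mapping[str, Sequence],
    budget: int,
    folds: int = 3,
    seed: int = 0,
    config: DiagnosisConfig | None = None,
) -> dict:
    """Seeded randomized hyperparameter search maximizing CV accuracy.

    ``budget`` is the number of sampled configurations; budget 0 returns the
    declared defaults unchanged.  The returned dict always lies inside the
    declared space (or equals the defaults).
    """
    config = config if config is not None else DiagnosisConfig()
    if budget < 0:
        raise DiagnosisError("budget must be nonnegative")
    defaults = asdict(config)
    if budget == 0:
        return defaults
    if not space:
        raise DiagnosisError("empty hyperparameter space")
    y = np.asarray(y, dtype=int)
    Xa = X.to_numpy(dtype=float)
    best_params, best_acc = None, -np.inf
    for params in ParameterSampler(dict(space), n_iter=budget, random_state=seed):
        trial = DiagnosisConfig(**{**defaults, **params})
        acc = _cv_accuracy(Xa, y, trial, folds, seed)
        if acc > best_acc:
            best_acc, best_params = acc, {**defaults, **params}
    return best_params


@dataclass
class BRModel:
    """Fitted binary-relevance model: per-label classifier, selected feature
    subset and validation accuracy, in canonical label order."""

    labels: tuple[str, ...]
    classifiers: dict[str, object]
    selected_features: dict[str, list[str]]
    validation_accuracy: dict[str, float]
    config: DiagnosisConfig
    seed: int


def fit_br(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    feature_columns: Sequence[str],
    labels: Sequence[str] = LABELS,
    config: DiagnosisConfig | None = None,
    seed: int = 0,
) -> BRModel:
    """Fit one binary classifier per label on its forward-selected features.

    Validation accuracy is recorded per label for model-choice bookkeeping.
    Deterministic given ``seed``.  Raises :class:`DiagnosisError` for a label
    with a single class in the training data.
    """
    config = config if config is not None else DiagnosisConfig()
    classifiers: dict[str, object] = {}
    selected: dict[str, list[str]] = {}
    val_acc: dict[str, float] = {}
    X_train = train[list(feature_columns)]
    for label in labels:
        y = train[label].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise DiagnosisError(f"label {label!r} has a single class in training data")
        feats = forward_select(X_train, y, config.selection_folds, seed, config)
        clf = _make_learner(config, seed)
        clf.fit(train[feats].to_numpy(dtype=float), y)
        classifiers[label] = clf
        selected[label] = feats
        if len(validation):
            pred = clf.predict(validation[feats].to_numpy(dtype=float))
            val_acc[label] = float(np.mean(pred == validation[label].to_numpy(dtype=int)))
        else:
            val_acc[label] = float("nan")
    return BRModel(
        labels=tuple(labels),
        classifiers=classifiers,
        selected_features=selected,
        validation_accuracy=val_acc,
        config=config,
        seed=seed,
    )


def predict(model: BRModel, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-label binary predictions and positive-class probabilities.

    Threshold is ``config.threshold`` (default 0.5); a probability exactly at
    the threshold resolves positive.  Raises :class:`DiagnosisError` naming
    any missing selected feature.
    """
    n = len(X)
    labels = np.zeros((n, len(model.labels)), dtype=int)
    probs = np.zeros((n, len(model.labels)))
    for j, label in enumerate(model.labels):
        feats = model.selected_features[label]
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise DiagnosisError(f"missing feature(s) {missing} for label {label!r}")
        p = model.classifiers[label].predict_proba(X[feats].to_numpy(dtype=float))[:, 1]
        probs[:, j] = p
        labels[:, j] = (p >= model.config.threshold).astype(int)
    return labels, probs


def resolve_diagnosis(labels, probs=None) -> dict:
    """Collapse the six binary labels into a per-jaw clinical diagnosis.

    Over/under-development conflicts for a jaw resolve to the higher
    probability; neither positive means normal development.
    """
    lab = {name: int(v) for name, v in zip(LABELS, np.asarray(labels).ravel())}
    if probs is None:
        prob = {name: float(v) for name, v in zip(LABELS, np.asarray(labels).ravel())}
    else:
        prob = {name: float(v) for name, v in zip(LABELS, np.asarray(probs).ravel())}

    def development(jaw: str) -> str:
        over, under = f"{jaw}_overdevelopment", f"{jaw}_underdevelopment"
        if lab[over] and lab[under]:
            return "over" if prob[over] >= prob[under] else "under"
        if lab[over]:
            return "over"
        if lab[under]:
            return "under"
        return "normal"

    return {
        "maxilla": {
            "development": development("maxillary"),
            "deviation": bool(lab["maxillary_deviation"]),
        },
        "mandible": {
            "development": development("mandibular"),
            "deviation": bool(lab["mandibular_deviation"]),
        },
    }


class DiagnosisModel:
    """Multilabel diagnostic model over a labeled tabular dataset.

    ``data`` must carry numeric feature columns and the six binary label
    columns; every non-label, non-identifier numeric column is treated as a
    feature unless ``feature_columns`` is given.  ``fit`` splits the data
    7:3:1 into train/validation/test, runs per-label forward selection and
    classifier fits, and returns :class:`DiagnosisResults` with the held-out
    test metrics.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_columns: Sequence[str] | None = None,
        labels: Sequence[str] = LABELS,
        config: DiagnosisConfig | None = None,
    ):
        self.data = data.reset_index(drop=True)
        self.labels = tuple(labels)
        missing = [c for c in self.labels if c not in data.columns]
        if missing:
            raise DiagnosisError(f"missing label column(s): {missing}")
        if feature_columns is None:
            skip = set(self.labels) | {"patient_id", "sex"}
            feature_columns = [
                c
                for c in data.columns
                if c not in skip and pd.api.types.is_numeric_dtype(data[c])
            ]
        if not feature_columns:
            raise DiagnosisError("no feature columns")
        self.feature_columns = list(feature_columns)
        self.config = config if config is not None else DiagnosisConfig()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DiagnosisModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, seed: int = 0) -> "DiagnosisResults":
        train, validation, test = split_dataset(self.data, seed)
        br = fit_br(
            train, validation, self.feature_columns, self.labels, self.config, seed
        )
        return DiagnosisResults(self, br, train, validation, test, seed)


class DiagnosisResults:
    """Fitted diagnostic model plus its split and held-out test metrics."""

    def __init__(self, model, br: BRModel, train, validation, test, seed: int):
        self.model = model
        self.br = br
        self.train = train
        self.validation = validation
        self.test = test
        self.seed = seed
        self._metrics: pd.DataFrame | None = None

    def predict(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return predict(self.br, X)

    def diagnose(self, x: pd.DataFrame) -> dict:
        labels, probs = predict(self.br, x)
        return resolve_diagnosis(labels[0], probs[0])

    def metrics(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-label metric battery on ``data`` (default: the test split)."""
        if data is None:
            if self._metrics is not None:
                return self._metrics
            data = self.test
        labels, probs = predict(self.br, data)
        rows = []
        for j, label in enumerate(self.br.labels):
            y = data[label].to_numpy(dtype=int)
            counts = ConfusionCounts.from_predictions(y, labels[:, j])
            rep = compute_metrics(counts)
            auc = roc_auc(y, probs[:, j]) if len(np.unique(y)) == 2 else np.nan
            rows.append(
                {
                    "label": label,
                    "accuracy": rep.accuracy,
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "specificity": rep.specificity,
                    "f1": rep.f1,
                    "auc": auc,
                    "n_features": len(self.br.selected_features[label]),
                }
            )
        table = pd.DataFrame(rows).set_index("label")
        if data is self.test:
            self._metrics = table
        return table

    def summary(self) -> str:
        """Plain-text per-label test-set report."""
        table = self.metrics()
        sizes = (len(self.train), len(self.validation), len(self.test))
        return (
            "Binary-relevance diagnosis "
            f"(learner={self.br.config.learner}, seed={self.seed})\n"
            f"split train/validation/test: {sizes[0]}/{sizes[1]}/{sizes[2]}\n\n"
            + table.round(3).to_string()
            + "\n"
        )
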