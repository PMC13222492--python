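"""Stacked ensemble classifier with confidence-based abstention.

Five base learners spanning distinct inductive biases — linear discriminant
analysis, a calibrated RBF support-vector machine, a multilayer perceptron,
multinomial logistic regression, and a random forest — feed their class
probabilities into a logistic-regression meta-learner. Meta-features are
produced by internal cross-validation so the meta-learner never sees a base
learner's prediction on a sample that learner was trained on.

A prediction's confidence is the meta-learner's maximum class posterior.
Abstention thresholds are calibrated from pooled out-of-bag confidences of
bootstrap-refit models: the overall cutoff is the largest threshold that
still retains the target fraction (0.95 solid-tumor profile, 0.90
hematologic profile); classes with too few pooled out-of-bag samples for
that quantile to be meaningful ("minor" classes) instead get
max(0.5, minimum observed confidence in the class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC


@dataclass
class ClassifierConfig:
    cv_folds: int = 5
    calibration_folds: int = 3
    rf_estimators: int = 100
    mlp_hidden: tuple[int, ...] = (32,)
    mlp_max_iter: int = 300
    svm_c: float = 1.0
    lr_max_iter: int = 2000
    seed: int = 0


@dataclass
class StackedModel:
    estimator: StackingClassifier
    classes: list[str]
    config: ClassifierConfig
    n_features: int

    def predict_proba(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape} does not match training ({self.n_features})"
            )
        proba = self.estimator.predict_proba(X)
        return proba / proba.sum(axis=1, keepdims=True)


@dataclass
class ThresholdModel:
    overall_threshold: float
    per_class_thresholds: dict[str, float]
    retention_target: float
    minor_class_floor: float = 0.5
    minor_classes: list[str] = field(default_factory=list)

    def threshold_for(self, predicted_class: str) -> float:
        return self.per_class_thresholds.get(predicted_class, self.overall_threshold)


@dataclass
class Prediction:
    sample_id: str
    predicted_class: str
    confidence: float
    status: str  # "scored" | "filtered"
    threshold_applied: float


def _build_estimator(classes: int, config: ClassifierConfig) -> StackingClassifier:
    seed = config.seed
    base = [
        ("lda", LinearDiscriminantAnalysis()),
        (
            "svm",
            CalibratedClassifierCV(
                SVC(C=config.svm_c, kernel="rbf", random_state=seed),
                method="sigmoid",
                cv=config.calibration_folds,
            ),
        ),
        (
            "mlp",
            MLPClassifier(
                hidden_layer_sizes=config.mlp_hidden,
                max_iter=config.mlp_max_iter,
                random_state=seed,
            ),
        ),
        ("lr", LogisticRegression(max_iter=config.lr_max_iter, random_state=seed)),
        (
            "rf",
            RandomForestClassifier(
                n_estimators=config.rf_estimators, random_state=seed
            ),
        ),
    ]
    final = LogisticRegression(max_iter=config.lr_max_iter, random_state=seed)
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    return StackingClassifier(
        estimators=base,
        final_estimator=final,
        cv=cv,
        stack_method="predict_proba",
        n_jobs=1,
    )


def train_stacked(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
) -> StackedModel:
    """Fit the stacked ensemble on PC-score features."""
    if config is None:
        config = ClassifierConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    if counts.min() < config.cv_folds:
        small = classes[counts < config.cv_folds].tolist()
        raise ValueError(
            f"classes {small} have fewer samples than the {config.cv_folds} internal "
            "cross-validation folds; merge or drop them, or lower cv_folds"
        )
    est = _build_estimator(classes.size, config)
    est.fit(X, y)
    return StackedModel(
        estimator=est, classes=list(est.classes_), config=config, n_features=X.shape[1]
    )


def predict_proba(model: StackedModel, features: np.ndarray | pd.DataFrame) -> np.ndarray:
    return model.predict_proba(features)


def confidence(probabilities: np.ndarray) -> np.ndarray:
    """Confidence score: maximum class posterior of the meta-learner."""
    return np.asarray(probabilities).max(axis=1)


def retention_threshold(confidences: np.ndarray, retention_target: float) -> float:
    """Largest cutoff t such that the fraction of confidences >= t meets the target."""
    c = np.sort(np.asarray(confidences, dtype=float))[::-1]
    n = c.size
    m = int(np.ceil(retention_target * n))
    m = min(max(m, 1), n)
    return float(c[m - 1])


def calibrate_thresholds(
    oob: pd.DataFrame,
    retention_target: float,
    minor_class_floor: float = 0.5,
) -> ThresholdModel:
    """Calibrate abstention cutoffs from pooled out-of-bag results.

    ``oob`` needs columns ``confidence`` and ``true_class`` (one row per
    pooled OOB prediction). Major classes share the class-level retention
    quantile; a class is minor when its pooled OOB count is below
    1/(1 - retention_target), too few samples for the retention quantile to
    be achievable, and receives max(floor, min observed confidence).
    """
    if oob.empty:
        raise ValueError("empty out-of-bag pool")
    conf = oob["confidence"].to_numpy(dtype=float)
    overall = retention_threshold(conf, retention_target)
    min_major = int(np.ceil(1.0 / (1.0 - retention_target))) if retention_target < 1 else np.inf
    per_class: dict[str, float] = {}
    minors: list[str] = []
    for cls, grp in oob.groupby("true_class"):
        if len(grp) < min_major:
            minors.append(str(cls))
            per_class[str(cls)] = float(
                max(minor_class_floor, grp["confidence"].min())
            )
        else:
            per_class[str(cls)] = overall
    return ThresholdModel(
        overall_threshold=overall,
        per_class_thresholds=per_class,
        retention_target=retention_target,
        minor_class_floor=minor_class_floor,
        minor_classes=sorted(minors),
    )


def classify(
    model: StackedModel,
    thresholds: ThresholdModel,
    features: np.ndarray | pd.DataFrame,
    sample_ids: list[str],
) -> list[Prediction]:
    """Predict, attach confidences, and mark below-threshold calls as filtered.

    A sample is filtered when its confidence is strictly below the cutoff
    of its predicted class (falling back to the overall cutoff); exactly at
    the cutoff counts as scored.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] != len(sample_ids):
        raise ValueError("sample id count does not match feature rows")
    if X.shape[0] == 0:
        return []
    proba = model.predict_proba(X)
    conf = confidence(proba)
    idx = proba.argmax(axis=1)
    out = []
    for sid, i, c in zip(sample_ids, idx, conf):
        cls = model.classes[i]
        cut = thresholds.threshold_for(cls)
        out.append(
            Prediction(
                sample_id=sid,
                predicted_class=cls,
                confidence=float(c),
                status="scored" if c >= cut else "filtered",
                threshold_applied=float(cut),
            )
        )
    return out


def predictions_frame(predictions: list[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.sample_id, p.predicted_class, p.confidence, p.status, p.threshold_applied)
            for p in predictions
        ],
        columns=["sample_id", "predicted_class", "confidence", "status", "threshold_applied"],
    )
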