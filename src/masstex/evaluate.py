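"""Classifiers and evaluation: softmax head, RBF/linear SVM, kNN, XGBoost;
accuracy / sensitivity / specificity, ROC and AUC under stratified 5-fold CV.

Conventions fixed throughout the package: labels are binary with the
*malignant-like* class coded 1 and treated as the positive class, so

    Acc  = N_correct / N = (TP + TN) / N
    Sens = TP / (TP + FN)          (malignant caught)
    Spec = TN / (FP + TN)          (benign cleared)

AUC is the area under the ROC curve by trapezoidal integration over all
probability thresholds, numerically identical to the Mann-Whitney
probability that a random positive outscores a random negative.

All estimators run inside a pipeline that standardizes features with
train-fold statistics, and are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .block import FeatureBlock
from .errors import AlignmentError, ConfigurationError, DegenerateLabelsError

__all__ = [
    "ClassifierSpec",
    "EvalReport",
    "CvResult",
    "SoftmaxClassifier",
    "make_estimator",
    "train_classifier",
    "evaluate",
    "cross_validate",
    "tune_svm_c",
]

CLASSIFIER_KINDS = ("svm_rbf", "svm_linear", "softmax", "knn", "gradient_boosting")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family plus kind-specific hyperparameters."""

    kind: str = "svm_rbf"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigurationError(
                f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}")


class SoftmaxClassifier(BaseEstimator, ClassifierMixin):
    """Single affine layer + softmax, input dropout, SGD on cross-entropy.

    The head used on directly-fused features: full-batch gradient descent for
    ``epochs`` epochs at learning rate ``lr``, with Bernoulli dropout (rate
    ``dropout``) on the input activations during training only.  The clean
    (dropout-free) cross-entropy is recorded per epoch in ``loss_trace_``.
    """

    def __init__(self, lr: float = 1e-3, epochs: int = 200,
                 dropout: float = 0.5, seed: int = 0):
        self.lr = lr
        self.epochs = epochs
        self.dropout = dropout
        self.seed = seed

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise DegenerateLabelsError("softmax head requires two classes")
        onehot = (y[:, None] == self.classes_[None, :]).astype(np.float64)
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        self.W_ = np.zeros((d, self.classes_.size))
        self.b_ = np.zeros(self.classes_.size)
        keep = 1.0 - self.dropout
        self.loss_trace_ = []
        for _ in range(self.epochs):
            if self.dropout > 0:
                mask = rng.binomial(1, keep, size=X.shape) / keep
                Xd = X * mask
            else:
                Xd = X
            p = self._softmax(Xd @ self.W_ + self.b_)
            grad_w = Xd.T @ (p - onehot) / n
            grad_b = (p - onehot).mean(axis=0)
            self.W_ -= self.lr * grad_w
            self.b_ -= self.lr * grad_b
            p_clean = self._softmax(X @ self.W_ + self.b_)
            self.loss_trace_.append(
                float(-np.mean(np.sum(onehot * np.log(p_clean + 1e-12), axis=1))))
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self._softmax(X @ self.W_ + self.b_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def make_estimator(spec: ClassifierSpec):
    """Standardizer + classifier pipeline for a spec (deterministic per seed)."""
    spec.validate()
    hp = spec.hyperparams
    if spec.kind == "svm_rbf":
        model = SVC(kernel="rbf", C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"),
                    probability=True, random_state=spec.seed)
    elif spec.kind == "svm_linear":
        model = SVC(kernel="linear", C=hp.get("C", 1.0),
                    probability=True, random_state=spec.seed)
    elif spec.kind == "softmax":
        model = SoftmaxClassifier(lr=hp.get("lr", 1e-3), epochs=hp.get("epochs", 200),
                                  dropout=hp.get("dropout", 0.5), seed=spec.seed)
    elif spec.kind == "knn":
        model = KNeighborsClassifier(n_neighbors=hp.get("k", 5))
    else:  # gradient_boosting
        from xgboost import XGBClassifier
        model = XGBClassifier(n_estimators=hp.get("rounds", 200),
                              max_depth=hp.get("depth", 3),
                              learning_rate=hp.get("lr", 0.1),
                              random_state=spec.seed, verbosity=0,
                              eval_metric="logloss")
    return Pipeline([("scale", StandardScaler()), ("clf", model)])


def train_classifier(X: FeatureBlock | np.ndarray, y, spec: ClassifierSpec):
    """Fit the spec'd pipeline; returns the fitted model handle."""
    Xv = X.values if isinstance(X, FeatureBlock) else np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training requires two classes")
    if not np.all(np.isfinite(Xv)):
        raise AlignmentError("features must be finite")
    return make_estimator(spec).fit(Xv, y)


def positive_proba(model, X) -> np.ndarray:
    """Probability of the positive (malignant, label 1) class."""
    proba = model.predict_proba(X)
    classes = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    return proba[:, list(classes).index(1)]


@dataclass
class EvalReport:
    """Confusion counts and derived metrics at one threshold, plus ROC/AUC."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sens: float
    spec: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "acc": self.acc, "sens": self.sens, "spec": self.spec,
                "auc": self.auc, "n": self.n, "threshold": self.threshold}


def evaluate(probabilities, y_true, threshold: float = 0.5) -> EvalReport:
    """Confusion counts, Acc/Sens/Spec and trapezoidal AUC at a threshold.

    ``probabilities`` are P(malignant); predictions are ``p >= threshold``.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(y_true)
    if p.shape != y.shape:
        raise AlignmentError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ConfigurationError("probabilities must lie in [0, 1]")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("AUC undefined for single-class labels")

    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = tp + tn + fp + fn
    fpr, tpr, _ = roc_curve(y, p)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn,
                      acc=(tp + tn) / n,
                      sens=tp / (tp + fn),
                      spec=tn / (fp + tn),
                      fpr=fpr, tpr=tpr, auc=auc, threshold=threshold)


@dataclass
class CvResult:
    """Per-fold reports plus their unweighted means and standard deviations."""

    folds: list[EvalReport]
    mean_acc: float
    std_acc: float
    mean_sens: float
    mean_spec: float
    mean_auc: float
    std_auc: float
    fold_assignment: np.ndarray

    @classmethod
    def from_folds(cls, folds: list[EvalReport], assignment: np.ndarray) -> "CvResult":
        accs = np.array([f.acc for f in folds])
        aucs = np.array([f.auc for f in folds])
        return cls(folds=folds,
                   mean_acc=float(accs.mean()), std_acc=float(accs.std()),
                   mean_sens=float(np.mean([f.sens for f in folds])),
                   mean_spec=float(np.mean([f.spec for f in folds])),
                   mean_auc=float(aucs.mean()), std_auc=float(aucs.std()),
                   fold_assignment=assignment)

    def to_dict(self) -> dict:
        return {"mean_acc": self.mean_acc, "std_acc": self.std_acc,
                "mean_sens": self.mean_sens, "mean_spec": self.mean_spec,
                "mean_auc": self.mean_auc, "std_auc": self.std_auc,
                "folds": [f.to_dict() for f in self.folds]}


def cross_validate(X: FeatureBlock | np.ndarray, y, spec: ClassifierSpec,
                   folds: int = 5, seed: int = 0, groups=None) -> CvResult:
    """Stratified (and, with ``groups``, group-aware) k-fold CV.

    Augmented copies of one source patch share a group id so they can never
    straddle a fold boundary.  Fold assignment is deterministic given seed.
    """
    Xv = X.values if isinstance(X, FeatureBlock) else np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("CV requires two classes")
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xv, y, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xv, y)

    assignment = np.full(y.size, -1, dtype=int)
    reports = []
    for k, (tr, te) in enumerate(split_iter):
        assignment[te] = k
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ConfigurationError(
                "group constraint left a fold with a single class")
        model = make_estimator(spec).fit(Xv[tr], y[tr])
        reports.append(evaluate(positive_proba(model, Xv[te]), y[te]))
    return CvResult.from_folds(reports, assignment)


def tune_svm_c(X_train, y_train, X_val, y_val, grid,
               kind: str = "svm_rbf", seed: int = 0) -> tuple[float, dict]:
    """Pick the C maximizing validation accuracy; ties go to the smallest C."""
    grid = sorted(grid)
    if not grid:
        raise ConfigurationError("C grid must be non-empty")
    accs: dict[float, float] = {}
    best_c, best_acc = None, -np.inf
    for c in grid:
        model = train_classifier(np.asarray(X_train), y_train,
                                 ClassifierSpec(kind=kind, hyperparams={"C": c},
                                                seed=seed))
        acc = float(np.mean(model.predict(np.asarray(X_val)) == np.asarray(y_val)))
        accs[c] = acc
        if acc > best_acc:  # strict: first (smallest) C wins ties
            best_c, best_acc = c, acc
    return best_c, accs
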