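"""Classifiers and stratified cross-validated evaluation.

Two classifiers are supported:

* a hand-rolled linear SVM trained by per-sample stochastic gradient
  descent on the L2-regularized hinge loss (decision rule
  ``sign(v . s - k)``), with the decaying learning rate
  ``eta_t = eta0 / (1 + eta0 * lambda * t)``;
* an RBF-kernel soft-margin SVM (C = 1 by default), delegated to the
  libsvm solver behind :class:`sklearn.svm.SVC`.

Evaluation reports the five standard metrics — AUC, classification
accuracy (CA, %), F1, precision (PPV, %) and recall (%) — pooled over the
folds of a stratified k-fold cross-validation in which the min/max scaler
(and, when used, the feature ranking) is refit on each training split
only, so no test-fold information leaks into scaling or selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.svm import SVC

from .errors import ConfigError
from .features import MinMaxScaler
from .selection import rank_features


@dataclass
class SgdHyper:
    """Hyper-parameters of the hinge/L2 SGD linear SVM."""

    eta0: float = 0.1
    lam: float = 1e-4
    epochs: int = 100
    seed: int = 0


@dataclass
class LinearModel:
    """One-vs-rest linear SVM: per-class weights v and bias k."""

    classes: np.ndarray
    weights: np.ndarray  # (n_classes, n_features)
    bias: np.ndarray  # (n_classes,)
    hyper: SgdHyper

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights.T - self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes[np.argmax(scores, axis=1)]


def train_sgd_linear(X, y, hyper: SgdHyper = None) -> LinearModel:
    """Train the linear SVM by per-sample SGD on the regularized hinge loss.

    Each epoch shuffles the samples with the run seed, then applies
    ``v := v - eta_t * grad(lam*||v||^2/2 + hinge(t(v.s - k)))`` per sample
    (bias unregularized).  Multiclass is handled one-vs-rest.  The result
    is a pure function of ``(X, y, hyper)``.
    """
    hyper = hyper or SgdHyper()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigError("training requires at least two classes")
    n, d = X.shape
    weights = np.zeros((len(classes), d))
    bias = np.zeros(len(classes))
    for ci, cls in enumerate(classes):
        t = np.where(y == cls, 1.0, -1.0)
        rng = np.random.default_rng(hyper.seed + ci)
        v = np.zeros(d)
        k = 0.0
        step = 0
        for _ in range(hyper.epochs):
            for i in rng.permutation(n):
                step += 1
                eta = hyper.eta0 / (1.0 + hyper.eta0 * hyper.lam * step)
                margin = t[i] * (v @ X[i] - k)
                v *= 1.0 - eta * hyper.lam
                if margin < 1.0:
                    v += eta * t[i] * X[i]
                    k -= eta * t[i]
        weights[ci] = v
        bias[ci] = k
    return LinearModel(classes=classes, weights=weights, bias=bias, hyper=hyper)


def train_svm_rbf(X, y, c: float = 1.0, gamma="scale") -> SVC:
    """Soft-margin RBF-kernel SVM (dual solved by libsvm); C defaults to 1.

    ``gamma="scale"`` is ``1/(n_features * var(X))``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ConfigError("training requires at least two classes")
    model = SVC(C=c, kernel="rbf", gamma=gamma, decision_function_shape="ovr")
    model.fit(np.asarray(X, dtype=np.float64), y)
    return model


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Deterministic stratified partition: fold index per sample.

    Within each class the (seed-shuffled) members are dealt round-robin,
    so per-class counts differ by at most one across folds.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ConfigError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assign = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ConfigError(f"class {cls!r} has {len(idx)} members, fewer than k={k}")
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % k
    return assign


@dataclass
class MetricsReport:
    """AUC / CA / F1 / PPV / recall plus the pooled confusion matrix."""

    auc: float
    ca_pct: float
    f1: float
    ppv_pct: float
    recall_pct: float
    confusion: np.ndarray
    classes: np.ndarray
    per_fold_ca: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ca_pct": self.ca_pct,
            "f1": self.f1,
            "ppv_pct": self.ppv_pct,
            "recall_pct": self.recall_pct,
            "confusion": self.confusion.tolist(),
            "classes": [str(c) for c in self.classes],
            "per_fold_ca": self.per_fold_ca,
        }


def evaluate_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Compute the five report metrics from pooled predictions.

    ``scores`` may be a 1-D decision value (binary) or an
    ``(n, n_classes)`` matrix; AUC is the Mann-Whitney rank statistic for
    binary labels and macro one-vs-rest for multiclass.  Omitting scores
    yields ``auc = nan``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty evaluation input")
    classes = np.unique(y_true)
    ca = 100.0 * np.mean(y_true == y_pred)
    ppv, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="weighted", zero_division=0
    )
    auc = np.nan
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if len(classes) == 2:
            s = scores[:, 1] if scores.ndim == 2 else scores
            auc = roc_auc_score((y_true == classes[1]).astype(int), s)
        else:
            auc = roc_auc_score(y_true, scores, multi_class="ovr", average="macro", labels=classes)
    return MetricsReport(
        auc=float(auc),
        ca_pct=float(ca),
        f1=float(f1),
        ppv_pct=float(100.0 * ppv),
        recall_pct=float(100.0 * rec),
        confusion=confusion_matrix(y_true, y_pred, labels=classes),
        classes=classes,
    )


@dataclass
class ClassifierSpec:
    """Which classifier to run and with what hyper-parameters."""

    name: str = "sgd"  # "sgd" | "svm_rbf"
    c: float = 1.0
    gamma: object = "scale"
    eta0: float = 0.1
    lam: float = 1e-4
    epochs: int = 100

    def __post_init__(self) -> None:
        if self.name not in ("sgd", "svm_rbf"):
            raise ConfigError(f"unknown classifier: {self.name!r}")


def _fit_predict(spec: ClassifierSpec, Xtr, ytr, Xte, seed: int):
    if spec.name == "sgd":
        model = train_sgd_linear(
            Xtr, ytr, SgdHyper(eta0=spec.eta0, lam=spec.lam, epochs=spec.epochs, seed=seed)
        )
        return model.predict(Xte), model.decision_scores(Xte)
    model = train_svm_rbf(Xtr, ytr, c=spec.c, gamma=spec.gamma)
    scores = model.decision_function(Xte)
    if scores.ndim == 1:
        scores = np.column_stack([-scores, scores])
    return model.predict(Xte), scores


def cross_validate(
    table: pd.DataFrame,
    labels,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    feature_subset=None,
    rank_top_k: int = None,
    ig_bins: int = 10,
) -> MetricsReport:
    """Stratified k-fold evaluation with per-fold scaling (and ranking).

    ``feature_subset`` fixes the columns used; ``rank_top_k`` instead
    refits an information-gain ranking on each training split and keeps
    its top-k columns.  Metrics are micro-pooled over the folds.
    """
    labels = np.asarray(labels)
    folds = stratified_folds(labels, k, seed)
    classes = np.unique(labels)
    pooled_true, pooled_pred = [], []
    pooled_scores = np.zeros((len(labels), len(classes)))
    order = []
    per_fold_ca = []
    for f in range(k):
        te = np.flatnonzero(folds == f)
        tr = np.flatnonzero(folds != f)
        cols = list(table.columns)
        if rank_top_k is not None:
            ranking = rank_features(table.iloc[tr], labels[tr], bins=ig_bins)
            cols = ranking.top(rank_top_k)
        elif feature_subset is not None:
            cols = list(feature_subset)
        scaler = MinMaxScaler().fit(table.iloc[tr][cols])
        Xtr = scaler.transform(table.iloc[tr][cols]).to_numpy()
        Xte = scaler.transform(table.iloc[te][cols]).to_numpy()
        pred, scores = _fit_predict(spec, Xtr, labels[tr], Xte, seed=seed + f)
        pooled_true.append(labels[te])
        pooled_pred.append(pred)
        pooled_scores[te] = scores
        order.append(te)
        per_fold_ca.append(float(100.0 * np.mean(labels[te] == pred)))
    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    idx = np.concatenate(order)
    report = evaluate_metrics(y_true, y_pred, pooled_scores[idx])
    report.per_fold_ca = per_fold_ca
    return report
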