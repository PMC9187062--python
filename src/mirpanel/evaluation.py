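"""Marker evaluation: per-miRNA ROC/AUC, exhaustive logistic-combination
search, fixed-threshold classification metrics, and hierarchical clustering
of samples over the selected panel.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_X_y, check_is_fitted

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

MAX_PANEL_FOR_EXHAUSTIVE = 15


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


@dataclass
class MetricsReport:
    """Confusion counts and the derived metrics at a fixed threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    auc: float

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
            "threshold": self.threshold, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn,
        }


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC for binary labels (1 = cancer).

    The AUC equals the Mann-Whitney pair statistic: the fraction of
    (cancer, control) pairs in which the cancer sample scores higher, with
    half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = roc_curve(y, scores)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr,
                     auc=float(sk_auc(fpr, tpr)))


class CombinationClassifier(ClassifierMixin, BaseEstimator):
    """Binomial logistic model over a marker subset.

    With two classes the multinomial logistic model reduces to the binomial
    one; a small ridge penalty (lambda ~ 1/n, i.e. ``C = n_samples``) keeps
    the fit defined under complete separation, which planted markers make
    common.  Constant covariates are dropped with a warning before fitting.

    Fitted attributes: ``coef_`` (per kept covariate), ``intercept_``,
    ``kept_``, ``training_auc_``.
    """

    def __init__(self, C: Optional[float] = None, max_iter: int = 2000):
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if len(np.unique(y)) != 2:
            raise ValueError("need exactly two classes")
        keep = X.std(axis=0) > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant covariate(s)",
                          stacklevel=2)
        if not keep.any():
            raise ValueError("all covariates are constant")
        self.kept_ = keep
        C = self.C if self.C is not None else float(len(y))
        self._lr = LogisticRegression(C=C, solver="lbfgs",
                                      max_iter=self.max_iter)
        self._lr.fit(X[:, keep], y)
        self.classes_ = self._lr.classes_
        self.coef_ = np.zeros(X.shape[1])
        self.coef_[keep] = self._lr.coef_[0]
        self.intercept_ = float(self._lr.intercept_[0])
        self.training_auc_ = roc_auc(self.decision_function(X), y).auc
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


@dataclass
class CombinationModel:
    """A fitted marker-combination score: sum(beta_i * x_i) + intercept."""

    subset: List[str]
    coefficients: np.ndarray
    intercept: float
    training_auc: float
    classifier: CombinationClassifier

    def as_dict(self) -> dict:
        return {"subset": list(self.subset),
                "coefficients": [float(c) for c in self.coefficients],
                "intercept": float(self.intercept),
                "training_auc": float(self.training_auc)}


def fit_combination(train: ExpressionMatrix,
                    subset: Sequence[str]) -> CombinationModel:
    """Fit the logistic combination score for one marker subset."""
    if not subset:
        raise ValueError("subset must be non-empty")
    X, y, names = train.to_xy(probes=list(subset))
    clf = CombinationClassifier().fit(X, y)
    return CombinationModel(subset=list(names), coefficients=clf.coef_.copy(),
                            intercept=clf.intercept_,
                            training_auc=clf.training_auc_, classifier=clf)


def classification_metrics(probabilities, labels,
                           threshold: float = 0.5) -> MetricsReport:
    """Confusion counts and metrics calling cancer when probability >= threshold."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    y = np.asarray(labels).astype(int)
    call = p >= threshold
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    tn = int(np.sum(~call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    a = roc_auc(p, y).auc if len(np.unique(y)) == 2 else float("nan")
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold, auc=a)


def best_combination(train: ExpressionMatrix, validation: ExpressionMatrix,
                     panel: Sequence[str],
                     threshold: float = 0.5
                     ) -> Tuple[CombinationModel, MetricsReport, pd.DataFrame]:
    """Exhaustive search over all non-empty panel subsets.

    Every subset is fitted on the training set only; the winner maximizes
    training AUC with ties broken by smaller subset size then lexicographic
    order.  The winner is then scored once on the validation set.  Returns
    ``(model, validation_metrics, combinations_table)``.
    """
    panel = sorted(panel)
    if not panel:
        raise ValueError("panel is empty")
    if len(panel) > MAX_PANEL_FOR_EXHAUSTIVE:
        raise ValueError(
            f"refusing exhaustive search over 2^{len(panel)} subsets; "
            f"panel must have <= {MAX_PANEL_FOR_EXHAUSTIVE} members"
        )
    best_model: Optional[CombinationModel] = None
    rows = []
    # iteration order (size, lexicographic) + strict improvement = tie-break
    for size in range(1, len(panel) + 1):
        for subset in itertools.combinations(panel, size):
            model = fit_combination(train, subset)
            rows.append({"subset": "+".join(subset), "size": size,
                         "training_auc": model.training_auc})
            if best_model is None or model.training_auc > best_model.training_auc:
                best_model = model
    table = pd.DataFrame(rows)
    Xv, yv, _ = validation.to_xy(probes=best_model.subset)
    proba = best_model.classifier.predict_proba(Xv)[:, 1]
    report = classification_metrics(proba, yv, threshold=threshold)
    logger.info("best combination %s: training AUC %.4f, validation AUC %.4f",
                "+".join(best_model.subset), best_model.training_auc, report.auc)
    return best_model, report, table


def hierarchical_cluster(matrix: ExpressionMatrix, panel: Sequence[str],
                         n_clusters: int = 2):
    """Complete-linkage Euclidean clustering of samples over the panel probes.

    Returns ``(labels, linkage_matrix)`` where ``labels`` is a pandas Series
    of cluster ids (1..n_clusters) indexed by sample id.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    sub = matrix.subset_probes(list(panel))
    X = sub.values.to_numpy().T
    if X.shape[0] < n_clusters:
        raise ValueError("fewer samples than requested clusters")
    if X.shape[0] == 1:
        return pd.Series([1], index=sub.sample_ids), np.empty((0, 4))
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=sub.sample_ids), Z
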