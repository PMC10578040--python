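"""Supervised endotype assignment: stratified splitting, SMOTE balancing,
multi-class and binary classifiers, evaluation metrics, centroid label
transfer, and feature attribution (Gini, permutation, Monte-Carlo Shapley).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (cohen_kappa_score, confusion_matrix,
                             precision_recall_curve, roc_auc_score, roc_curve)
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsOneClassifier, OneVsRestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC


@dataclass
class ClassifierSpec:
    algorithm: str = "random_forest"  # random_forest | linear_svm | logistic_regression | gradient_boosting
    scheme: str = "one_vs_one"        # one_vs_one | one_vs_rest | binary
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class TrainedModel:
    estimator: object
    spec: ClassifierSpec
    classes: list
    feature_ids: list[str]


@dataclass
class EvaluationReport:
    confusion: pd.DataFrame
    per_class: pd.DataFrame     # sensitivity, specificity, f1 per class
    accuracy: float
    kappa: float
    roc: dict | None = None     # class -> {fpr, tpr, auc}
    pr: dict | None = None      # class -> {precision, recall}


def split_train_validation(sample_ids, labels, train_frac: float = 0.8,
                           seed: int = 0) -> tuple[list, list]:
    """Stratified train/validation split: train size = floor(train_frac * n),
    disjoint and exhaustive, deterministic given the seed."""
    sample_ids = list(sample_ids)
    y = np.asarray(labels)
    train, val = train_test_split(sample_ids, train_size=train_frac,
                                  stratify=y, random_state=seed)
    return list(train), list(val)


def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balance every class up to the majority count with SMOTE.

    Each synthetic point is x + u * (x_nn - x) for a random minority point x,
    one of its k nearest within-class neighbors x_nn, and u ~ U(0, 1).  If a
    class has <= k members, k is reduced for that class; a single-member
    class cannot be interpolated and is an error.  Majority points are never
    altered; an already-balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    if np.all(counts == target):
        return X, y
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, count in zip(classes, counts):
        need = int(target - count)
        if need == 0:
            continue
        if count < 2:
            raise ValueError(f"class {cls!r} has a single member; cannot interpolate")
        pts = X[y == cls]
        k = min(k_neighbors, count - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        _, neigh = nn.kneighbors(pts)  # col 0 is the point itself
        base = rng.integers(0, count, size=need)
        pick = neigh[base, rng.integers(1, k + 1, size=need)]
        u = rng.uniform(size=(need, 1))
        synth = pts[base] + u * (pts[pick] - pts[base])
        new_X.append(synth)
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


_DEFAULTS = {
    "random_forest": dict(n_estimators=200),
    "linear_svm": dict(kernel="linear", C=1.0),
    "logistic_regression": dict(max_iter=2000),
    "gradient_boosting": dict(n_estimators=100),
}


def _base_estimator(spec: ClassifierSpec):
    params = {**_DEFAULTS[spec.algorithm], **spec.hyperparameters}
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.algorithm == "linear_svm":
        return SVC(random_state=spec.seed, **params)
    if spec.algorithm == "logistic_regression":
        return LogisticRegression(random_state=spec.seed, **params)
    if spec.algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **params)
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


def train(spec: ClassifierSpec, X, y, feature_ids: list[str] | None = None) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if spec.scheme == "binary":
        if len(classes) != 2:
            raise ValueError("binary scheme requires exactly 2 classes")
        est = _base_estimator(spec)
    elif spec.scheme == "one_vs_one":
        est = OneVsOneClassifier(_base_estimator(spec))
    elif spec.scheme == "one_vs_rest":
        est = OneVsRestClassifier(_base_estimator(spec))
    else:
        raise ValueError(f"unknown scheme {spec.scheme!r}")
    est.fit(X, y)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X.shape[1])]
    return TrainedModel(est, spec, classes, list(feature_ids))


def predict(model: TrainedModel, X) -> np.ndarray:
    return model.estimator.predict(np.asarray(X, dtype=float))


def class_scores(model: TrainedModel, X) -> pd.DataFrame | None:
    """Per-class decision scores (probabilities where available, otherwise
    decision-function values); None when the scheme exposes neither."""
    X = np.asarray(X, dtype=float)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        try:
            return pd.DataFrame(est.predict_proba(X), columns=est.classes_)
        except AttributeError:
            pass
    if hasattr(est, "decision_function"):
        s = est.decision_function(X)
        if s.ndim == 1:
            s = np.column_stack([-s, s])
        return pd.DataFrame(s, columns=est.classes_)
    return None


def evaluate(y_true, y_pred, scores: pd.DataFrame | None = None) -> EvaluationReport:
    """Confusion-matrix metrics plus one-vs-rest ROC/PR per class.

    Sensitivity is the per-class recall; specificity is the one-vs-rest true
    negative rate; AUROC is the rank statistic against the class score.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    rows = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = cm.sum() - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * prec * sens / (prec + sens)) if (prec + sens) else 0.0
        rows[cls] = {"sensitivity": sens, "specificity": spec, "f1": f1}
    roc = pr = None
    if scores is not None:
        roc, pr = {}, {}
        for cls in classes:
            if cls not in scores.columns:
                continue
            truth = (y_true == cls).astype(int)
            if truth.min() == truth.max():
                continue
            s = scores[cls].to_numpy()
            fpr, tpr, _ = roc_curve(truth, s)
            prec_c, rec_c, _ = precision_recall_curve(truth, s)
            roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(roc_auc_score(truth, s))}
            pr[cls] = {"precision": prec_c, "recall": rec_c}
    return EvaluationReport(
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        per_class=pd.DataFrame(rows).T,
        accuracy=float((y_true == y_pred).mean()),
        kappa=float(cohen_kappa_score(y_true, y_pred)),
        roc=roc, pr=pr,
    )


def centroid_transfer(X, centroids: pd.DataFrame) -> np.ndarray:
    """Label each row of X with the nearest centroid (Euclidean); exact ties
    go to the lowest centroid index."""
    X = np.asarray(X, dtype=float)
    C = centroids.to_numpy(dtype=float)
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # argmin returns the first (lowest) index on ties
    return np.asarray(centroids.index)[idx]


# ---------------------------------------------------------------------------
# feature attribution
# ---------------------------------------------------------------------------

def feature_attribution(model: TrainedModel, X, method: str = "gini",
                        y=None, n_mc: int = 1000, seed: int = 0,
                        background: np.ndarray | None = None,
                        positive_class=None):
    """Per-feature contributions.

    gini: impurity-decrease totals (tree ensembles only).
    permutation: mean accuracy drop over label-preserving shuffles (needs y).
    shapley_mc: Monte-Carlo permutation-sampling Shapley estimates per sample
    (returned as a samples x features DataFrame); contributions sum exactly
    to prediction - baseline because each sampled permutation telescopes.
    """
    X = np.asarray(X, dtype=float)
    if method == "gini":
        est = model.estimator
        base = getattr(est, "estimator", None) or est
        if hasattr(est, "feature_importances_"):
            imp = est.feature_importances_
        elif hasattr(est, "estimators_") and all(
                hasattr(e, "feature_importances_") for e in est.estimators_):
            imp = np.mean([e.feature_importances_ for e in est.estimators_], axis=0)
        else:
            raise ValueError("gini importance requires a tree-based model")
        return pd.Series(imp, index=model.feature_ids)
    if method == "permutation":
        if y is None:
            raise ValueError("permutation importance needs labels")
        res = permutation_importance(model.estimator, X, np.asarray(y),
                                     n_repeats=10, random_state=seed)
        return pd.Series(res.importances_mean, index=model.feature_ids)
    if method == "shapley_mc":
        return shapley_mc(model, X, n_mc=n_mc, seed=seed, background=background,
                          positive_class=positive_class)
    raise ValueError(f"unknown attribution method {method!r}")


def _value_fn(model: TrainedModel, positive_class):
    est = model.estimator
    if hasattr(est, "predict_proba"):
        classes = list(est.classes_)
        col = classes.index(positive_class if positive_class is not None else classes[-1])
        return lambda Z: est.predict_proba(Z)[:, col]
    if hasattr(est, "decision_function"):
        def f(Z):
            s = est.decision_function(Z)
            return s if s.ndim == 1 else s[:, -1]
        return f
    raise ValueError("model exposes neither probabilities nor decision scores")


def shapley_mc(model: TrainedModel, X, n_mc: int = 1000, seed: int = 0,
               background: np.ndarray | None = None, positive_class=None
               ) -> pd.DataFrame:
    """Monte-Carlo Shapley values with a background (reference) set.

    The value of a coalition S for sample x is the mean model output over
    background rows with features in S replaced by x's values.  ``n_mc``
    random feature permutations are averaged; marginal contributions along a
    permutation telescope, so per-sample attributions sum exactly to
    f(x) - E_background[f].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if background is None:
        background = X
    background = np.asarray(background, dtype=float)
    f = _value_fn(model, positive_class)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    b = background.shape[0]
    phi = np.zeros((n, p))
    for s in range(n):
        x = X[s]
        contrib = np.zeros(p)
        for _ in range(n_mc):
            perm = rng.permutation(p)
            Z = background.copy()
            prev = f(Z).mean()
            for j in perm:
                Z[:, j] = x[j]
                cur = f(Z).mean()
                contrib[j] += cur - prev
                prev = cur
        phi[s] = contrib / n_mc
    return pd.DataFrame(phi, columns=model.feature_ids)


def shapley_baseline(model: TrainedModel, background: np.ndarray,
                     positive_class=None) -> float:
    """E_background[f]: the baseline that per-sample Shapley sums are
    measured against."""
    f = _value_fn(model, positive_class)
    return float(f(np.asarray(background, dtype=float)).mean())
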