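"""Feature-panel derivation: correlation culling plus balanced-fold
importance ranking over binary contrasts (disease vs control, active vs
inactive), reproducing the 134 -> 72 -> 32 style reduction on any score
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.svm import LinearSVC

from .data_model import ScoreMatrix


@dataclass
class FeaturePanel:
    """Outcome of panel derivation.

    ``retained`` is ordered; ``removed_correlated`` holds (removed, kept, r)
    triples; ``importance_table`` is feature x (cohort, algorithm) mean
    importances; ``readded`` lists manually re-included features (flagged,
    e.g. an immunoglobulin-chain module kept for ancestry-classification
    value even if unranked).
    """

    retained: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    importance_table: pd.DataFrame | None = None
    readded: list[str] = field(default_factory=list)


def correlation_cull(scores: ScoreMatrix, threshold: float = 0.9) -> FeaturePanel:
    """Remove the later member of every feature pair with Pearson r above
    ``threshold`` (greedy keep-first, deterministic in panel order)."""
    df = scores.data
    if df.shape[1] < 3:
        raise ValueError("correlation culling needs at least 3 samples")
    corr = np.corrcoef(df.to_numpy(dtype=float))
    names = list(df.index)
    kept: list[int] = []
    removed: list[tuple[str, str, float]] = []
    for i in range(len(names)):
        hit = None
        for j in kept:
            if corr[i, j] > threshold:
                hit = j
                break
        if hit is None:
            kept.append(i)
        else:
            removed.append((names[i], names[hit], float(corr[i, hit])))
    return FeaturePanel(retained=[names[i] for i in kept], removed_correlated=removed)


def balanced_folds(labels: pd.Series | np.ndarray, n_folds: int, seed: int,
                   val_frac: float = 0.3) -> list[dict]:
    """Build class-balanced folds by subsampling the majority class without
    replacement down to the minority-class size.

    Each fold holds *all* minority samples plus an equally sized random
    majority subsample, then is split 70/30 train/validation stratified by
    class.  Folds differ through the seeded RNG stream; the same seed gives
    identical folds.
    """
    labels = pd.Series(np.asarray(labels))
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("balanced_folds requires exactly two classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if counts.min() == counts.max():
        raise ValueError("classes already balanced; majority must exceed minority")
    min_idx = np.flatnonzero(labels.to_numpy() == minority)
    maj_idx = np.flatnonzero(labels.to_numpy() == majority)
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        pick = rng.choice(maj_idx, size=len(min_idx), replace=False)
        fold_idx = np.concatenate([min_idx, pick])
        train, val = [], []
        for cls_idx in (min_idx, pick):
            perm = rng.permutation(cls_idx)
            n_val = max(1, int(round(val_frac * len(perm))))
            val.extend(perm[:n_val])
            train.extend(perm[n_val:])
        folds.append({
            "indices": np.sort(fold_idx),
            "train": np.array(sorted(train)),
            "validation": np.array(sorted(val)),
        })
    return folds


def fold_importances(scores: ScoreMatrix, labels: pd.Series, n_folds: int,
                     seed: int, n_estimators: int = 200) -> pd.DataFrame:
    """Per-fold feature importances for one binary contrast: Gini importance
    from a random forest and permutation importance from a linear SVM,
    fit on each balanced fold's 70% training split."""
    X = scores.data.to_numpy(dtype=float).T
    y = labels.reindex(scores.sample_ids).to_numpy()
    folds = balanced_folds(y, n_folds, seed)
    rows = []
    for k, fold in enumerate(folds):
        tr = fold["train"]
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed + k)
        rf.fit(X[tr], y[tr])
        rows.append(pd.Series(rf.feature_importances_, index=scores.feature_ids,
                              name=("random_forest", k)))
        svm = LinearSVC(dual="auto", random_state=seed + k, max_iter=5000)
        svm.fit(X[tr], y[tr])
        perm = permutation_importance(svm, X[tr], y[tr], n_repeats=5,
                                      random_state=seed + k)
        rows.append(pd.Series(perm.importances_mean, index=scores.feature_ids,
                              name=("linear_svm", k)))
    table = pd.DataFrame(rows).T
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["algorithm", "fold"])
    return table


def rank_features(importances: dict[str, pd.DataFrame], top_k: int = 20,
                  readded: list[str] | None = None) -> FeaturePanel:
    """Aggregate per-fold importances into the final panel.

    ``importances`` maps cohort name -> feature x (algorithm, fold) table.
    Mean importance is taken across folds per (cohort, algorithm); the union
    of each top-``top_k`` list, deduplicated in first-seen order, plus any
    re-added features, is the panel.
    """
    mean_cols = {}
    panel: list[str] = []
    for cohort, table in importances.items():
        if table.shape[0] < top_k:
            raise ValueError(
                f"cohort {cohort!r} has {table.shape[0]} features; need >= {top_k}"
            )
        for algorithm in table.columns.get_level_values("algorithm").unique():
            mean_imp = table[algorithm].mean(axis=1)
            mean_cols[(cohort, algorithm)] = mean_imp
            top = mean_imp.sort_values(ascending=False, kind="stable").index[:top_k]
            for f in top:
                if f not in panel:
                    panel.append(f)
    readded = list(readded or [])
    flagged = [f for f in readded if f not in panel]
    for f in flagged:
        panel.append(f)
    return FeaturePanel(
        retained=panel,
        importance_table=pd.DataFrame(mean_cols),
        readded=flagged,
    )


def derive_panel(scores: ScoreMatrix, contrasts: dict[str, pd.Series],
                 folds_per_contrast: dict[str, int], seed: int,
                 corr_threshold: float = 0.9, top_k: int = 20,
                 readded: list[str] | None = None) -> FeaturePanel:
    """Full derivation: correlation culling, then balanced-fold importance
    ranking for each binary contrast, then top-k union (+ re-adds)."""
    culled = correlation_cull(scores, corr_threshold)
    sub = ScoreMatrix(scores.data.loc[culled.retained], dataset_ids=scores.dataset_ids)
    importances = {
        name: fold_importances(sub, labels, folds_per_contrast[name], seed)
        for name, labels in contrasts.items()
    }
    panel = rank_features(importances, top_k=top_k, readded=readded)
    panel.removed_correlated = culled.removed_correlated
    return panel
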