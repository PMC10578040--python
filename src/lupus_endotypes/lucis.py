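"""LuCIS: a composite immunologic score for lupus patients.

A ridge-penalized logistic model is fit to separate the least abnormal from
the most abnormal endotype on *binarized* module enrichment scores (score
> 0 -> 1, otherwise 0).  The per-feature coefficients then weight each
patient's binarized scores; their sum is the raw LuCIS, shifted by the
minimum attainable value so scores live on [0, max_score], and staged into
six equal sextiles of the attainable range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV


@dataclass
class LucisModel:
    coefficients: pd.Series     # feature -> weight, binarized-feature scale
    intercept: float
    lambda_: float              # chosen ridge penalty (1 / sklearn C)
    min_attainable: float       # sum of negative coefficients
    max_attainable: float       # sum of positive coefficients
    separation_flag: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def normalization_offset(self) -> float:
        return -self.min_attainable

    @property
    def max_score(self) -> float:
        """Width of the attainable score range after normalization."""
        return self.max_attainable - self.min_attainable

    @property
    def sextile_boundaries(self) -> np.ndarray:
        return np.arange(1, 7) * self.max_score / 6.0


def binarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Score > 0 -> 1; score <= 0 -> 0 (exact zero maps to 0)."""
    return (scores > 0).astype(int)


def fit_lucis(scores: pd.DataFrame, labels: pd.Series,
              lambda_grid: np.ndarray | None = None, seed: int = 0,
              cv: int = 10, positive_label=None) -> LucisModel:
    """Fit the ridge-logistic model on bookend-endotype samples.

    ``scores`` is features x samples (raw enrichment scores; binarization
    happens here); ``labels`` holds two classes, the most-abnormal one being
    ``positive_label`` (default: the lexicographically larger class).  The
    penalty is chosen by ``cv``-fold cross-validated deviance over
    ``lambda_grid`` (log-spaced 1e-3..1e3 by default).
    """
    y = labels.reindex(scores.columns)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    counts = y.value_counts()
    if counts.min() < 10:
        raise ValueError("each bookend class needs at least 10 samples")
    if positive_label is None:
        positive_label = classes[-1]
    X = binarize_scores(scores).to_numpy(dtype=float).T
    yb = (y == positive_label).astype(int).to_numpy()
    if lambda_grid is None:
        lambda_grid = np.logspace(-3, 3, 25)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))
    n = len(yb)
    # sklearn's logistic loss is sum-form; C = 1/lambda on that scale
    Cs = 1.0 / lambda_grid[::-1]
    clf = LogisticRegressionCV(Cs=Cs, cv=cv, penalty="l2",
                               scoring="neg_log_loss", max_iter=5000,
                               random_state=seed)
    clf.fit(X, yb)
    lam = float(1.0 / clf.C_[0])
    coef = pd.Series(clf.coef_[0], index=scores.index)
    # near-zero training deviance at the weakest available penalty suggests
    # complete separation
    pred = clf.predict_proba(X)[:, 1]
    dev = -np.mean(yb * np.log(np.clip(pred, 1e-12, 1)) +
                   (1 - yb) * np.log(np.clip(1 - pred, 1e-12, 1)))
    separation = bool(lam <= lambda_grid[0] * (1 + 1e-9) and dev < 1e-3)
    return LucisModel(
        coefficients=coef,
        intercept=float(clf.intercept_[0]),
        lambda_=lam,
        min_attainable=float(coef[coef < 0].sum()),
        max_attainable=float(coef[coef > 0].sum()),
        separation_flag=separation,
        provenance={"seed": seed, "cv": cv, "positive_label": str(positive_label),
                    "n_samples": n},
    )


def compute_lucis(binarized: pd.DataFrame, model: LucisModel) -> pd.DataFrame:
    """Per-sample LuCIS from a binarized features x samples matrix.

    raw = sum_f b_f * beta_f (the intercept is excluded); normalized = raw
    minus the minimum attainable raw value, so the lowest possible score is
    exactly 0 and the highest is ``model.max_score``.
    """
    common = model.coefficients.index
    missing = common.difference(binarized.index)
    if len(missing):
        raise ValueError(f"binarized matrix lacks model features: {list(missing)[:5]}")
    B = binarized.loc[common].to_numpy(dtype=float)
    raw = model.coefficients.to_numpy() @ B
    normalized = raw - model.min_attainable
    sextile = assign_sextile(normalized, model.max_score)
    return pd.DataFrame({
        "raw": raw,
        "normalized": normalized,
        "sextile": sextile,
    }, index=binarized.columns)


def assign_sextile(normalized, max_score: float) -> np.ndarray:
    """Stage normalized scores into sextiles of the attainable range.

    Boundaries sit at i * max_score / 6.  Sextile 1 is the closed interval
    [0, max/6]; later sextiles are half-open (lo, hi], so a score exactly on
    a boundary belongs to the lower sextile.
    """
    x = np.atleast_1d(np.asarray(normalized, dtype=float))
    if max_score <= 0:
        raise ValueError("max_score must be positive")
    frac = x * 6.0 / max_score
    # guard boundary values against float rounding before taking the ceiling
    frac = np.where(np.isclose(frac, np.round(frac), rtol=0.0, atol=1e-12),
                    np.round(frac), frac)
    s = np.ceil(frac).astype(int)
    return np.clip(s, 1, 6)
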