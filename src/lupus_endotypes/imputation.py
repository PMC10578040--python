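"""Cross-platform enrichment-score imputation.

Platforms missing a module's genes cannot score that module directly.  A
reference cohort measuring everything supplies, for each target module, its
best-correlated measured module and a ratio coefficient on shifted scores
(score + 1, so ratios are positive): c = mean over reference samples of
(s_target + 1) / (s_correlate + 1).  On a deficient platform the target is
reconstructed as c * (s_correlate + 1) - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EPS = 1e-9


@dataclass
class ImputationRule:
    target_feature: str
    correlate_feature: str
    coefficient: float
    reference_r: float
    reference_dataset: str = ""
    fallbacks: list = field(default_factory=list)  # (feature, coefficient, r), next-best first

    def to_dict(self) -> dict:
        return asdict(self)


def derive_rule(reference: pd.DataFrame, target_feature: str,
                reference_dataset: str = "", n_fallbacks: int = 3) -> ImputationRule:
    """Derive the imputation rule for one target from a reference
    features x samples score matrix.

    The correlate is the feature with the highest Pearson correlation to the
    target; the coefficient is the mean per-sample ratio of shifted scores.
    Next-best correlates are retained as fallbacks for platforms that also
    lack the primary correlate.
    """
    if target_feature not in reference.index:
        raise ValueError(f"target {target_feature!r} not in reference")
    if reference.shape[1] < 3:
        raise ValueError("reference needs at least 3 samples")
    others = [f for f in reference.index if f != target_feature]
    if not others:
        raise ValueError("reference has no candidate correlate features")
    t = reference.loc[target_feature].to_numpy(dtype=float)
    rs = {}
    for f in others:
        u = reference.loc[f].to_numpy(dtype=float)
        if np.std(t) < EPS or np.std(u) < EPS:
            r = 0.0 if len(others) > 1 else 1.0
        else:
            r = float(np.corrcoef(t, u)[0, 1])
        rs[f] = 0.0 if np.isnan(r) else r
    ranked = sorted(others, key=lambda f: -rs[f])

    def coeff(f: str) -> float:
        u = reference.loc[f].to_numpy(dtype=float)
        if np.any(u + 1 <= EPS):
            raise ValueError(
                f"degenerate reference: (score+1) <= 0 for correlate {f!r}"
            )
        return float(np.mean((t + 1.0) / (u + 1.0)))

    best = ranked[0]
    fallbacks = []
    for f in ranked[1:1 + n_fallbacks]:
        try:
            fallbacks.append((f, coeff(f), rs[f]))
        except ValueError:
            continue
    return ImputationRule(
        target_feature=target_feature,
        correlate_feature=best,
        coefficient=coeff(best),
        reference_r=rs[best],
        reference_dataset=reference_dataset,
        fallbacks=fallbacks,
    )


def derive_rules(reference: pd.DataFrame, targets: list[str],
                 reference_dataset: str = "") -> dict[str, ImputationRule]:
    return {t: derive_rule(reference, t, reference_dataset) for t in targets}


def impute(rule: ImputationRule, observed, clamp: bool = True):
    """Impute target scores from observed correlate scores:
    c * (s + 1) - 1, clamped to [-1, 1] (out-of-range results are logged)."""
    s = np.asarray(observed, dtype=float)
    out = rule.coefficient * (s + 1.0) - 1.0
    if clamp:
        n_out = int(np.sum((out < -1) | (out > 1)))
        if n_out:
            logger.warning("imputation of %s: %d value(s) clamped to [-1, 1]",
                           rule.target_feature, n_out)
        out = np.clip(out, -1.0, 1.0)
    return out if out.shape else float(out)


def complete_scores(scores: pd.DataFrame, rules: dict[str, ImputationRule],
                    all_features: list[str] | None = None) -> pd.DataFrame:
    """Fill features missing from a platform's score matrix using the rules.

    If a rule's primary correlate is itself unmeasured, the next-best
    measured fallback is used (logged).  Features with no usable rule stay
    absent.
    """
    out = scores.copy()
    wanted = all_features if all_features is not None else list(rules)
    for feat in wanted:
        if feat in out.index or feat not in rules:
            continue
        rule = rules[feat]
        candidates = [(rule.correlate_feature, rule.coefficient)] + \
            [(f, c) for f, c, _ in rule.fallbacks]
        chosen = next(((f, c) for f, c in candidates if f in out.index), None)
        if chosen is None:
            logger.warning("no measured correlate available to impute %s", feat)
            continue
        f, c = chosen
        if f != rule.correlate_feature:
            logger.info("imputing %s from fallback correlate %s", feat, f)
        used = ImputationRule(feat, f, c, rule.reference_r, rule.reference_dataset)
        out.loc[feat] = impute(used, out.loc[f].to_numpy(dtype=float))
    if all_features is not None:
        present = [f for f in all_features if f in out.index]
        out = out.loc[present]
    return out
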