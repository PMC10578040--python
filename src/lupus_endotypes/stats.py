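"""Association statistics for endotype and sextile characterization:
chi-square independence, odds ratios, the Cochran-Armitage trend test,
Pearson correlation, and Kruskal-Wallis with Dunn's post hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    warning: str | None = None


def chi_square_independence(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on an RxC contingency table; no continuity
    correction by default.  Tables with any expected cell below 1 are
    flagged, not rejected."""
    counts = np.asarray(table, dtype=float)
    if counts.min() < 0 or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    stat, p, df, expected = sps.chi2_contingency(counts, correction=yates)
    warning = "expected cell count < 1" if expected.min() < 1 else None
    return TestResult(float(stat), float(df), float(p), warning)


def odds_ratio(table) -> dict:
    """OR = ad/bc on a 2x2 table with a Woolf (log-scale) 95% CI.

    Zero cells trigger the Haldane-Anscombe 0.5 correction (flagged)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("odds ratio needs a 2x2 table")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) + np.array([-1, 1]) * 1.96 * se)
    return {"odds_ratio": float(orr), "ci95": (float(lo), float(hi)),
            "haldane_corrected": corrected}


def chi_square_trend(successes, totals, scores=None) -> TestResult:
    """Cochran-Armitage test for a linear trend in proportions across
    ordered groups (default scores 1..G); chi-square with 1 df."""
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or np.any(x > n) or np.any(n <= 0):
        raise ValueError("successes/totals mismatch")
    G = len(x)
    s = np.arange(1, G + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    N = n.sum()
    pbar = x.sum() / N
    if pbar in (0.0, 1.0):
        return TestResult(0.0, 1.0, 1.0, "degenerate: all successes or all failures")
    num = (s * (x - n * pbar)).sum()
    den = pbar * (1 - pbar) * ((n * s ** 2).sum() - (n * s).sum() ** 2 / N)
    stat = num ** 2 / den
    return TestResult(float(stat), 1.0, float(sps.chi2.sf(stat, 1)))


def pearson(x, y) -> TestResult:
    r, p = sps.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return TestResult(float(r), float(len(np.asarray(x)) - 2), float(p))


def kruskal_wallis(groups: list) -> TestResult:
    """Tie-corrected Kruskal-Wallis H across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if all(np.array_equal(groups[0], g) for g in groups[1:]) and all(
            np.ptp(g) == 0 for g in groups):
        # scipy raises on all-identical data; H is 0 by definition
        return TestResult(0.0, float(len(groups) - 1), 1.0)
    try:
        h, p = sps.kruskal(*groups)
    except ValueError:
        return TestResult(0.0, float(len(groups) - 1), 1.0)
    return TestResult(float(h), float(len(groups) - 1), float(p))


def dunn_posthoc(groups: list, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests from pooled mean ranks with tie correction.

    Returns a tidy frame with one row per pair: z, raw p, adjusted p.
    Adjustment is Bonferroni over all pairs (or none).
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    m = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
            rows.append({"group_a": i, "group_b": j, "z": float(z),
                         "p": float(p), "p_adj": float(p_adj)})
    return pd.DataFrame(rows)
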