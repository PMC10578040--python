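"""Per-sample gene-set enrichment via the KS-like weighted random walk.

The score for a (sample, gene set) pair is built in three steps:

1. *Expression statistic*: each gene's expression in a sample is converted to
   a cross-sample relative level, either a Gaussian-kernel CDF estimate
   (bandwidth s_i/4 per gene) or the empirical CDF.
2. *Ranking*: within each sample, genes are ordered by decreasing statistic
   and given the symmetric rank weight |p/2 - r + 1/2| (largest at both
   extremes of the list).
3. *Random walk*: walking down the ranked list, set members push the walk up
   by their (tau-powered) normalized weight, non-members push it down by
   1/(p - m).  The enrichment score (ES) is the largest positive deviation
   plus the largest negative deviation, and always lies in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data_model import ExpressionMatrix, ModuleLibrary, ScoreMatrix

logger = logging.getLogger(__name__)

EPS = 1e-12  # floor for degenerate bandwidths and weights


@dataclass
class GsvaParams:
    """Engine parameters.  ``score_mode`` is fixed to the max-difference rule
    (largest positive plus largest negative walk deviation)."""

    tau: float = 1.0
    kernel: str = "gaussian"  # or "ecdf"
    score_mode: str = "max_diff"
    min_set_size: int = 1

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.kernel not in ("gaussian", "ecdf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.score_mode != "max_diff":
            raise ValueError("only the max_diff score mode is supported")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")


def expression_statistic(matrix: ExpressionMatrix, kernel: str = "gaussian") -> np.ndarray:
    """Cross-sample relative expression statistic, genes x samples, in (0, 1].

    gaussian: statistic_ij = mean_k Phi((x_ij - x_ik) / h_i) with per-gene
    bandwidth h_i = s_i / 4 (sample SD), floored at EPS for constant genes.
    ecdf: the empirical CDF value (fraction of samples <= x_ij).
    """
    x = matrix.values
    n = x.shape[1]
    if kernel == "gaussian":
        if n < 3:
            raise ValueError("gaussian kernel needs at least 3 samples")
        h = np.maximum(x.std(axis=1, ddof=1) / 4.0, EPS)
        # pairwise differences per gene: (genes, samples, samples)
        diff = (x[:, :, None] - x[:, None, :]) / h[:, None, None]
        return norm.cdf(diff).mean(axis=2)
    if kernel == "ecdf":
        stat = np.empty_like(x)
        for i in range(x.shape[0]):
            stat[i] = rankdata(x[i], method="max") / n
        return stat
    raise ValueError(f"unknown kernel {kernel!r}")


def rank_weights(statistic: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Order genes by decreasing statistic (ties: statistic desc, then gene id
    asc) and return (order, weights).

    ``order[r]`` is the index of the gene at 1-based rank r+1; the weight at
    rank r (1-based) is |p/2 - r + 1/2|, floored at EPS so a single-gene
    universe does not produce an all-zero weight.
    """
    p = len(statistic)
    ids = np.asarray(gene_ids)
    # lexsort: last key is primary
    order = np.lexsort((ids, -np.asarray(statistic, dtype=float)))
    r = np.arange(1, p + 1, dtype=float)
    weights = np.abs(p / 2.0 - r + 0.5)
    weights = np.maximum(weights, EPS)
    return order, weights


def enrichment_score(order: np.ndarray, weights: np.ndarray,
                     in_set: np.ndarray, tau: float = 1.0) -> float:
    """ES for one sample and one set.

    ``in_set`` is a boolean mask over gene indices (the unordered universe);
    ``order``/``weights`` come from :func:`rank_weights`.
    """
    p = len(order)
    mask = np.asarray(in_set, dtype=bool)[order]
    m = int(mask.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the gene universe")
    if m == p:
        raise ValueError("gene set equals the gene universe")
    w = weights ** tau
    up = np.where(mask, w, 0.0)
    denom = up.sum()
    walk = np.cumsum(up) / denom - np.cumsum(~mask) / (p - m)
    pos = max(walk.max(), 0.0)
    neg = min(walk.min(), 0.0)
    return float(pos + neg)


def gsva(matrix: ExpressionMatrix, library: ModuleLibrary,
         params: GsvaParams | None = None) -> ScoreMatrix:
    """Transform a genes x samples matrix into a modules x samples score
    matrix.

    Genes absent from the matrix are dropped from each module (counts
    logged); modules whose intersection with the universe falls below
    ``min_set_size`` (or equals the whole universe) are dropped, not scored,
    and recorded in the output provenance.
    """
    params = params or GsvaParams()
    stat = expression_statistic(matrix, params.kernel)
    genes = matrix.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    p = len(genes)

    masks: dict[str, np.ndarray] = {}
    dropped: dict[str, str] = {}
    for name in library.names:
        members = [gene_pos[g] for g in library.modules[name] if g in gene_pos]
        lost = len(library.modules[name]) - len(members)
        if lost:
            logger.info("module %s: %d/%d genes absent from matrix", name, lost,
                        len(library.modules[name]))
        if len(members) < params.min_set_size or len(members) == 0:
            dropped[name] = f"only {len(members)} genes present (< {params.min_set_size})"
            continue
        if len(members) == p:
            dropped[name] = "set equals the gene universe"
            continue
        mask = np.zeros(p, dtype=bool)
        mask[members] = True
        masks[name] = mask
    if not masks:
        raise ValueError("every module was dropped; nothing to score")
    if dropped:
        logger.warning("dropped modules: %s", sorted(dropped))

    scores = np.empty((len(masks), matrix.n_samples))
    names = list(masks)
    for j in range(matrix.n_samples):
        order, weights = rank_weights(stat[:, j], genes)
        # per-sample reusable pieces of the walk
        w = weights ** params.tau
        for fi, name in enumerate(names):
            mask = masks[name][order]
            m = mask.sum()
            up = np.where(mask, w, 0.0)
            walk = np.cumsum(up) / up.sum() - np.cumsum(~mask) / (p - m)
            scores[fi, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)

    df = pd.DataFrame(scores, index=names, columns=matrix.sample_ids)
    return ScoreMatrix(
        df,
        provenance={
            "dataset_id": matrix.dataset_id,
            "kernel": params.kernel,
            "tau": params.tau,
            "dropped_modules": dropped,
        },
    )
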