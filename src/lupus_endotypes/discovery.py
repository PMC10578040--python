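"""Unsupervised endotype discovery and cross-dataset consensus.

Per dataset: restarted k-means++ on module scores with k chosen by elbow and
silhouette.  Across datasets: cluster mean-score profiles are matched by
cosine similarity and merged by complete-linkage hierarchical clustering cut
at a fixed height, yielding the final endotype universe (A, B, ... ordered by
increasing transcriptional abnormality).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

DEFAULT_RESTARTS = 5000
DEFAULT_MAX_ITER = 300
DEFAULT_CUT_HEIGHT = 1.8
DEFAULT_COSINE_THRESHOLD = 0.7


@dataclass
class ClusteringResult:
    labels: pd.Series          # sample -> cluster id (0..k-1)
    centroids: pd.DataFrame    # cluster x feature mean-score profiles
    inertia: float
    k: int
    n_restarts: int
    seed: int | None


@dataclass
class EndotypeModel:
    """Consensus endotypes: mean score profile per endotype plus provenance."""

    endotype_ids: list[str]
    profiles: pd.DataFrame               # endotype x feature
    members: dict[str, list[str]] = field(default_factory=dict)
    linkage_matrix: np.ndarray | None = None
    cut_height: float = DEFAULT_CUT_HEIGHT


def _as_sample_matrix(scores) -> tuple[np.ndarray, list[str], list[str]]:
    """Accept a ScoreMatrix (features x samples) or DataFrame and return
    (samples x features array, sample ids, feature ids)."""
    df = scores.data if hasattr(scores, "data") else scores
    return df.to_numpy(dtype=float).T, list(df.columns), list(df.index)


def kmeans(scores, k: int, n_restarts: int = DEFAULT_RESTARTS,
           max_iter: int = DEFAULT_MAX_ITER, seed: int | None = None) -> ClusteringResult:
    """Best-of-restarts Lloyd k-means with k-means++ seeding.

    The reported result is the minimum-inertia run among ``n_restarts``
    independently seeded starts (restart seeds fan out from ``seed`` through
    the library RNG).
    """
    X, sample_ids, feature_ids = _as_sample_matrix(scores)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} samples")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(X)
    centroids = pd.DataFrame(km.cluster_centers_, columns=feature_ids)
    return ClusteringResult(
        labels=pd.Series(labels, index=sample_ids),
        centroids=centroids,
        inertia=float(km.inertia_),
        k=k, n_restarts=n_restarts, seed=seed,
    )


def choose_k(scores, k_range: range | list[int], n_restarts: int = 100,
             seed: int | None = None, sil_rtol: float = 0.05) -> dict:
    """Scan k over ``k_range``; report inertia and mean silhouette per k,
    the elbow (maximum perpendicular distance to the chord of the normalized
    inertia curve) and the silhouette argmax.

    Both diagnostics are reported.  The selection policy (``k_selected``) is
    the largest k whose silhouette is within ``sil_rtol`` of the maximum:
    near-tied silhouettes favor the finer partition, because an over-split
    cluster is recoverable downstream (its centroids merge back in the
    consensus step) while an under-split one loses an endotype.  A
    non-monotone inertia curve is flagged as evidence the restart count is
    too small.
    """
    X, _, _ = _as_sample_matrix(scores)
    ks = sorted(k_range)
    if ks[0] < 2 or ks[-1] > X.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n_samples - 1]")
    inertias, silhouettes = [], []
    for k in ks:
        res = kmeans(scores, k, n_restarts=n_restarts, seed=seed)
        inertias.append(res.inertia)
        silhouettes.append(float(silhouette_score(X, res.labels.to_numpy())))
    inertias_arr = np.asarray(inertias)
    monotone = bool(np.all(np.diff(inertias_arr) <= 1e-9 * max(1.0, inertias_arr[0])))
    # knee: distance to the chord on axes normalized to [0, 1]
    kx = (np.asarray(ks, dtype=float) - ks[0]) / max(ks[-1] - ks[0], 1)
    span = inertias_arr[0] - inertias_arr[-1]
    iy = (inertias_arr - inertias_arr[-1]) / (span if span > 0 else 1.0)
    # chord from (0, iy[0]) to (1, iy[-1]); perpendicular distance per point
    x0, y0, x1, y1 = kx[0], iy[0], kx[-1], iy[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * kx - (x1 - x0) * iy + x1 * y0 - y1 * x0) / max(norm, 1e-12)
    sil_arr = np.asarray(silhouettes)
    near_best = sil_arr >= (1 - sil_rtol) * sil_arr.max()
    return {
        "k_values": ks,
        "inertia": inertias,
        "silhouette": silhouettes,
        "k_elbow": int(ks[int(np.argmax(dist))]),
        "k_silhouette": int(ks[int(np.argmax(silhouettes))]),
        "k_selected": int(np.asarray(ks)[near_best].max()),
        "inertia_monotone": monotone,
    }


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement in [-1, 1]."""
    return float(adjusted_rand_score(np.asarray(labels_a), np.asarray(labels_b)))


def cosine_similarity_matrix(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame) -> pd.DataFrame:
    a = profiles_a.to_numpy(dtype=float)
    b = profiles_b.reindex(columns=profiles_a.columns).to_numpy(dtype=float)
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    sim = (a / np.maximum(na, 1e-12)) @ (b / np.maximum(nb, 1e-12)).T
    return pd.DataFrame(sim, index=profiles_a.index, columns=profiles_b.index)


def cosine_match(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame,
                 threshold: float = DEFAULT_COSINE_THRESHOLD) -> dict:
    """Greedy best-pair matching of cluster profiles by cosine similarity.

    Repeatedly pairs the most similar unmatched (a, b) while similarity
    exceeds ``threshold``; leftovers on either side are flagged unique.
    """
    sim = cosine_similarity_matrix(profiles_a, profiles_b)
    free_a = list(sim.index)
    free_b = list(sim.columns)
    pairs: list[tuple[str, str, float]] = []
    while free_a and free_b:
        block = sim.loc[free_a, free_b]
        i, j = np.unravel_index(np.argmax(block.to_numpy()), block.shape)
        best = float(block.iat[i, j])
        if best <= threshold:
            break
        a, b = free_a[i], free_b[j]
        pairs.append((a, b, best))
        free_a.remove(a)
        free_b.remove(b)
    return {"pairs": pairs, "unique_a": free_a, "unique_b": free_b, "similarity": sim}


def consensus_merge(profiles: pd.DataFrame, cut_height: float = DEFAULT_CUT_HEIGHT,
                    method: str = "complete") -> EndotypeModel:
    """Merge per-dataset cluster profiles into final endotypes.

    Complete-linkage agglomeration on Euclidean distances between mean
    profiles, cut at ``cut_height``; each final endotype's profile is the
    mean of its merged members.  Endotypes are lettered A, B, ... in order
    of increasing mean signed enrichment (A = least abnormal; relatively
    unenriched modules score negative, so the signed mean tracks the breadth
    of activation).
    """
    if profiles.shape[0] < 2:
        raise ValueError("consensus requires at least 2 profiles")
    X = profiles.to_numpy(dtype=float)
    if cut_height <= 0:
        groups = np.arange(X.shape[0]) + 1
        Z = None
    else:
        Z = linkage(X, method=method, metric="euclidean")
        groups = fcluster(Z, t=cut_height, criterion="distance")
    merged = {}
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        merged[g] = (X[idx].mean(axis=0), [str(profiles.index[i]) for i in idx])
    # order by mean signed profile ascending; tie-break on first member name
    ordering = sorted(merged, key=lambda g: (float(merged[g][0].mean()),
                                             merged[g][1][0]))
    letters = list(string.ascii_uppercase)
    ids = [letters[i] if i < 26 else f"E{i}" for i in range(len(ordering))]
    prof = pd.DataFrame([merged[g][0] for g in ordering], index=ids,
                        columns=profiles.columns)
    members = {eid: merged[g][1] for eid, g in zip(ids, ordering)}
    return EndotypeModel(endotype_ids=ids, profiles=prof, members=members,
                         linkage_matrix=Z, cut_height=cut_height)


def relabel_to_reference(local: ClusteringResult | pd.DataFrame,
                         reference: EndotypeModel,
                         threshold: float = DEFAULT_COSINE_THRESHOLD) -> dict:
    """Map each local cluster to the reference endotype of maximal cosine
    similarity (ties broken by reference order; sub-threshold matches are
    flagged but still mapped)."""
    centroids = local.centroids if isinstance(local, ClusteringResult) else local
    sim = cosine_similarity_matrix(centroids, reference.profiles)
    mapping: dict = {}
    flagged: list = []
    for c in sim.index:
        row = sim.loc[c]
        best = row.idxmax()  # first maximum in reference order
        mapping[c] = best
        if row[best] <= threshold:
            flagged.append(c)
    return {"mapping": mapping, "similarity": sim, "below_threshold": flagged}


def relabel_samples(scores, reference: EndotypeModel, metric: str = "cosine") -> pd.Series:
    """Assign every sample directly to its most similar reference endotype
    (cosine similarity of, or Euclidean distance from, the sample's score
    vector to each profile)."""
    X, sample_ids, _ = _as_sample_matrix(scores)
    df = pd.DataFrame(X, index=sample_ids,
                      columns=(scores.data if hasattr(scores, "data") else scores).index)
    if metric == "cosine":
        sim = cosine_similarity_matrix(df, reference.profiles)
        return sim.idxmax(axis=1)
    if metric == "euclidean":
        P = reference.profiles.reindex(columns=df.columns).to_numpy(dtype=float)
        d = ((df.to_numpy(dtype=float)[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
        idx = d.argmin(axis=1)
        return pd.Series([reference.endotype_ids[i] for i in idx], index=sample_ids)
    raise ValueError(f"unknown metric {metric!r}")
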