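"""End-to-end orchestration: simulate -> enrichment scoring -> endotype
discovery -> classification -> LuCIS -> imputation -> clinical associations.

Each stage draws its seed deterministically from the master seed by stable
hashing of the stage name, so a rerun with the same config reproduces the
report exactly.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, discovery, lucis, simulate, stats
from .data_model import ScoreMatrix, filter_low_iqr
from .gsva import GsvaParams, gsva
from .imputation import derive_rules, complete_scores

logger = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out (stable across runs/platforms)."""
    return (int(master) * 100003 + zlib.crc32(stage.encode())) % (2 ** 31)


def score_cohort(cohort: simulate.Cohort, kernel: str = "gaussian",
                 tau: float = 1.0) -> dict[str, ScoreMatrix]:
    """IQR-filter and enrichment-score every pseudo-dataset separately."""
    params = GsvaParams(tau=tau, kernel=kernel, min_set_size=3)
    out = {}
    for name, matrix in cohort.matrices.items():
        out[name] = gsva(filter_low_iqr(matrix), cohort.library, params)
    return out


def common_features(scores_by_ds: dict[str, ScoreMatrix]) -> list[str]:
    """Features measured in every dataset, in first-dataset order."""
    names = list(scores_by_ds)
    common = set(scores_by_ds[names[0]].feature_ids)
    for n in names[1:]:
        common &= set(scores_by_ds[n].feature_ids)
    return [f for f in scores_by_ds[names[0]].feature_ids if f in common]


def concat_scores(scores_by_ds: dict[str, ScoreMatrix],
                  datasets: list[str] | None = None,
                  features: list[str] | None = None) -> pd.DataFrame:
    """Column-concatenate per-dataset score matrices (features x samples)."""
    datasets = datasets or list(scores_by_ds)
    features = features or common_features(
        {d: scores_by_ds[d] for d in datasets})
    return pd.concat([scores_by_ds[d].data.loc[features] for d in datasets],
                     axis=1)


def discover_endotypes(scores_by_ds: dict[str, ScoreMatrix],
                       datasets: list[str], seed: int,
                       n_restarts: int = 200, k_range=range(2, 9),
                       cut_height: float = discovery.DEFAULT_CUT_HEIGHT,
                       sle_only: pd.Index | None = None,
                       features: list[str] | None = None) -> dict:
    """Per-dataset k-means with silhouette-chosen k, then cross-dataset
    consensus of cluster mean-score profiles."""
    if features is None:
        features = common_features({d: scores_by_ds[d] for d in datasets})
    per_dataset = {}
    profiles = []
    for d in datasets:
        df = scores_by_ds[d].data.loc[features]
        if sle_only is not None:
            df = df[[c for c in df.columns if c in sle_only]]
        kmax = min(max(k_range), df.shape[1] - 1)
        report = discovery.choose_k(df, range(min(k_range), kmax + 1),
                                    n_restarts=max(20, n_restarts // 10),
                                    seed=seed)
        k = report["k_selected"]
        res = discovery.kmeans(df, k, n_restarts=n_restarts, seed=seed)
        per_dataset[d] = {"choose_k": report, "clustering": res}
        prof = res.centroids.copy()
        prof.index = [f"{d}:c{c}" for c in prof.index]
        profiles.append(prof)
    model = discovery.consensus_merge(pd.concat(profiles), cut_height=cut_height)
    return {"per_dataset": per_dataset, "consensus": model, "features": features}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis from a YAML/JSON config (or dict) and return a
    provenance-stamped report.  Missing stage keys fall back to defaults;
    unknown stage names are an error."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    known = {"seed", "simulate", "gsva", "discover", "classify", "lucis", "stats"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ValueError("pipeline config requires a 'seed' key")
    master = int(config["seed"])
    report: dict = {"seed": master, "stages": {}}

    # --- simulate -----------------------------------------------------------
    sim_cfg = config.get("simulate", {}) or {}
    cohort_config = simulate.default_paper_like_config()
    for key in ("effect_size", "noise_sd", "genes_per_module", "n_background"):
        if key in sim_cfg:
            setattr(cohort_config, key, sim_cfg[key])
    cohort = simulate.generate_cohort(cohort_config, seed=stage_seed(master, "simulate"))
    train_ds = cohort.training_datasets
    report["stages"]["simulate"] = {
        "n_datasets": len(cohort.matrices),
        "n_samples": int(len(cohort.truth)),
        "n_sle": int((cohort.metadata["cohort"] == "SLE").sum()),
    }

    # --- enrichment scoring -------------------------------------------------
    g_cfg = config.get("gsva", {}) or {}
    scores_by_ds = score_cohort(cohort, kernel=g_cfg.get("kernel", "gaussian"),
                                tau=g_cfg.get("tau", 1.0))
    report["stages"]["gsva"] = {
        d: {"n_features": len(s.feature_ids), "n_samples": len(s.sample_ids)}
        for d, s in scores_by_ds.items()
    }

    # --- discovery ----------------------------------------------------------
    d_cfg = config.get("discover", {}) or {}
    sle_ids = cohort.metadata.index[cohort.metadata["cohort"] == "SLE"]
    disc = discover_endotypes(
        scores_by_ds, train_ds, seed=stage_seed(master, "discover"),
        n_restarts=d_cfg.get("restarts", 200),
        k_range=range(d_cfg.get("kmin", 2), d_cfg.get("kmax", 8) + 1),
        cut_height=d_cfg.get("cut_height", discovery.DEFAULT_CUT_HEIGHT),
        sle_only=sle_ids,
        features=common_features(scores_by_ds))
    consensus = disc["consensus"]
    features = disc["features"]
    report["stages"]["discover"] = {
        "per_dataset_k": {d: v["clustering"].k for d, v in disc["per_dataset"].items()},
        "n_consensus_endotypes": len(consensus.endotype_ids),
    }

    # final labels: k-means at the consensus count on concatenated training
    # scores, relabeled to consensus endotypes
    train_scores = concat_scores(scores_by_ds, train_ds, features)
    train_scores = train_scores[[c for c in train_scores.columns if c in sle_ids]]
    k_final = len(consensus.endotype_ids)
    final = discovery.kmeans(train_scores, k_final,
                             n_restarts=d_cfg.get("restarts", 200),
                             seed=stage_seed(master, "final-labels"))
    mapping = discovery.relabel_to_reference(final, consensus)["mapping"]
    labels = final.labels.map(mapping)
    report["stages"]["discover"]["final_label_counts"] = (
        labels.value_counts().sort_index().to_dict())

    # --- classification -----------------------------------------------------
    c_cfg = config.get("classify", {}) or {}
    c_seed = stage_seed(master, "classify")
    X = train_scores.to_numpy(dtype=float).T
    y = labels.to_numpy()
    tr_ids, val_ids = classify.split_train_validation(
        train_scores.columns, y, train_frac=c_cfg.get("train_frac", 0.8),
        seed=c_seed)
    tr_mask = train_scores.columns.isin(tr_ids)
    Xb, yb = classify.smote_oversample(X[tr_mask], y[tr_mask], seed=c_seed)
    spec = classify.ClassifierSpec(
        algorithm=c_cfg.get("algorithm", "random_forest"),
        scheme=c_cfg.get("scheme", "one_vs_one"), seed=c_seed)
    model = classify.train(spec, Xb, yb, feature_ids=features)
    val_mask = ~tr_mask
    pred = classify.predict(model, X[val_mask])
    ev = classify.evaluate(y[val_mask], pred, classify.class_scores(model, X[val_mask]))
    report["stages"]["classify"] = {
        "algorithm": spec.algorithm, "scheme": spec.scheme,
        "n_train": int(tr_mask.sum()), "n_validation": int(val_mask.sum()),
        "accuracy": ev.accuracy, "kappa": ev.kappa,
        "per_class": ev.per_class.round(4).to_dict(orient="index"),
    }

    # centroid transfer of unseen test datasets
    test_ds = [d for d in cohort.matrices if d not in train_ds]
    test_scores = concat_scores(scores_by_ds, test_ds, features)
    test_scores = test_scores[[c for c in test_scores.columns if c in sle_ids]]
    centroids = pd.DataFrame(
        {e: train_scores.loc[:, labels == e].mean(axis=1)
         for e in consensus.endotype_ids}).T
    transfer = classify.centroid_transfer(test_scores.to_numpy(dtype=float).T,
                                          centroids)
    transfer = pd.Series(transfer, index=test_scores.columns)
    report["stages"]["classify"]["test_label_counts"] = (
        transfer.value_counts().sort_index().to_dict())

    # --- imputation + LuCIS -------------------------------------------------
    l_seed = stage_seed(master, "lucis")
    reference = concat_scores(scores_by_ds, train_ds[:2],
                              scores_by_ds[train_ds[0]].feature_ids)
    all_feats = list(cohort.library.names)
    rules = derive_rules(reference, [f for f in all_feats
                                     if f not in features],
                         reference_dataset="+".join(train_ds[:2]))
    completed = {d: complete_scores(scores_by_ds[d].data, rules, all_feats)
                 for d in cohort.matrices}
    full_train = pd.concat([completed[d] for d in train_ds], axis=1)
    full_train = full_train[[c for c in full_train.columns if c in sle_ids]]
    # bookend fit on the two reference datasets (both contain the extremes)
    bookends = (consensus.endotype_ids[0], consensus.endotype_ids[-1])
    ref_samples = pd.Index(completed[train_ds[0]].columns).append(
        pd.Index(completed[train_ds[1]].columns))
    book_ids = [s for s in labels.index
                if labels[s] in bookends and s in set(ref_samples)]
    lmodel = lucis.fit_lucis(full_train[book_ids], labels[book_ids],
                             seed=l_seed, positive_label=bookends[1])
    all_scores = pd.concat([completed[d] for d in cohort.matrices], axis=1)
    lscores = lucis.compute_lucis(lucis.binarize_scores(all_scores), lmodel)
    by_endotype = lscores.loc[labels.index].groupby(labels)["normalized"].mean()
    report["stages"]["lucis"] = {
        "lambda": lmodel.lambda_,
        "max_score": lmodel.max_score,
        "mean_by_endotype": by_endotype.round(3).to_dict(),
        "sextile_counts": lscores["sextile"].value_counts().sort_index().to_dict(),
    }

    # --- clinical associations ---------------------------------------------
    meta = cohort.metadata
    sle_meta = meta[meta["cohort"] == "SLE"]
    endo_of = pd.concat([labels, transfer])
    sle_meta = sle_meta.loc[sle_meta.index.intersection(endo_of.index)]
    endo = endo_of.loc[sle_meta.index]
    groups = [sle_meta.loc[endo == e, "activity_score"].to_numpy()
              for e in sorted(endo.unique()) if (endo == e).sum() >= 2]
    kw = stats.kruskal_wallis(groups)
    is_a = (endo == consensus.endotype_ids[0])
    table = [[int((sle_meta.loc[is_a, "flare_52wk"] == 1).sum()),
              int((sle_meta.loc[is_a, "flare_52wk"] == 0).sum())],
             [int((sle_meta.loc[~is_a, "flare_52wk"] == 1).sum()),
              int((sle_meta.loc[~is_a, "flare_52wk"] == 0).sum())]]
    orr = stats.odds_ratio(table)
    sext = lscores.loc[sle_meta.index, "sextile"]
    succ, tot = [], []
    for s in range(1, 7):
        in_s = sle_meta[(sext == s).to_numpy()]
        if len(in_s):
            succ.append(int(in_s["flare_52wk"].sum()))
            tot.append(len(in_s))
    trend = stats.chi_square_trend(succ, tot)
    report["stages"]["stats"] = {
        "activity_kruskal_wallis": {"H": kw.statistic, "p": kw.p_value},
        "flare_endotype_A_vs_rest_OR": orr["odds_ratio"],
        "flare_trend_across_sextiles": {"chi2": trend.statistic, "p": trend.p_value},
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonify)
        endo_of.rename("endotype").to_csv(out_dir / "endotype_labels.tsv", sep="\t")
        lscores.to_csv(out_dir / "lucis_scores.tsv", sep="\t")
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
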