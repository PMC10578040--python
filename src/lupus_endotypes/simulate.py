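"""Synthetic multi-dataset lupus cohorts with planted endotype structure.

The generator emulates the statistical shape of a multi-platform blood
transcriptome compendium: several pseudo-datasets of log2 expression, each a
mix of patients drawn from latent endotypes with distinct module activation
patterns, a "least abnormal" endotype indistinguishable from healthy
controls, per-platform feature dropout (modules whose genes are not
measured), and clinical covariates statistically linked to endotype
severity.

Activation is planted at the gene level, so the enrichment engine is
exercised end to end; a fast score-level generator is also provided for
classifier unit tests.  Endotypes activate nested, increasing sets of
modules (A activates none), with a fixed minority of modules perturbed
downward (-1) the way lymphocyte signatures drop in active disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, ModuleLibrary

MODULE_NAMES = [
    # block 1: abnormal from endotype B onward
    "IFN", "Plasma_cell", "Myeloid_cell", "TNF",
    # block 2: from C
    "IG_chains", "Monocyte", "Neutrophil", "Inflammatory_cytokine",
    # block 3: from D
    "B_cell", "T_cell", "Granulocyte", "LDG",
    # block 4: from E
    "TCRA", "MHC_II", "gd_T_cell", "NK_cell",
    # block 5: from F
    "TCRAJ", "Dendritic_cell", "pDC", "Anti_inflammation",
    # block 6: from G
    "TCRB", "Cell_cycle", "Platelet", "Complement",
    # block 7: H only (includes one down-regulated module so the top
    # severity step carries a robust negative-direction differentiator)
    "TCRD", "Erythropoiesis", "Apoptosis", "Oxid_phos",
    # block 8: never abnormal
    "Treg", "Mito_dysfunction", "Unfolded_protein", "Lymphoid_other",
]

# modules perturbed downward when abnormal (lymphocyte-like depletion)
NEGATIVE_MODULES = {"T_cell", "NK_cell", "Apoptosis"}

# modules unmeasured on some platforms (score imputation targets)
DROPPABLE_MODULES = ["IG_chains", "TCRA", "TCRAJ", "TCRB", "TCRD", "Treg"]

ENDOTYPE_IDS = list("ABCDEFGH")


@dataclass
class DatasetSpec:
    name: str
    n_samples: int
    endotypes: list[str]                    # endotypes present in this cohort
    n_controls: int = 0
    dropped_modules: list[str] = field(default_factory=list)


@dataclass
class CohortConfig:
    n_modules: int = 32
    genes_per_module: int = 10
    n_background: int = 200
    activation: pd.DataFrame | None = None  # endotype x module in {-1,0,+1}
    effect_size: float = 1.5                # delta, log2 units
    noise_sd: float = 0.5                   # sigma
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    datasets: list[DatasetSpec] = field(default_factory=list)
    # clinical model: activity = a0 + a1 * n_abnormal_modules + noise
    activity_intercept: float = 2.0
    activity_slope: float = 0.4
    activity_noise_sd: float = 2.0
    # flare ~ Bernoulli(logistic(b0 + b1 * severity))
    flare_intercept: float = -2.5
    flare_slope: float = 0.4
    # responder ~ Bernoulli(logistic(c0 + c1 * severity + c2 * treated))
    response_intercept: float = -1.5
    response_severity_slope: float = 0.15
    response_treatment_effect: float = 0.8

    def __post_init__(self) -> None:
        if self.effect_size <= 0 or self.noise_sd <= 0:
            raise ValueError("effect_size and noise_sd must be positive")
        if self.activation is None:
            self.activation = default_activation(self.n_modules)
        if not (self.activation.to_numpy() == 0).all(axis=1).any():
            raise ValueError("at least one endotype must be all-zero (least abnormal)")
        for ds in self.datasets:
            bad = set(ds.dropped_modules) - set(self.activation.columns)
            if bad:
                raise ValueError(f"dataset {ds.name}: unknown dropped modules {bad}")
            if len(ds.dropped_modules) >= self.activation.shape[1]:
                raise ValueError(f"dataset {ds.name} drops every module")

    @property
    def module_names(self) -> list[str]:
        return list(self.activation.columns)

    @property
    def endotype_ids(self) -> list[str]:
        return list(self.activation.index)


def default_activation(n_modules: int = 32) -> pd.DataFrame:
    """Nested activation: endotype at severity e abnormalizes the first
    4*e modules (A none ... H 28), leaving the last block untouched."""
    if n_modules == 32:
        names = MODULE_NAMES
    else:
        names = [f"module_{i:02d}" for i in range(n_modules)]
    sign = np.array([-1 if n in NEGATIVE_MODULES else 1 for n in names])
    act = np.zeros((len(ENDOTYPE_IDS), n_modules), dtype=int)
    for e in range(len(ENDOTYPE_IDS)):
        k = min(4 * e, n_modules)
        act[e, :k] = sign[:k]
    return pd.DataFrame(act, index=ENDOTYPE_IDS, columns=names)


def default_paper_like_config() -> CohortConfig:
    """The study-shaped fixture: 32 modules, 8 endotypes, 17 pseudo-datasets
    at roughly 1/10 of the study's per-dataset sizes, planted effect 3x the
    noise SD, and exactly 6 modules droppable per platform restrictions.

    Every pseudo-dataset keeps the least abnormal endotype plus its most
    severe endotype and a few controls, anchoring the within-dataset rank
    statistics so the same endotype scores comparably across heterogeneous
    cohort compositions.
    """
    train = [
        DatasetSpec("ds01", 80, list("ABCEFH"), n_controls=8),
        DatasetSpec("ds02", 80, list("ABCDGH"), n_controls=8),
        DatasetSpec("ds03", 28, list("ABEFH"), n_controls=3,
                    dropped_modules=["IG_chains", "TCRAJ", "TCRB", "TCRD"]),
        DatasetSpec("ds04", 14, list("ACDG"), n_controls=2),
        DatasetSpec("ds05", 16, list("AEFGH"), n_controls=2,
                    dropped_modules=["Treg"]),
    ]
    test_specs = [
        ("ds06", 5, "ABC", ["TCRA"]),
        ("ds07", 5, "ABF", []),
        ("ds08", 5, "ACD", ["IG_chains", "TCRA"]),
        ("ds09", 6, "ABDE", []),
        ("ds10", 8, "ACEG", ["TCRAJ", "TCRD"]),
        ("ds11", 10, "ABCDH", ["Treg"]),
        ("ds12", 5, "ADG", []),
        ("ds13", 14, "ABCEFH", ["TCRB"]),
        ("ds14", 5, "ABE", []),
        ("ds15", 31, "ABCDEFGH", ["IG_chains"]),
        ("ds16", 18, "ABCDEG", ["TCRD", "Treg"]),
        ("ds17", 5, "ABH", []),
    ]
    test = [DatasetSpec(name, n, list(eids), n_controls=2, dropped_modules=drop)
            for name, n, eids, drop in test_specs]
    return CohortConfig(datasets=train + test)


@dataclass
class Cohort:
    matrices: dict[str, ExpressionMatrix]
    metadata: pd.DataFrame          # indexed by sample_id
    truth: pd.Series                # sample_id -> endotype letter / "control"
    library: ModuleLibrary
    config: CohortConfig
    seed: int

    @property
    def training_datasets(self) -> list[str]:
        return list(self.matrices)[:5]


def _make_library(config: CohortConfig) -> tuple[ModuleLibrary, list[str]]:
    modules = {}
    for name in config.module_names:
        modules[name] = {f"{name}.g{i:02d}" for i in range(config.genes_per_module)}
    background = [f"BG.g{i:03d}" for i in range(config.n_background)]
    return ModuleLibrary(modules, {n: "synthetic module" for n in modules}), background


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Draw a full multi-dataset cohort.

    Gene g of module m in sample s with endotype e is
    baseline_g + delta * activation(e, m) + N(0, sigma^2); background genes
    carry no endotype signal; controls are drawn from the all-zero profile.
    The same seed gives byte-identical output.
    """
    config = config or default_paper_like_config()
    if not config.datasets:
        raise ValueError("config declares no datasets")
    rng = np.random.default_rng(seed)
    library, background = _make_library(config)
    genes = [g for name in config.module_names
             for g in sorted(library.modules[name])] + background
    gene_module = {}
    for name in config.module_names:
        for g in library.modules[name]:
            gene_module[g] = name
    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes)),
        index=genes)
    act = config.activation
    severity = {e: i for i, e in enumerate(config.endotype_ids)}
    n_abnormal = (act != 0).sum(axis=1)

    matrices: dict[str, ExpressionMatrix] = {}
    meta_rows = []
    truth = {}
    ancestries = np.array(["EA", "AA", "Hispanic"])
    for ds in config.datasets:
        # near-equal allocation over the endotypes present, so every planted
        # endotype is actually represented; remainder assigned at random
        base, extra = divmod(ds.n_samples, len(ds.endotypes))
        eids = np.repeat(ds.endotypes, base)
        if extra:
            eids = np.concatenate([
                eids, rng.choice(ds.endotypes, size=extra, replace=False)])
        eids = rng.permutation(eids)
        eids = np.concatenate([eids, np.array(["control"] * ds.n_controls)])
        sample_ids = [f"{ds.name}_s{i:03d}" for i in range(len(eids))]
        keep_genes = [g for g in genes
                      if gene_module.get(g) not in ds.dropped_modules]
        mu = baseline.loc[keep_genes].to_numpy()
        X = rng.normal(0.0, config.noise_sd, size=(len(keep_genes), len(eids)))
        X += mu[:, None]
        # vectorized planted shift: per-gene module row of the activation
        # matrix, per-sample endotype column (controls = all-zero row)
        mod_idx = {m: k for k, m in enumerate(config.module_names)}
        act_ext = np.vstack([act.to_numpy(dtype=float),
                             np.zeros(act.shape[1])])  # last row = control
        e_idx = {e: i for i, e in enumerate(config.endotype_ids)}
        sample_rows = np.array([e_idx.get(e, len(e_idx)) for e in eids])
        gene_cols = np.array([mod_idx.get(gene_module.get(g), -1)
                              for g in keep_genes])
        act_cols = np.hstack([act_ext, np.zeros((act_ext.shape[0], 1))])  # -1 = background
        X += config.effect_size * act_cols[sample_rows][:, gene_cols].T
        matrices[ds.name] = ExpressionMatrix(
            pd.DataFrame(X, index=keep_genes, columns=sample_ids),
            dataset_id=ds.name)
        for sid, e in zip(sample_ids, eids):
            truth[sid] = e
            if e == "control":
                sev, n_ab = 0, 0
            else:
                sev, n_ab = severity[e], int(n_abnormal[e])
            activity = max(0.0, config.activity_intercept
                           + config.activity_slope * n_ab
                           + rng.normal(0, config.activity_noise_sd)) \
                if e != "control" else 0.0
            p_aa = 0.1 + 0.03 * sev
            p_hisp = 0.15
            ancestry = rng.choice(ancestries, p=[1 - p_aa - p_hisp, p_aa, p_hisp])
            treated = int(rng.random() < 0.5)
            flare = int(rng.random() < _logistic(
                config.flare_intercept + config.flare_slope * sev))
            responder = int(rng.random() < _logistic(
                config.response_intercept
                + config.response_severity_slope * sev
                + config.response_treatment_effect * treated))
            lymphopenia = int(rng.random() < _logistic(-2.0 + 0.3 * sev))
            meta_rows.append({
                "sample_id": sid,
                "dataset": ds.name,
                "cohort": "control" if e == "control" else "SLE",
                "activity_score": activity,
                "ancestry": ancestry,
                "lymphopenia": lymphopenia,
                "treatment_arm": "active" if treated else "placebo",
                "flare_52wk": flare,
                "responder": responder,
            })
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return Cohort(matrices=matrices, metadata=metadata,
                  truth=pd.Series(truth), library=library,
                  config=config, seed=seed)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_scores(activation: pd.DataFrame | None = None,
                    n_per_endotype: int = 30, es_scale: float = 0.6,
                    noise_sd: float = 0.1, seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Fast score-level generator for classifier unit tests: feature scores
    are activation * es_scale + Gaussian noise, clipped to [-1, 1].

    Returns (features x samples DataFrame, sample -> endotype labels).
    """
    activation = default_activation() if activation is None else activation
    rng = np.random.default_rng(seed)
    cols, labels, blocks = [], [], []
    for e in activation.index:
        base = activation.loc[e].to_numpy(dtype=float) * es_scale
        block = base[None, :] + rng.normal(0, noise_sd,
                                           size=(n_per_endotype, len(base)))
        blocks.append(block)
        labels += [e] * n_per_endotype
        cols += [f"{e}_s{i:03d}" for i in range(n_per_endotype)]
    X = np.clip(np.vstack(blocks), -1, 1).T
    return (pd.DataFrame(X, index=activation.columns, columns=cols),
            pd.Series(labels, index=cols))
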