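"""Shared fixtures: a small toy expression matrix and the study-shaped
synthetic cohort (generated once per session; several suites reuse it)."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from lupus_endotypes import pipeline, simulate
from lupus_endotypes.data_model import ExpressionMatrix, ModuleLibrary

logging.disable(logging.WARNING)

COHORT_SEED = 1


@pytest.fixture(scope="session")
def paper_like_cohort() -> simulate.Cohort:
    return simulate.generate_cohort(simulate.default_paper_like_config(),
                                    seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_scores(paper_like_cohort):
    """Per-dataset enrichment scores for the session cohort."""
    return pipeline.score_cohort(paper_like_cohort)


@pytest.fixture(scope="session")
def sle_samples(paper_like_cohort) -> pd.Index:
    meta = paper_like_cohort.metadata
    return meta.index[meta["cohort"] == "SLE"]


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i:02d}" for i in range(20)]
    samples = [f"s{j}" for j in range(6)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(8, 1, size=(20, 6)), index=genes, columns=samples),
        dataset_id="toy")


@pytest.fixture
def toy_library() -> ModuleLibrary:
    return ModuleLibrary({
        "setA": {"g00", "g01", "g02", "g03"},
        "setB": {"g10", "g11", "g12"},
    })
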