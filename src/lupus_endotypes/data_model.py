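"""Domain containers and text-format I/O for expression data, gene-set
libraries and per-sample metadata.

Expression matrices are always genes-in-rows (log2 units); any orientation
change downstream is explicit.  Duplicate gene or sample identifiers are
errors, never silently merged: merging changes within-sample ranks and hence
every enrichment score computed from the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class DataModelError(ValueError):
    """Raised on malformed inputs (duplicate ids, bad headers, non-numeric cells)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Values must be finite.
    dataset_id
        Name of the cohort/platform the matrix came from.
    """

    data: pd.DataFrame
    dataset_id: str = ""

    def __post_init__(self) -> None:
        idx = pd.Index(self.data.index.astype(str))
        cols = pd.Index(self.data.columns.astype(str))
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate gene identifiers: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataModelError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise DataModelError("expression values must be finite")
        self.data = self.data.copy()
        self.data.index = idx
        self.data.columns = cols
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ModuleLibrary:
    """Named gene sets (immune-cell / inflammatory-pathway modules).

    ``modules`` maps module name -> set of gene ids; insertion order is
    preserved and meaningful (panel order drives deterministic culling rules
    downstream).  Genes are expected to appear in at most one module, with
    rare documented exceptions (e.g. CD177 shared by granulocyte and
    neutrophil modules); this is not enforced.
    """

    modules: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.modules.items():
            if not genes:
                raise DataModelError(f"module {name!r} is empty")
        for name in self.modules:
            self.descriptions.setdefault(name, "")

    @property
    def names(self) -> list[str]:
        return list(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, name: str) -> set[str]:
        return self.modules[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModuleLibrary):
            return NotImplemented
        return self.names == other.names and all(
            self.modules[n] == other.modules[n] for n in self.modules
        )


@dataclass
class ScoreMatrix:
    """Per-sample module enrichment scores, features x samples, in [-1, 1]."""

    data: pd.DataFrame
    dataset_ids: pd.Series | None = None  # dataset of origin per sample
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1 - 1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise DataModelError("enrichment scores must lie in [-1, 1]")
        if self.dataset_ids is None:
            ds = self.provenance.get("dataset_id", "")
            self.dataset_ids = pd.Series(ds, index=self.data.columns, dtype=object)
        else:
            self.dataset_ids = self.dataset_ids.reindex(self.data.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, format: str = "tsv",
                           dataset_id: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV (header row = sample ids,
    first column = gene ids) or GCT 1.2/1.3.

    Duplicated gene rows raise an error naming the offending gene.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    elif format == "gct":
        df = _read_gct(path)
    else:
        raise DataModelError(f"unknown expression format {format!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataModelError(f"non-numeric expression cell in {path.name}: {exc}") from exc
    return ExpressionMatrix(df, dataset_id=dataset_id or path.stem)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise DataModelError(f"malformed GCT header {version!r} (expected #1.2 or #1.3)")
        dims = fh.readline().split("\t")
        if len(dims) < 2:
            raise DataModelError("malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    # GCT column 2 is a free-text description; extra 1.3 metadata columns are
    # not supported here.
    df = body.set_index(body.columns[0]).drop(columns=[body.columns[1]])
    if df.shape != (n_genes, n_samples):
        raise DataModelError(
            f"GCT header declares {n_genes}x{n_samples} but body is "
            f"{df.shape[0]}x{df.shape[1]}"
        )
    return df


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            format: str = "tsv") -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        matrix.data.to_csv(path, sep=sep, index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = matrix.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise DataModelError(f"unknown expression format {format!r}")


def read_gmt(path: str | Path) -> ModuleLibrary:
    """Read a GMT gene-set file: name, description, then >=1 gene per line."""
    modules: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataModelError(
                    f"GMT line {lineno} has {len(fields)} fields (need name, "
                    "description and at least one gene)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise DataModelError(f"GMT line {lineno}: module {name!r} has no genes")
            if name in modules:
                raise DataModelError(f"duplicate module name {name!r} at line {lineno}")
            modules[name] = set(genes)
            descriptions[name] = desc
    return ModuleLibrary(modules, descriptions)


def write_gmt(library: ModuleLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in library.names:
            genes = sorted(library.modules[name])
            fh.write("\t".join([name, library.descriptions.get(name, "")] + genes) + "\n")


def read_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a per-sample metadata table; requires a ``sample_id`` column,
    which becomes the index.  Missing values stay as NaN."""
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise DataModelError("metadata table must have a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataModelError(f"duplicate sample_id in metadata: {dups[:5]}")
    return df.set_index("sample_id")


def write_score_matrix(scores: ScoreMatrix, path: str | Path) -> None:
    scores.data.to_csv(path, sep="\t", index_label="feature_id")


def read_score_matrix(path: str | Path, dataset_id: str = "") -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(df, provenance={"dataset_id": dataset_id})


# ---------------------------------------------------------------------------
# gene-level filtering
# ---------------------------------------------------------------------------

def filter_low_iqr(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose across-sample interquartile range is zero.

    The IQR uses linear-interpolation quantiles (the common default).  Gene
    order is preserved; the operation is idempotent.  Raises if every gene is
    constant, since nothing downstream can rank an all-flat matrix.
    """
    if matrix.n_samples < 2:
        raise DataModelError("filter_low_iqr requires at least 2 samples")
    q75, q25 = np.percentile(matrix.values, [75, 25], axis=1, method="linear")
    keep = (q75 - q25) > 0
    if not keep.any():
        raise DataModelError(
            f"all {matrix.n_genes} genes have zero IQR in dataset "
            f"{matrix.dataset_id!r}; nothing to analyze"
        )
    return ExpressionMatrix(matrix.data.loc[keep], dataset_id=matrix.dataset_id)
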