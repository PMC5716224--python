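"""Core data model and I/O for expression matrices and sample metadata.

The universal currency of every pipeline stage is the
:class:`ExpressionMatrix`: a dense genes x samples numeric table with
ordered, unique gene and sample identifiers.  A :class:`Dataset` pairs a
matrix with a :class:`SampleMetadata` sheet whose rows are aligned,
one-to-one and in order, with the matrix columns.

Matrices move through four value spaces as the pipeline runs:

``counts``
    non-negative integers straight from quantification;
``raw``
    non-negative reals (e.g. after merging or rescaling counts);
``log``
    log2(x + pseudocount) transformed values;
``normalized``
    output of a column-wise normalization step.

The value space is carried on the matrix so downstream stages can check
they are being fed what they expect, but no stage silently re-transforms
data: transformations are always explicit calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_SPACES = ("counts", "raw", "log", "normalized")


class CellpipeError(ValueError):
    """Base class for all data-contract violations raised by this package."""


def _check_unique(ids, kind: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = seen.get(x, 0) + 1
    if dups:
        raise CellpipeError(
            f"duplicate {kind} identifier(s): {sorted(set(dups))}"
        )


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression table.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers (rows).
    sample_ids
        Ordered unique sample identifiers (columns).
    values
        Numeric array of shape ``(n_genes, n_samples)``; all entries
        finite.  Count/raw matrices must be non-negative.
    value_space
        One of ``counts``, ``raw``, ``log``, ``normalized``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_space: str = "raw"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CellpipeError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CellpipeError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise CellpipeError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.value_space not in VALUE_SPACES:
            raise CellpipeError(
                f"value_space must be one of {VALUE_SPACES}, got {self.value_space!r}"
            )
        if self.value_space in ("counts", "raw") and np.any(self.values < 0):
            raise CellpipeError(
                f"negative value in a {self.value_space!r} matrix"
            )

    # -- convenience -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids),
            self.values.copy(), self.value_space,
        )

    def with_values(self, values: np.ndarray, value_space: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids),
            values, value_space or self.value_space,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_space: str = "raw") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), value_space)

    def sample_index(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise CellpipeError(f"unknown sample id(s): {missing}")
        return np.array([pos[s] for s in ids], dtype=int)


@dataclass
class SampleMetadata:
    """Per-sample attribute table (groups, batches, ...). Values are strings."""

    sample_ids: list[str]
    columns: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        for name, col in self.columns.items():
            if len(col) != len(self.sample_ids):
                raise CellpipeError(
                    f"metadata column {name!r} has {len(col)} entries for "
                    f"{len(self.sample_ids)} samples"
                )
            self.columns[name] = [str(v) for v in col]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns, index=self.sample_ids)

    def subset(self, ids: list[str]) -> "SampleMetadata":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise CellpipeError(f"metadata is missing sample id(s): {missing}")
        idx = [pos[s] for s in ids]
        return SampleMetadata(
            list(ids),
            {name: [col[i] for i in idx] for name, col in self.columns.items()},
        )

    def with_column(self, name: str, values: list[str]) -> "SampleMetadata":
        cols = dict(self.columns)
        cols[name] = list(values)
        return SampleMetadata(list(self.sample_ids), cols)


@dataclass
class Dataset:
    """An expression matrix paired with sample metadata in matching order."""

    matrix: ExpressionMatrix
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        if self.metadata.sample_ids != self.matrix.sample_ids:
            raise CellpipeError(
                "metadata sample ids do not match matrix sample ids in order"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_table(path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, header=0, index_col=0, dtype=str)
    if df.index.name is None and df.shape[1] == 0:
        raise CellpipeError(f"{path}: empty or header-only file")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def read_expression_matrix(path, delimiter: str = ",") -> ExpressionMatrix:
    """Parse a delimited genes x samples table.

    Row 1 is the sample header, column 1 the gene identifiers; every body
    cell must be numeric.  Duplicate identifiers and non-numeric cells are
    hard errors that name the offender.
    """
    df = _read_table(path, delimiter)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise CellpipeError(f"{path}: expression matrix has no data body")
    _check_unique(list(df.index), "gene")
    _check_unique(list(df.columns), "sample")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j in range(df.shape[1]):
        try:
            # numpy's parser is correctly rounded, so %.17g output
            # round-trips bit-exactly
            values[:, j] = raw[:, j].astype(np.float64)
        except (ValueError, TypeError):
            col = pd.to_numeric(raw[:, j], errors="coerce").astype(float)
            i = int(np.argmax(~np.isfinite(col)))
            raise CellpipeError(
                f"{path}: non-numeric value {raw[i, j]!r} at gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            ) from None
    return ExpressionMatrix(list(df.index), list(df.columns), values, "raw")


def read_metadata(path, delimiter: str = ",") -> SampleMetadata:
    """Parse a metadata sheet: column 1 = sample id, header names attributes."""
    df = _read_table(path, delimiter)
    _check_unique(list(df.index), "sample")
    cols = {str(c): [("" if pd.isna(v) else str(v).strip()) for v in df[c]]
            for c in df.columns}
    return SampleMetadata(list(df.index), cols)


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str = ",") -> None:
    # %.17g guarantees exact binary round trip for float64
    matrix.to_frame().to_csv(path, sep=delimiter, float_format="%.17g",
                             index_label="gene")


def write_metadata(metadata: SampleMetadata, path, delimiter: str = ",") -> None:
    metadata.to_frame().to_csv(path, sep=delimiter, index_label="sample")


# ---------------------------------------------------------------------------
# Plumbing operations
# ---------------------------------------------------------------------------

def align(matrix: ExpressionMatrix, metadata: SampleMetadata) -> Dataset:
    """Pair a matrix with metadata, reordering metadata to the matrix order.

    The metadata may cover a superset of the matrix samples; extra rows are
    dropped with a logged warning.  A matrix sample absent from the
    metadata is an error.
    """
    extra = [s for s in metadata.sample_ids if s not in set(matrix.sample_ids)]
    if extra:
        logger.warning("dropping %d metadata row(s) not in matrix: %s",
                       len(extra), extra)
    meta = metadata.subset(matrix.sample_ids)
    return Dataset(matrix, meta)


def merge_datasets(datasets: list[Dataset], batch_column: str | None = None) -> Dataset:
    """Merge plates: gene intersection, sample concatenation, batch labels.

    Genes are intersected across datasets (kept in the first dataset's
    order); a union would fabricate zeros that later confound batch
    correction.  Unless ``batch_column`` names an existing metadata column
    to use, a ``batch`` column holding the 1-based dataset index is added.
    """
    if not datasets:
        raise CellpipeError("merge_datasets requires at least one dataset")
    all_ids = [s for d in datasets for s in d.matrix.sample_ids]
    _check_unique(all_ids, "sample")

    genes = list(datasets[0].matrix.gene_ids)
    keep = set(genes)
    for d in datasets[1:]:
        keep &= set(d.matrix.gene_ids)
    genes = [g for g in genes if g in keep]
    if not genes:
        raise CellpipeError("gene intersection across datasets is empty")
    logger.info("merging %d dataset(s): %d shared genes, %d samples",
                len(datasets), len(genes), len(all_ids))

    blocks = []
    for d in datasets:
        pos = {g: i for i, g in enumerate(d.matrix.gene_ids)}
        blocks.append(d.matrix.values[[pos[g] for g in genes], :])
    values = np.concatenate(blocks, axis=1)

    col_names: set[str] = set()
    for d in datasets:
        col_names |= set(d.metadata.columns)
    cols: dict[str, list[str]] = {name: [] for name in col_names}
    for d in datasets:
        for name in col_names:
            cols[name].extend(d.metadata.columns.get(name, [""] * d.n_samples))
    if batch_column is not None:
        if any(batch_column not in d.metadata.columns for d in datasets):
            raise CellpipeError(
                f"batch column {batch_column!r} missing from some metadata"
            )
    else:
        cols["batch"] = [str(i + 1) for i, d in enumerate(datasets)
                         for _ in range(d.n_samples)]
    space = datasets[0].matrix.value_space
    matrix = ExpressionMatrix(genes, all_ids, values, space)
    return Dataset(matrix, SampleMetadata(all_ids, cols))


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Element-wise ``log2(x + pseudocount)``; requires non-negative input."""
    if pseudocount <= 0:
        raise CellpipeError("pseudocount must be positive")
    if np.any(matrix.values < 0):
        raise CellpipeError("log_transform requires non-negative values")
    return matrix.with_values(np.log2(matrix.values + pseudocount), "log")


def remove_samples(dataset: Dataset, ids) -> Dataset:
    """Drop the given samples from matrix and metadata, preserving order."""
    ids = set(ids)
    unknown = ids - set(dataset.matrix.sample_ids)
    if unknown:
        raise CellpipeError(f"unknown sample id(s): {sorted(unknown)}")
    survivors = [s for s in dataset.matrix.sample_ids if s not in ids]
    if not survivors:
        raise CellpipeError("removing all samples would leave an empty dataset")
    idx = dataset.matrix.sample_index(survivors)
    matrix = ExpressionMatrix(
        list(dataset.matrix.gene_ids), survivors,
        dataset.matrix.values[:, idx], dataset.matrix.value_space,
    )
    return Dataset(matrix, dataset.metadata.subset(survivors))
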