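"""Quality control: outlier-cell detection and over-dispersion gene filtering.

Outlier detection scores each cell by the Euclidean norm of its expression
vector after every gene has been scaled to zero mean and unit standard
deviation; cells whose norm z-score is extreme (|z| above a threshold), or
the top-n cells by norm, are flagged.  The z-score rule is two-sided: an
abnormally low-expression cell compresses its whole profile toward the
zero-inflated floor and shows up as an unusually SMALL standardized norm,
while doublet-like or contaminated cells show up as unusually large ones,
so both tails carry real quality failures.

Gene filtering estimates a per-gene negative-binomial dispersion by method
of moments (Var = mu + phi * mu^2, so phi = (var - mu)/mu^2, clamped at
zero), fits the mean-dispersion trend phi_hat(mu) = a0 + a1/mu by least
squares, and keeps genes that exceed both a mean-expression threshold and
a multiple of their fitted trend dispersion — i.e. genes more variable
than the technical expectation at their expression level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import CellpipeError, Dataset, ExpressionMatrix, remove_samples

__all__ = [
    "OutlierReport", "DispersionTable", "DispersionTrend",
    "cell_norms", "detect_outliers", "remove_samples",
    "dispersion_table", "fit_dispersion_trend", "filter_genes",
]

logger = logging.getLogger(__name__)

FITTED_FLOOR = 1e-6


@dataclass
class OutlierReport:
    sample_ids: list[str]
    norms: np.ndarray
    zscores: np.ndarray
    flagged: list[str]
    mode: str = "z"
    value_space: str = "raw"

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "norms": self.norms.tolist(),
            "zscores": self.zscores.tolist(),
            "flagged": self.flagged,
            "mode": self.mode,
            "value_space": self.value_space,
        }


@dataclass
class DispersionTrend:
    a0: float
    a1: float

    def __call__(self, mean_expr: np.ndarray) -> np.ndarray:
        mu = np.asarray(mean_expr, dtype=float)
        with np.errstate(divide="ignore"):
            fitted = self.a0 + self.a1 / mu
        return np.maximum(fitted, FITTED_FLOOR)


@dataclass
class DispersionTable:
    gene_ids: list[str]
    mean_expr: np.ndarray
    dispersion: np.ndarray  # NaN where mean_expr == 0 (undefined)
    fitted: np.ndarray | None = None
    keep: np.ndarray | None = None
    summary: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return self.mean_expr > 0


def cell_norms(matrix: ExpressionMatrix) -> np.ndarray:
    """Euclidean norm per cell after per-gene standardization.

    Genes with zero standard deviation across samples carry no signal and
    are dropped before scaling (logged).
    """
    if matrix.n_samples < 2:
        raise CellpipeError("cell_norms requires at least 2 samples")
    X = matrix.values
    sd = X.std(axis=1, ddof=0)
    usable = sd > 0
    if not np.any(usable):
        raise CellpipeError("every gene has zero standard deviation")
    if not np.all(usable):
        logger.info("dropping %d zero-SD gene(s) before scaling",
                    int((~usable).sum()))
    Xs = X[usable]
    Z = (Xs - Xs.mean(axis=1, keepdims=True)) / sd[usable][:, None]
    return np.sqrt((Z ** 2).sum(axis=0))


def detect_outliers(
    norms: np.ndarray,
    sample_ids: list[str],
    z_threshold: float = 2.0,
    n_outliers: int | None = None,
    value_space: str = "raw",
) -> OutlierReport:
    """Flag outlier cells by norm z-score (two-sided), or the top-n norms.

    ``n_outliers`` overrides the z-score mode when given.  Ties in n-mode
    are broken by sample order (earlier samples flagged first).  If the
    norms have zero spread, z-mode flags nothing.
    """
    norms = np.asarray(norms, dtype=float)
    if len(sample_ids) != norms.size:
        raise CellpipeError("sample_ids and norms lengths differ")
    sd = norms.std(ddof=1) if norms.size > 1 else 0.0
    if sd > 0:
        z = (norms - norms.mean()) / sd
    else:
        z = np.zeros_like(norms)
    if n_outliers is not None:
        if n_outliers >= norms.size:
            raise CellpipeError(
                f"n_outliers={n_outliers} must be below the sample count {norms.size}"
            )
        # stable sort on -norm: earlier sample wins ties
        order = np.argsort(-norms, kind="stable")
        flagged = [sample_ids[i] for i in sorted(order[:n_outliers])]
        mode = "n"
    else:
        if norms.size < 3:
            raise CellpipeError("z-score mode requires at least 3 samples")
        if sd == 0:
            logger.info("norms have zero spread; no outliers flagged")
            flagged = []
        else:
            flagged = [s for s, zi in zip(sample_ids, z)
                       if abs(zi) > z_threshold]
        mode = "z"
    return OutlierReport(list(sample_ids), norms, z, flagged, mode, value_space)


def dispersion_table(counts: ExpressionMatrix) -> DispersionTable:
    """Method-of-moments NB dispersion per gene: phi = max(0, (var-mu)/mu^2).

    The sample variance (ddof=1) is used.  Genes with zero mean have
    undefined dispersion (NaN) and can never be kept.
    """
    if counts.value_space not in ("counts", "raw"):
        raise CellpipeError(
            "dispersion_table expects a counts/raw matrix, got "
            f"{counts.value_space!r}"
        )
    if counts.n_samples < 2:
        raise CellpipeError("dispersion_table requires at least 2 samples")
    mu = counts.values.mean(axis=1)
    var = counts.values.var(axis=1, ddof=1)
    phi = np.full_like(mu, np.nan)
    pos = mu > 0
    phi[pos] = np.maximum(0.0, (var[pos] - mu[pos]) / mu[pos] ** 2)
    return DispersionTable(list(counts.gene_ids), mu, phi)


def fit_dispersion_trend(table: DispersionTable) -> DispersionTrend:
    """Least-squares fit of phi = a0 + a1/mu over genes with phi > 0."""
    usable = (table.mean_expr > 0) & (np.nan_to_num(table.dispersion, nan=-1.0) > 0)
    if int(usable.sum()) < 3:
        raise CellpipeError(
            f"trend fit needs >= 3 genes with positive mean and dispersion, "
            f"got {int(usable.sum())}"
        )
    x = 1.0 / table.mean_expr[usable]
    y = table.dispersion[usable]
    A = np.column_stack([np.ones_like(x), x])
    (a0, a1), *_ = np.linalg.lstsq(A, y, rcond=None)
    return DispersionTrend(float(a0), float(a1))


def filter_genes(
    table: DispersionTable,
    trend: DispersionTrend,
    mean_threshold: float,
    dispersion_ratio: float = 1.0,
) -> DispersionTable:
    """Keep genes with mu > mean_threshold and phi > ratio * trend(mu)."""
    mu = table.mean_expr
    phi = table.dispersion
    fitted = np.full_like(mu, np.nan)
    defined = table.defined
    fitted[defined] = trend(mu[defined])
    keep = np.zeros(mu.size, dtype=bool)
    with np.errstate(invalid="ignore"):
        keep[defined] = (mu[defined] > mean_threshold) & (
            phi[defined] > dispersion_ratio * fitted[defined]
        )
    summary = {"n_kept": int(keep.sum()), "n_total": int(mu.size)}
    logger.info("gene filter keeps %d of %d genes", summary["n_kept"],
                summary["n_total"])
    return DispersionTable(list(table.gene_ids), mu, phi, fitted, keep, summary)


def apply_gene_filter(dataset: Dataset, table: DispersionTable) -> Dataset:
    """Subset a dataset to the kept genes of a filtered dispersion table."""
    if table.keep is None:
        raise CellpipeError("run filter_genes before applying the filter")
    if table.gene_ids != dataset.matrix.gene_ids:
        raise CellpipeError("dispersion table does not match the dataset genes")
    idx = np.flatnonzero(table.keep)
    if idx.size == 0:
        raise CellpipeError("gene filter would remove every gene")
    m = dataset.matrix
    matrix = ExpressionMatrix([m.gene_ids[i] for i in idx], list(m.sample_ids),
                              m.values[idx], m.value_space)
    return Dataset(matrix, dataset.metadata)
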