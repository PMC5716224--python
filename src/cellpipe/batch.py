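"""Batch-effect removal.

Two correctors are provided:

* :func:`median_align` — a multiplicative method.  Each sample's median
  expression ``med_i`` (over its strictly positive entries) is computed,
  each batch's level is summarised as the geometric mean of its members'
  medians, and every sample in batch *b* is multiplied by

      factor_b = geomMean_{i in 1..m}(med_i) / geomMean_{i in batch_b}(med_i)

  which pulls all batches to the global geometric mean of the sample
  medians.  The correction is a single per-batch scale: it preserves
  within-sample rank order exactly and is idempotent.

* :func:`eb_batch_adjust` — a parametric empirical-Bayes location/scale
  adjuster for log-scale data.  Per gene the data are standardized against
  the grand mean and pooled variance; per gene-and-batch a location
  (gamma) and scale (delta^2) effect is estimated, shrunk toward a normal
  / inverse-gamma prior whose hyperparameters come from method of moments
  across genes, and the shrunken effects are removed.

Sample medians are taken over strictly positive entries only: single-cell
matrices are zero-inflated, and a whole-column median of zero would make
the geometric mean undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import CellpipeError, ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class BatchAssignment:
    """One batch label per sample; every batch non-empty."""

    sample_ids: list[str]
    batch_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.batch_labels):
            raise CellpipeError("one batch label per sample is required")
        self.batch_labels = [str(b) for b in self.batch_labels]

    @property
    def batches(self) -> list[str]:
        seen: list[str] = []
        for b in self.batch_labels:
            if b not in seen:
                seen.append(b)
        return seen

    def members(self, batch: str) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.batch_labels) if b == batch])

    @classmethod
    def from_metadata(cls, metadata: SampleMetadata, column: str) -> "BatchAssignment":
        if column not in metadata.columns:
            raise CellpipeError(f"metadata has no column {column!r}")
        return cls(list(metadata.sample_ids), list(metadata.columns[column]))


@dataclass
class MedianAlignmentReport:
    sample_medians: dict[str, float]
    batch_means: dict[str, float]
    global_mean: float
    factors: dict[str, float]
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_medians": self.sample_medians,
            "batch_means": self.batch_means,
            "global_mean": self.global_mean,
            "factors": self.factors,
        }


def _geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def sample_medians(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-sample median over strictly positive entries (``med_i``)."""
    meds = np.empty(matrix.n_samples)
    for i in range(matrix.n_samples):
        col = matrix.values[:, i]
        pos = col[col > 0]
        if pos.size == 0:
            raise CellpipeError(
                f"sample {matrix.sample_ids[i]!r} has no positive entries; "
                "its median is undefined"
            )
        meds[i] = np.median(pos)
    return meds


def median_align(
    matrix: ExpressionMatrix, batches: BatchAssignment
) -> tuple[ExpressionMatrix, MedianAlignmentReport]:
    """Multiply each batch toward the global geometric mean of sample medians."""
    if batches.sample_ids != matrix.sample_ids:
        raise CellpipeError("batch assignment does not cover the matrix samples")
    meds = sample_medians(matrix)
    global_mean = _geometric_mean(meds)
    values = matrix.values.copy()
    batch_means: dict[str, float] = {}
    factors: dict[str, float] = {}
    for b in batches.batches:
        idx = batches.members(b)
        bm = _geometric_mean(meds[idx])
        f = global_mean / bm
        values[:, idx] *= f
        batch_means[b] = bm
        factors[b] = f
    report = MedianAlignmentReport(
        sample_medians=dict(zip(matrix.sample_ids, meds.tolist())),
        batch_means=batch_means,
        global_mean=global_mean,
        factors=factors,
    )
    return matrix.with_values(values), report


def eb_batch_adjust(
    matrix: ExpressionMatrix,
    batches: BatchAssignment,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Intended for log-scale data.  Requires at least two batches, each with
    at least two samples.  Genes with zero pooled variance are passed
    through unadjusted with a warning.
    """
    if batches.sample_ids != matrix.sample_ids:
        raise CellpipeError("batch assignment does not cover the matrix samples")
    labels = batches.batches
    if len(labels) < 2:
        raise CellpipeError("eb_batch_adjust requires at least two batches")
    idx_by_batch = {b: batches.members(b) for b in labels}
    for b, idx in idx_by_batch.items():
        if idx.size < 2:
            raise CellpipeError(f"batch {b!r} has fewer than 2 samples")

    Y = matrix.values  # genes x samples
    n, m = Y.shape
    n_b = np.array([idx_by_batch[b].size for b in labels], dtype=float)

    # per-gene batch means and grand mean weighted by batch size
    batch_mean = np.stack(
        [Y[:, idx_by_batch[b]].mean(axis=1) for b in labels], axis=1
    )  # genes x batches
    grand = batch_mean @ (n_b / m)

    resid = np.empty_like(Y)
    for k, b in enumerate(labels):
        idx = idx_by_batch[b]
        resid[:, idx] = Y[:, idx] - batch_mean[:, [k]]
    # var_pooled over all samples (divide by m, as in the classic EB adjuster)
    var_pooled = (resid ** 2).sum(axis=1) / m

    ok = var_pooled > 0
    if not np.all(ok):
        logger.warning("%d zero-variance gene(s) passed through unadjusted",
                       int((~ok).sum()))
    sd = np.sqrt(var_pooled[ok])
    Z = (Y[ok] - grand[ok, None]) / sd[:, None]

    out = Y.copy()
    Zadj = Z.copy()
    for k, b in enumerate(labels):
        idx = idx_by_batch[b]
        Zb = Z[:, idx]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)

        # method-of-moments hyperpriors across genes
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        if d_var <= 0:
            a_prior, b_prior = 0.0, 0.0
        else:
            a_prior = (2 * d_var + d_mean ** 2) / d_var
            b_prior = (d_mean * d_var + d_mean ** 3) / d_var

        nb = idx.size
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            if t2 > 0:
                g_new = (nb * t2 * gamma_hat + delta_star * gamma_bar) / (
                    nb * t2 + delta_star
                )
            else:
                g_new = np.full_like(gamma_hat, gamma_bar)
            sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            denom = nb / 2 + a_prior - 1
            if denom <= 0:
                d_new = delta_hat.copy()
            else:
                d_new = (0.5 * sse + b_prior) / denom
            change = np.max(np.abs(d_new - delta_star))
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break

        Zadj[:, idx] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out[ok] = Zadj * sd[:, None] + grand[ok, None]
    space = matrix.value_space if matrix.value_space == "log" else "normalized"
    return matrix.with_values(out, space)
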