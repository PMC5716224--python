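"""Column-wise normalization: quantile, geometric-mean alignment, size factors.

* :func:`quantile_normalize` forces every sample onto the identical value
  distribution (the rank-wise mean of the sorted columns), the classic
  rank-mean procedure.  Ties within a column are mapped to the mean of the
  reference values over the tie group's rank span.
* :func:`mean_align` multiplies each sample so that all samples share the
  same geometric mean of their strictly positive entries.
* :func:`size_factor_normalize` divides each sample by a median-of-ratios
  size factor: the median over genes of the sample's counts relative to a
  per-gene geometric-mean reference computed from genes expressed in all
  samples.  Factors are rescaled to geometric mean 1 so normalization only
  redistributes depth, never changes the overall scale.

Geometric means are taken over strictly positive entries only, because
single-cell matrices are zero-inflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CellpipeError, ExpressionMatrix


@dataclass
class SizeFactors:
    sample_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise CellpipeError("size factors must be strictly positive")

    def to_dict(self) -> dict:
        return {"sample_ids": self.sample_ids, "factors": self.factors.tolist()}


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic rank-mean quantile normalization across samples."""
    if matrix.n_samples < 2:
        raise CellpipeError("quantile_normalize requires at least 2 samples")
    X = matrix.values
    n, m = X.shape
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        i = 0
        while i < n:
            # tie group: identical values occupy a rank span; assign the
            # mean of the reference over that span to every member
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            mapped[order[i:k + 1]] = reference[i:k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    return matrix.with_values(out, "normalized")


def _positive_geomean(col: np.ndarray, label: str) -> float:
    pos = col[col > 0]
    if pos.size == 0:
        raise CellpipeError(f"sample {label!r} has no positive entries")
    return float(np.exp(np.mean(np.log(pos))))


def mean_align(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so all geometric means (positive entries) agree."""
    g = np.array([
        _positive_geomean(matrix.values[:, i], matrix.sample_ids[i])
        for i in range(matrix.n_samples)
    ])
    G = float(np.exp(np.mean(np.log(g))))
    factors = G / g
    return matrix.with_values(matrix.values * factors[None, :], "normalized")


def size_factors(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors, rescaled to geometric mean 1."""
    X = counts.values
    all_pos = np.all(X > 0, axis=1)
    if not np.any(all_pos):
        raise CellpipeError(
            "no gene is strictly positive in every sample; size factors "
            "are undefined"
        )
    logref = np.log(X[all_pos]).mean(axis=1)  # log geometric mean per gene
    ratios = np.log(X[all_pos]) - logref[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1
    return SizeFactors(list(counts.sample_ids), s)


def size_factor_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its median-of-ratios size factor."""
    sf = size_factors(counts)
    return counts.with_values(counts.values / sf.factors[None, :], "normalized")
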