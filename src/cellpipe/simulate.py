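"""Seeded generator of single-cell-like count matrices with known truth.

The generator emulates the generative skeleton of standard scRNA-seq
simulators: per-gene base means drawn log-normally, round-robin cluster
membership with a fraction of genes given a multiplicative fold change
per cluster, log-normal library-size factors, negative-binomial counts
(Var = mu + phi * mu^2; Poisson when phi = 0), and an optional logistic
dropout that zeroes entries with probability rising as the underlying
mean falls.  Batch scaling and low-expression outlier cells can be
injected afterwards so batch correction and outlier detection can be
exercised against known ground truth.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .batch import BatchAssignment
from .core import CellpipeError, Dataset, ExpressionMatrix, SampleMetadata


@dataclass
class SimulationParams:
    """Simulation settings.

    Defaults model a modest droplet-style experiment: 1000 genes, 200
    cells in 3 clusters, 10% of genes per cluster up-regulated 8-fold,
    moderate over-dispersion (phi = 0.5), 20% log-library-size spread,
    and a dropout curve centred near the low-expression end.
    """

    n_genes: int = 1000
    n_cells: int = 200
    k_clusters: int = 3
    de_fraction: float = 0.1
    effect_size: float = 8.0
    mean_log_mu: float = 0.5
    sd_log_mu: float = 1.0
    dispersion: float = 0.5
    lib_sd: float = 0.2
    dropout_midpoint: float | None = 1.0   # None disables dropout
    dropout_slope: float = 1.0
    batch_factors: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1 or self.k_clusters < 1:
            raise CellpipeError("sizes must be >= 1")
        if self.k_clusters > self.n_cells:
            raise CellpipeError("more clusters than cells")
        if self.effect_size <= 1:
            raise CellpipeError("effect_size must exceed 1")
        if not (0 <= self.de_fraction <= 1):
            raise CellpipeError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0 or self.lib_sd < 0:
            raise CellpipeError("dispersion and lib_sd must be >= 0")


@dataclass
class SimulationTruth:
    cluster_labels: list[int]
    batch_labels: list[str]
    de_genes: dict[int, list[str]]
    outlier_cells: list[str] = field(default_factory=list)
    size_factors: list[float] = field(default_factory=list)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean).astype(float)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate_dataset(params: SimulationParams) -> tuple[Dataset, SimulationTruth]:
    """Draw a counts Dataset plus its ground truth, deterministically."""
    rng = np.random.default_rng(params.seed)
    n, m, k = params.n_genes, params.n_cells, params.k_clusters

    gene_ids = [f"g{i + 1}" for i in range(n)]
    cell_ids = [f"c{j + 1}" for j in range(m)]
    clusters = [(j % k) + 1 for j in range(m)]

    mu = rng.lognormal(params.mean_log_mu, params.sd_log_mu, size=n)

    # disjoint blocks of up-regulated genes per cluster keep clusters separable
    n_de = int(round(params.de_fraction * n))
    perm = rng.permutation(n)
    de_genes: dict[int, list[str]] = {}
    effect = np.ones((n, k))
    for c in range(k):
        block = perm[c * n_de: (c + 1) * n_de]
        effect[block, c] = params.effect_size
        de_genes[c + 1] = [gene_ids[g] for g in sorted(block)]

    lib = rng.lognormal(0.0, params.lib_sd, size=m) if params.lib_sd > 0 else np.ones(m)

    cl = np.array(clusters) - 1
    mean = mu[:, None] * effect[:, cl] * lib[None, :]
    counts = _nb_draw(rng, mean, params.dispersion)

    if params.dropout_midpoint is not None:
        x = params.dropout_slope * (params.dropout_midpoint - np.log(mean + 1))
        p_drop = 1.0 / (1.0 + np.exp(-x))
        counts[rng.random(size=counts.shape) < p_drop] = 0.0

    matrix = ExpressionMatrix(gene_ids, cell_ids, counts, "counts")
    meta = SampleMetadata(cell_ids, {"cluster": [str(c) for c in clusters]})

    batch_labels = ["1"] * m
    if params.batch_factors:
        nb = len(params.batch_factors)
        batch_labels = [str((j % nb) + 1) for j in range(m)]
        for b, f in enumerate(params.batch_factors, start=1):
            idx = [j for j, lab in enumerate(batch_labels) if lab == str(b)]
            matrix.values[:, idx] *= f
        matrix = ExpressionMatrix(gene_ids, cell_ids, matrix.values, "raw")
        meta = meta.with_column("batch", batch_labels)

    truth = SimulationTruth(
        cluster_labels=clusters,
        batch_labels=batch_labels,
        de_genes=de_genes,
        size_factors=lib.tolist(),
    )
    return Dataset(matrix, meta), truth


def inject_batch_scaling(
    dataset: Dataset, factor: float = 3.0, fraction: float = 0.5, seed: int = 0
) -> tuple[Dataset, BatchAssignment]:
    """Multiply a random fraction of cells by a constant, creating two
    artificial batches (label 1 untouched, label 2 scaled)."""
    if factor <= 0:
        raise CellpipeError("factor must be positive")
    m = dataset.n_samples
    rng = np.random.default_rng(seed)
    n_scaled = int(round(fraction * m))
    scaled = np.zeros(m, dtype=bool)
    scaled[rng.choice(m, size=n_scaled, replace=False)] = True

    values = dataset.matrix.values.copy()
    values[:, scaled] *= factor
    labels = ["2" if s else "1" for s in scaled]
    matrix = ExpressionMatrix(
        list(dataset.matrix.gene_ids), list(dataset.matrix.sample_ids),
        values, dataset.matrix.value_space,
    )
    meta = dataset.metadata.with_column("batch", labels)
    return Dataset(matrix, meta), BatchAssignment(list(matrix.sample_ids), labels)


def inject_outliers(
    dataset: Dataset,
    truth: SimulationTruth,
    n: int,
    scale: float = 5.0,
    seed: int = 0,
) -> tuple[Dataset, SimulationTruth]:
    """Divide n random cells by ``scale``, making low-expression outliers."""
    if scale <= 0:
        raise CellpipeError("scale must be positive")
    m = dataset.n_samples
    if n >= m:
        raise CellpipeError(f"n={n} outliers requires fewer than {m} cells")
    if n == 0:
        return dataset, truth
    rng = np.random.default_rng(seed)
    idx = rng.choice(m, size=n, replace=False)
    values = dataset.matrix.values.copy()
    values[:, idx] /= scale
    space = dataset.matrix.value_space
    matrix = ExpressionMatrix(
        list(dataset.matrix.gene_ids), list(dataset.matrix.sample_ids),
        values, "raw" if space == "counts" else space,
    )
    outliers = sorted(
        set(truth.outlier_cells) | {dataset.matrix.sample_ids[i] for i in idx}
    )
    return (
        Dataset(matrix, dataset.metadata),
        replace(truth, outlier_cells=outliers),
    )
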