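"""Embeddings, clustering, and automatic cluster-number selection.

Samples are embedded either by PCA (genes as variables, per-gene
centering, scores on the two largest-variance components) or by t-SNE run
on a precomputed correlation distance matrix

    D_ij = 1 - PearsonCorrelation(sample_i, sample_j),

which emphasises expression-profile shape over magnitude.  Clustering is
k-means, agglomerative (hclust), or NMF with the argmax-membership rule:
the log matrix (genes x samples) is factorized into non-negative H
(genes x k) and W (k x samples) and sample j joins the cluster of the
largest entry in column j of W.

The number of clusters is chosen by an elbow criterion on the
explained-variance curve EV(k) = 1 - within-SS / total-SS: a one-parameter
piecewise-linear model f(k) = beta * min(k, m) — rising through the origin
up to a breakpoint m, flat afterwards — is fit for every candidate
breakpoint, and the m with the best coefficient of determination R^2 is
the elbow.  The model is anchored at the origin and continuous at the
breakpoint, which reduces the fit to the closed form
beta = sum(EV_k * min(k,m)) / sum(min(k,m)^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF, PCA
from sklearn.manifold import TSNE

from .core import CellpipeError, ExpressionMatrix

logger = logging.getLogger(__name__)

CLUSTER_METHODS = ("kmeans", "hclust", "nmf", "kmeans_tsne", "hclust_tsne")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.sample_ids)
        if self.values.shape != (m, m):
            raise CellpipeError("distance matrix shape does not match sample ids")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise CellpipeError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise CellpipeError("distance matrix diagonal must be zero")


@dataclass
class Embedding:
    sample_ids: list[str]
    coords: np.ndarray  # m x 2
    method: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sample_ids), 2):
            raise CellpipeError("embedding must be m x 2")
        if not np.all(np.isfinite(self.coords)):
            raise CellpipeError("embedding coordinates must be finite")


@dataclass
class ClusterAssignment:
    sample_ids: list[str]
    labels: np.ndarray  # 1..k
    k: int
    method: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size != len(self.sample_ids):
            raise CellpipeError("one label per sample is required")
        present = set(self.labels.tolist())
        if present != set(range(1, self.k + 1)):
            raise CellpipeError(
                f"labels must cover 1..{self.k} with no empty cluster; "
                f"got {sorted(present)}"
            )

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class EVProfile:
    ks: list[int]
    ev: list[float]
    elbow: int
    r2_by_m: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"ks": self.ks, "ev": self.ev, "elbow": self.elbow,
                "r2_by_m": {str(k): v for k, v in self.r2_by_m.items()}}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _renumber(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber arbitrary labels to 1..k by order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out, len(mapping)


def as_coords(X) -> tuple[np.ndarray, list[str]]:
    """Resolve matrix-of-coordinates inputs to (samples x features, ids).

    Accepts an :class:`Embedding` (its 2-D coords), an
    :class:`ExpressionMatrix` (samples as rows, genes as features), or a
    plain samples-by-features array.
    """
    if isinstance(X, Embedding):
        return X.coords, list(X.sample_ids)
    if isinstance(X, ExpressionMatrix):
        return X.values.T, list(X.sample_ids)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise CellpipeError("coordinates must be 2-D")
    return arr, [str(i) for i in range(arr.shape[0])]


# ---------------------------------------------------------------------------
# dimension reduction
# ---------------------------------------------------------------------------

def select_top_genes(matrix: ExpressionMatrix, n: int = 500) -> ExpressionMatrix:
    """Keep the n genes with largest mean expression (ties: earlier gene)."""
    if n < 2:
        raise CellpipeError("select_top_genes requires n >= 2")
    if matrix.n_genes <= n:
        return matrix
    means = matrix.values.mean(axis=1)
    order = np.argsort(-means, kind="stable")[:n]
    idx = np.sort(order)  # preserve original gene order among the kept
    return ExpressionMatrix(
        [matrix.gene_ids[i] for i in idx], list(matrix.sample_ids),
        matrix.values[idx], matrix.value_space,
    )


def correlation_distance(matrix: ExpressionMatrix) -> DistanceMatrix:
    """1 - Pearson correlation between sample columns."""
    if matrix.n_samples < 2:
        raise CellpipeError("correlation_distance requires at least 2 samples")
    sd = matrix.values.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = [matrix.sample_ids[i] for i in const]
        raise CellpipeError(
            f"constant sample column(s) have undefined correlation: {names}"
        )
    C = np.corrcoef(matrix.values, rowvar=False)
    D = 1.0 - C
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(matrix.sample_ids), D)


def pca_embed(matrix: ExpressionMatrix) -> Embedding:
    """Scores on the two largest-variance principal components.

    Samples are the observations, genes the variables; per-gene centering.
    Sign convention: the loading of largest magnitude in each component is
    made positive, so embeddings are reproducible across runs.
    """
    if matrix.n_samples < 2 or matrix.n_genes < 2:
        raise CellpipeError("pca_embed requires >= 2 samples and >= 2 genes")
    X = matrix.values.T  # samples x genes
    n_comp = min(2, matrix.n_samples, matrix.n_genes)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    for c in range(scores.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    if scores.shape[1] < 2 or pca.explained_variance_[-1] <= 1e-12:
        logger.info("fewer than 2 non-degenerate components; padding zeros")
        padded = np.zeros((X.shape[0], 2))
        padded[:, : scores.shape[1]] = scores
        if scores.shape[1] == 2 and pca.explained_variance_[1] <= 1e-12:
            padded[:, 1] = 0.0
        scores = padded
    return Embedding(list(matrix.sample_ids), scores[:, :2], "pca")


def tsne_embed(dist: DistanceMatrix, seed: int, perplexity: float = 30.0,
               max_iter: int = 1000) -> Embedding:
    """2-D t-SNE from a precomputed distance matrix; deterministic per seed."""
    m = len(dist.sample_ids)
    if m < 4:
        raise CellpipeError("tsne_embed requires at least 4 samples")
    bound = (m - 1) / 3.0
    if perplexity >= bound:
        raise CellpipeError(
            f"perplexity must be below (m-1)/3 = {bound:.3f} for m={m}"
        )
    tsne = TSNE(
        n_components=2, metric="precomputed", init="random",
        random_state=int(seed), perplexity=float(perplexity),
        max_iter=int(max_iter),
    )
    coords = tsne.fit_transform(dist.values)
    return Embedding(list(dist.sample_ids), coords, "tsne")


def default_perplexity(m: int) -> float:
    """A perplexity safely inside the (m-1)/3 validity bound (cap 30)."""
    return min(30.0, 0.75 * (m - 1) / 3.0)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_kmeans(X, k: int, seed: int, n_restarts: int = 10) -> ClusterAssignment:
    """Best-of-restarts k-means on sample coordinates."""
    coords, ids = as_coords(X)
    m = coords.shape[0]
    if k < 2 or k > m:
        raise CellpipeError(f"k must be in [2, {m}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed))
    raw = km.fit_predict(coords)
    labels, k_eff = _renumber(raw)
    return ClusterAssignment(ids, labels, k_eff, "kmeans")


def cluster_hclust(X, k: int, linkage: str = "complete") -> ClusterAssignment:
    """Agglomerative clustering; the tree is cut into k groups."""
    if isinstance(X, DistanceMatrix):
        ids = list(X.sample_ids)
        m = len(ids)
        if k > m:
            raise CellpipeError(f"k={k} exceeds sample count {m}")
        Z = scipy_linkage(squareform(X.values, checks=False), method=linkage)
    else:
        coords, ids = as_coords(X)
        m = coords.shape[0]
        if k > m:
            raise CellpipeError(f"k={k} exceeds sample count {m}")
        Z = scipy_linkage(coords, method=linkage)
    if k < 2:
        raise CellpipeError("k must be >= 2")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels, k_eff = _renumber(raw)
    return ClusterAssignment(ids, labels, k_eff, "hclust")


def cluster_nmf(log_matrix: ExpressionMatrix, k: int, seed: int,
                max_iter: int = 500) -> ClusterAssignment:
    """NMF clustering: argmax over the k rows of W for each sample column.

    Ties in a column resolve to the lowest row index (argmax convention).
    """
    if np.any(log_matrix.values < 0):
        raise CellpipeError("NMF requires a non-negative matrix")
    if k < 2 or k > log_matrix.n_samples:
        raise CellpipeError(
            f"k must be in [2, {log_matrix.n_samples}], got {k}"
        )
    model = NMF(n_components=k, init="nndsvda", random_state=int(seed),
                max_iter=max_iter, tol=1e-6)
    # factorize genes x samples: H is genes x k, W is k x samples
    H = model.fit_transform(log_matrix.values)
    W = model.components_
    raw = np.argmax(W, axis=0) + 1
    labels, k_eff = _renumber(raw)
    return ClusterAssignment(list(log_matrix.sample_ids), labels, k_eff, "nmf")


def explained_variance(X, assignment: ClusterAssignment) -> float:
    """EV = 1 - sum of within-cluster SS / total SS about the grand centroid."""
    coords, ids = as_coords(X)
    if coords.shape[0] != len(assignment.sample_ids):
        raise CellpipeError("assignment does not cover the coordinates")
    grand = coords.mean(axis=0)
    total = float(((coords - grand) ** 2).sum())
    if total == 0:
        raise CellpipeError("total sum of squares is zero; EV undefined")
    within = 0.0
    for lab in range(1, assignment.k + 1):
        idx = assignment.members(lab)
        centroid = coords[idx].mean(axis=0)
        within += float(((coords[idx] - centroid) ** 2).sum())
    return 1.0 - within / total


def elbow_point(ks, ev) -> tuple[int, dict[int, float]]:
    """Breakpoint of the best-fitting rise-then-plateau model of EV(k).

    For each candidate m in 1..max(ks), fit f(k) = beta * min(k, m) with
    beta >= 0 by least squares (closed form) and score it by R^2; return
    the m with the largest R^2, smallest m on ties.  A flat EV curve
    (zero total variance) returns min(ks).
    """
    ks = np.asarray(list(ks), dtype=int)
    ev = np.asarray(list(ev), dtype=float)
    if ks.size != ev.size:
        raise CellpipeError("ks and ev lengths differ")
    if ks.size < 3:
        raise CellpipeError("elbow_point requires at least 3 (k, EV) points")
    sst = float(((ev - ev.mean()) ** 2).sum())
    if sst == 0:
        return int(ks.min()), {}
    best_m, best_r2 = None, -np.inf
    r2_by_m: dict[int, float] = {}
    for m in range(1, int(ks.max()) + 1):
        x = np.minimum(ks, m).astype(float)
        denom = float((x ** 2).sum())
        beta = max(0.0, float((ev * x).sum()) / denom) if denom > 0 else 0.0
        ssr = float(((ev - beta * x) ** 2).sum())
        r2 = 1.0 - ssr / sst
        r2_by_m[m] = r2
        if r2 > best_r2 + 1e-15:
            best_m, best_r2 = m, r2
    return int(best_m), r2_by_m


def auto_cluster(
    data,
    method: str,
    seed: int,
    k_range=range(2, 11),
    linkage: str = "complete",
    perplexity: float | None = None,
) -> tuple[ClusterAssignment, EVProfile]:
    """Cluster at every k in k_range and pick k by the elbow of EV(k).

    ``data`` is an ExpressionMatrix (log scale recommended; required for
    nmf and the *_tsne variants) or precomputed coordinates.  EV is always
    computed on the same coordinates the clusterer saw.  The elbow
    breakpoint is clamped into [min(k_range), max(k_range)].
    """
    if method not in CLUSTER_METHODS:
        raise CellpipeError(f"unknown method {method!r}; pick from {CLUSTER_METHODS}")
    ks = sorted(int(k) for k in k_range)

    if method.endswith("_tsne"):
        if not isinstance(data, ExpressionMatrix):
            raise CellpipeError("*_tsne methods need an ExpressionMatrix input")
        dist = correlation_distance(data)
        p = perplexity if perplexity is not None else default_perplexity(data.n_samples)
        emb = tsne_embed(dist, seed=seed, perplexity=p)
        coords_input = emb
        base = method[: -len("_tsne")]
    else:
        coords_input = data
        base = method

    coords, _ids = as_coords(coords_input)
    m = coords.shape[0]
    if max(ks) > m:
        raise CellpipeError(f"max k {max(ks)} exceeds sample count {m}")

    assignments: dict[int, ClusterAssignment] = {}
    evs: list[float] = []
    for k in ks:
        if base == "kmeans":
            a = cluster_kmeans(coords_input, k, seed=seed)
        elif base == "hclust":
            a = cluster_hclust(coords_input, k, linkage=linkage)
        elif base == "nmf":
            if not isinstance(data, ExpressionMatrix):
                raise CellpipeError("nmf needs an ExpressionMatrix input")
            a = cluster_nmf(data, k, seed=seed)
        else:  # pragma: no cover
            raise CellpipeError(f"unhandled method {base!r}")
        assignments[k] = a
        evs.append(explained_variance(coords_input, a))

    elbow, r2_by_m = elbow_point(ks, evs)
    k_star = int(np.clip(elbow, min(ks), max(ks)))
    if k_star not in assignments:  # elbow between grid points cannot occur,
        k_star = min(ks, key=lambda k: abs(k - k_star))  # but guard anyway
    profile = EVProfile(ks, evs, k_star, r2_by_m)
    logger.info("auto_cluster(%s): elbow at m=%d, selected k*=%d",
                method, elbow, k_star)
    return assignments[k_star], profile
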