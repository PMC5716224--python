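"""Differential-expression ranking and gene-set enrichment analysis.

The built-in per-gene statistic is a signed z-score derived from a Welch
t-test on log expression between two sample groups ("welch-z" in all
outputs): the two-sided p-value of the Welch t is mapped through the
standard-normal quantile and given the t's sign, so scores from genes
with very different within-group variances live on a common N(0,1)
scale.  Positive scores mean higher expression in the first group.  With
more than two clusters, every unordered cluster pair gets its own ranked
list.

GSEA scores a gene set against a ranked list with the classic weighted
running sum: walking the genes in decreasing-statistic order, a gene in
the set ("hit") moves the sum up by |stat|^w / N_R (N_R the sum of
|stat|^w over hits), any other gene moves it down by 1/(N - N_hits); the
enrichment score is the extreme of largest magnitude, signed.  Empirical
p-values come from a gene-label permutation null — random same-size gene
sets drawn from the ranking — as the two-sided tail probability of |ES|
(the signed ES preserves direction), with the +1/(n+1) convention so p is
never zero and is exactly uniform under a null ranking.  Benjamini-
Hochberg adjustment is applied across the retained sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CellpipeError, ExpressionMatrix
from .reduce_cluster import ClusterAssignment

logger = logging.getLogger(__name__)

Z_CAP = 38.0
DE_STAT_NAME = "welch-z"


@dataclass
class RankedGeneList:
    """Genes sorted by a signed score, descending; ties keep gene order."""

    gene_ids: list[str]
    stat: np.ndarray
    pair: tuple[str, str] = ("group_a", "group_b")

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float)
        if self.stat.size != len(self.gene_ids):
            raise CellpipeError("one statistic per gene is required")
        if not np.all(np.isfinite(self.stat)):
            raise CellpipeError("statistics must be finite")
        order = np.argsort(-self.stat, kind="stable")
        self.gene_ids = [self.gene_ids[i] for i in order]
        self.stat = self.stat[order]


@dataclass
class GeneSetCollection:
    set_names: list[str]
    members: dict[str, frozenset]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.set_names)) != len(self.set_names):
            raise CellpipeError("gene set names must be unique")
        for name in self.set_names:
            if not self.members[name]:
                raise CellpipeError(f"gene set {name!r} is empty")


@dataclass
class GseaResult:
    set_name: str
    es: float
    size: int
    p: float
    q: float


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def welch_z(a: np.ndarray, b: np.ndarray, z_cap: float = Z_CAP) -> np.ndarray:
    """Row-wise Welch t converted to a signed normal z-score.

    a, b: genes x samples blocks.  Zero variance in both groups gives z=0
    for equal means and +/- z_cap for unequal means (an infinitely
    confident call, capped).
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    d = ma - mb
    se2 = va / na + vb / nb
    z = np.zeros(d.size)

    degen = se2 == 0
    z[degen & (d > 0)] = z_cap
    z[degen & (d < 0)] = -z_cap

    reg = ~degen
    if np.any(reg):
        t = d[reg] / np.sqrt(se2[reg])
        df = se2[reg] ** 2 / (
            (va[reg] / na) ** 2 / (na - 1) + (vb[reg] / nb) ** 2 / (nb - 1)
        )
        # two-sided p through the normal quantile, sign restored from t
        logp_half = stats.t.logsf(np.abs(t), df)
        zmag = -stats.norm.ppf(np.exp(np.clip(logp_half, -700, 0)))
        zmag = np.clip(np.nan_to_num(zmag, posinf=z_cap), 0, z_cap)
        z[reg] = np.sign(t) * zmag
    return z


def de_two_group(
    log_matrix: ExpressionMatrix, group_a, group_b,
    pair: tuple[str, str] = ("group_a", "group_b"),
) -> RankedGeneList:
    """Rank genes by the welch-z statistic between two sample groups."""
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise CellpipeError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise CellpipeError("each group needs at least 2 samples")
    ia = log_matrix.sample_index(group_a)
    ib = log_matrix.sample_index(group_b)
    z = welch_z(log_matrix.values[:, ia], log_matrix.values[:, ib])
    return RankedGeneList(list(log_matrix.gene_ids), z, pair)


def de_pairwise(
    log_matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    n_workers: int = 1,
) -> dict[tuple[str, str], RankedGeneList]:
    """One ranked list per unordered cluster pair; worker count never
    changes the result, only the wall time."""
    if assignment.sample_ids != log_matrix.sample_ids:
        raise CellpipeError("assignment does not cover the matrix samples")
    if assignment.k < 2:
        raise CellpipeError("pairwise DE needs at least 2 clusters")
    groups = {
        lab: [assignment.sample_ids[i] for i in assignment.members(lab)]
        for lab in range(1, assignment.k + 1)
    }
    pairs = []
    for a, b in itertools.combinations(sorted(groups), 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            logger.warning("skipping pair (%s, %s): a cluster has <2 samples", a, b)
            continue
        pairs.append((a, b))
    tasks = (
        delayed(de_two_group)(log_matrix, groups[a], groups[b], (str(a), str(b)))
        for a, b in pairs
    )
    results = Parallel(n_jobs=n_workers)(tasks)
    return {(str(a), str(b)): r for (a, b), r in zip(pairs, results)}


def write_de_csv(ranked: RankedGeneList, path) -> None:
    df = pd.DataFrame({
        "gene": ranked.gene_ids,
        "stat": ranked.stat,
        "pair": f"{ranked.pair[0]} vs {ranked.pair[1]}",
        "statistic": DE_STAT_NAME,
    })
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise CellpipeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-delimited GMT file: name, description, members..."""
    names: list[str] = []
    members: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CellpipeError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            if name in members:
                raise CellpipeError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g.strip() for g in genes if g.strip()]
            names.append(name)
            members[name] = frozenset(genes)
            descriptions[name] = desc
    return GeneSetCollection(names, members, descriptions)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _es_from_hits(weights: np.ndarray, hit_pos: np.ndarray, n_total: int) -> np.ndarray:
    """Enrichment scores for a batch of equally-sized hit-position sets.

    weights: |stat|^w for the full ranking (length n_total, descending
    stat order).  hit_pos: (B, s) row-sorted 0-based positions.  Only the
    running-sum values adjacent to hits can be extremes, so the full walk
    never needs materialising.
    """
    hit_pos = np.atleast_2d(hit_pos)
    B, s = hit_pos.shape
    if s >= n_total:
        raise CellpipeError("a set covering all ranked genes has no misses")
    w = weights[hit_pos]
    nr = w.sum(axis=1, keepdims=True)
    zero_nr = nr[:, 0] == 0
    if np.any(zero_nr):
        # all-zero statistics in the set: fall back to equal hit increments
        w[zero_nr] = 1.0
        nr[zero_nr] = s
    cum = np.cumsum(w, axis=1) / nr
    miss = 1.0 / (n_total - s)
    j = np.arange(s)
    misses_before = hit_pos - j  # misses strictly before the j-th hit
    top = cum - misses_before * miss          # value just after each hit
    bottom = top - w / nr                      # value just before each hit
    hi = np.maximum(top.max(axis=1), 0.0)
    lo = np.minimum(bottom.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def enrichment_score(ranked: RankedGeneList, members, weight: float = 1.0) -> float:
    """Classic weighted running-sum enrichment score for one gene set."""
    pos = {g: i for i, g in enumerate(ranked.gene_ids)}
    hit_pos = np.sort([pos[g] for g in members if g in pos])
    n = len(ranked.gene_ids)
    if hit_pos.size == 0:
        raise CellpipeError("gene set does not intersect the ranking")
    if hit_pos.size >= n:
        raise CellpipeError("gene set covers every ranked gene")
    weights = np.abs(ranked.stat) ** weight
    return float(_es_from_hits(weights, hit_pos[None, :], n)[0])


def gsea(
    ranked: RankedGeneList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
) -> list[GseaResult]:
    """Permutation GSEA over a collection, with BH-adjusted q-values.

    The null for a set of effective size s is the ES of n_perm random
    s-gene subsets of the ranking (shared across sets of the same size);
    p is the +1-corrected fraction of null scores whose magnitude reaches
    |ES_obs|, a rank statistic that is uniform when the ranking carries no
    signal and bottoms out at 1/(n_perm + 1).
    """
    if not collection.set_names:
        raise CellpipeError("empty gene-set collection")
    n = len(ranked.gene_ids)
    weights = np.abs(ranked.stat) ** weight
    gene_pos = {g: i for i, g in enumerate(ranked.gene_ids)}

    retained: list[tuple[str, np.ndarray]] = []
    for name in collection.set_names:
        hit = np.sort([gene_pos[g] for g in collection.members[name] if g in gene_pos])
        if min_size <= hit.size <= max_size and hit.size < n:
            retained.append((name, hit))
    if not retained:
        return []

    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({hit.size for _, hit in retained}):
        perm = np.empty((n_perm, size), dtype=int)
        for b in range(n_perm):
            perm[b] = rng.choice(n, size=size, replace=False)
        perm.sort(axis=1)
        null_by_size[size] = _es_from_hits(weights, perm, n)

    es_obs = np.array([
        float(_es_from_hits(weights, hit[None, :], n)[0]) for _, hit in retained
    ])
    pvals = np.empty(es_obs.size)
    for i, (name, hit) in enumerate(retained):
        null = null_by_size[hit.size]
        exceed = int((np.abs(null) >= abs(es_obs[i])).sum())
        pvals[i] = (1 + exceed) / (1 + n_perm)
    qvals = bh_adjust(pvals)
    return [
        GseaResult(name, float(es_obs[i]), int(hit.size), float(pvals[i]),
                   float(qvals[i]))
        for i, (name, hit) in enumerate(retained)
    ]


def write_gsea_csv(results: list[GseaResult], path) -> None:
    df = pd.DataFrame([
        {"set": r.set_name, "es": r.es, "size": r.size, "p": r.p, "q": r.q}
        for r in results
    ], columns=["set", "es", "size", "p", "q"])
    df.to_csv(path, index=False, float_format="%.17g")
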