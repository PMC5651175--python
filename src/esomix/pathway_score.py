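"""Pathway-level differential-expression scoring with a permutation null.

For each gene a Kruskal–Wallis rank test compares expression between
sample groups (typically the two histologies of a cohort).  A pathway's
composite score is Fisher's combined statistic over its member genes,

    S = -2 * sum_i ln p_i ,

and its significance P_s is estimated empirically by scoring random
gene sets of the same size drawn from the expression matrix: with
n_perm permutations,

    P_s = (1 + #{S_rand >= S}) / (1 + n_perm) ,

the add-one estimator, so P_s is never zero and never below
1/(n_perm+1).  Per-pathway random streams are derived from the master
seed and the pathway name, making results independent of the order
pathways appear in the gene-set file.
"""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection, OmicsMatrix

logger = logging.getLogger("esomix")

__all__ = [
    "GenePValueTable",
    "PathwayScoreResult",
    "kruskal_wallis_p",
    "kruskal_wallis_p_matrix",
    "gene_pvalues",
    "fisher_combined_score",
    "empirical_pathway_p",
    "score_all_pathways",
]


@dataclass
class GenePValueTable:
    """Two-sided per-gene p-values plus the grouping that produced them."""

    pvalues: pd.Series  # gene -> p in (0, 1]
    group_labels: list[str]
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        p = self.pvalues.to_numpy()
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("gene p-values must lie in (0, 1]")
        if len(self.group_labels) < 2 or any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("need >= 2 groups with >= 2 samples each")


@dataclass(frozen=True)
class PathwayScoreResult:
    pathway: str
    k: int                      # genes matched to the expression matrix
    score: float                # Fisher-combined composite S
    p_s: float | None           # empirical significance (None if k == 0)
    n_permutations: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("composite score must be >= 0")
        if self.p_s is not None:
            lo = 1.0 / (self.n_permutations + 1)
            if not (lo - 1e-12 <= self.p_s <= 1.0):
                raise ValueError("P_s outside its attainable range")


# ---------------------------------------------------------------------------
# gene-level Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis_p(values, groups) -> float:
    """Kruskal–Wallis rank test p for one gene.

    Mid-rank tie correction; p from the chi-square approximation with
    (number of groups - 1) degrees of freedom.  An all-constant input
    (every observation tied) carries no rank information and returns
    p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    for g in labels:
        if np.sum(groups == g) == 0:
            raise ValueError(f"group {g!r} has no samples")
    p = kruskal_wallis_p_matrix(values[None, :], groups)
    return float(p[0])


def kruskal_wallis_p_matrix(values: np.ndarray, groups) -> np.ndarray:
    """Vectorized Kruskal–Wallis over the rows of ``values``.

    Each row is one feature; columns are samples.  Returns one p-value
    per row.  Rows that are entirely tied get p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    masks = [groups == g for g in labels]
    if any(m.sum() == 0 for m in masks):
        raise ValueError("every group needs >= 1 sample")
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1)  # mid-ranks
    h = np.zeros(values.shape[0])
    for m in masks:
        ni = m.sum()
        ri = ranks[:, m].sum(axis=1)
        h += ri**2 / ni
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (n^3 - n), per row
    order = np.sort(values, axis=1)
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(order[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    correction = 1.0 - tie_term / (n**3 - n)
    p = np.ones(values.shape[0])
    ok = correction > 0  # all-tied rows have correction == 0 -> p = 1
    df = len(labels) - 1
    p[ok] = stats.chi2.sf(h[ok] / correction[ok], df)
    # numerical floor: the table contract requires p in (0, 1]
    return np.clip(p, sys.float_info.min, 1.0)


def gene_pvalues(expr: OmicsMatrix, groups: pd.Series | dict) -> GenePValueTable:
    """Per-gene Kruskal–Wallis p-values for a genes x samples matrix."""
    g = pd.Series(groups)
    common = [s for s in expr.col_ids if s in g.index]
    if len(common) < len(expr.col_ids):
        logger.warning("dropping %d sample(s) without a group label",
                       len(expr.col_ids) - len(common))
    labels = g.loc[common].to_numpy()
    values = expr.values[common].to_numpy()
    p = kruskal_wallis_p_matrix(values, labels)
    sizes = pd.Series(labels).value_counts().to_dict()
    return GenePValueTable(
        pvalues=pd.Series(p, index=expr.row_ids),
        group_labels=[str(x) for x in pd.unique(labels)],
        group_sizes={str(k): int(v) for k, v in sizes.items()},
    )


# ---------------------------------------------------------------------------
# Fisher-combined pathway score and its permutation null
# ---------------------------------------------------------------------------

def fisher_combined_score(pvals) -> float:
    """Fisher's combined statistic S = -2 * sum(ln p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p-value of 0 floored at the smallest positive float")
        p = np.maximum(p, sys.float_info.min)
    return float(-2.0 * np.log(p).sum())


def _pathway_seed(master_seed: int, pathway: str) -> int:
    # stable across processes (unlike hash()); keeps streams independent
    return (int(master_seed) * 2654435761 + zlib.crc32(pathway.encode())) % (2**31)


def empirical_pathway_p(
    score: float,
    gene_p_pool: GenePValueTable | pd.Series | np.ndarray,
    k: int,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical P_s of a composite score against size-matched random sets.

    Draws ``n_perm`` gene sets of size ``k`` uniformly without
    replacement from the pool of gene p-values, scores each with
    Fisher's statistic, and returns the add-one upper-tail estimate.
    """
    if isinstance(gene_p_pool, GenePValueTable):
        pool = gene_p_pool.pvalues.to_numpy()
    else:
        pool = np.asarray(gene_p_pool, dtype=float)
    if k > pool.size:
        raise ValueError(f"pathway size {k} exceeds pool size {pool.size}")
    if k <= 0:
        raise ValueError("pathway size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neg2logp = -2.0 * np.log(np.maximum(pool, sys.float_info.min))
    n_pool = pool.size
    # without-replacement draws: argpartition of uniform keys, in chunks
    n_ge = 0
    chunk = max(1, min(n_perm, int(4e6 // max(n_pool, 1)) or 1))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n_pool))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        s_rand = neg2logp[idx].sum(axis=1)
        n_ge += int(np.sum(s_rand >= score))
        done += b
    return (1 + n_ge) / (1 + n_perm)


def score_all_pathways(
    expr: OmicsMatrix,
    groups: pd.Series | dict,
    gmt: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    gene_table: GenePValueTable | None = None,
) -> list[PathwayScoreResult]:
    """Score every pathway in a collection against one shared gene table.

    Genes absent from the expression matrix are dropped from each set
    (k = matched size); a pathway with no matched genes yields a result
    with ``p_s=None`` and a warning.  Each pathway's null is drawn with
    its own seed derived from the master seed and the pathway name, so
    results do not depend on pathway order.
    """
    table = gene_table if gene_table is not None else gene_pvalues(expr, groups)
    pool = table.pvalues
    present = set(pool.index)
    results = []
    for name, genes in gmt:
        matched = [g for g in genes if g in present]
        if not matched:
            logger.warning("pathway %r has no genes in the expression matrix", name)
            results.append(PathwayScoreResult(name, 0, 0.0, None, n_perm))
            continue
        s = fisher_combined_score(pool.loc[matched].to_numpy())
        p_s = empirical_pathway_p(
            s, pool.to_numpy(), len(matched), n_perm,
            seed=np.random.default_rng(_pathway_seed(seed, name)),
        )
        results.append(PathwayScoreResult(name, len(matched), s, p_s, n_perm))
    return results
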