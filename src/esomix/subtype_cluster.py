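"""Per-platform hierarchical subtyping and cluster-of-clusters integration.

Per-platform clustering follows the conventions common to TCGA-style
expression subtyping: keep the most variable genes above a mean-
expression floor, transform to log10(x+1), z-score each gene, and
agglomerate samples by Ward's minimum-variance criterion (the ward.D2
convention: dissimilarities are squared inside the Lance-Williams
update) on 1 - Pearson-correlation dissimilarities.

Cross-platform integration clusters samples on the one-hot encoding of
their per-platform cluster labels:

* SuperCluster scales each platform's indicator block so every
  platform contributes equal total variance (equal platform weight);
* COCA scales each platform block by 1/sqrt(K_p), K_p being that
  platform's cluster count, so finer-grained platforms are not
  over-counted.

An external-centroid classifier (nearest centroid by Pearson
correlation after log2 transform and per-gene median-centring) maps
samples onto published subtype schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import OmicsMatrix

logger = logging.getLogger("esomix")

__all__ = [
    "PlatformClustering",
    "IntegrativeClusterResult",
    "CentroidSet",
    "select_features",
    "transform_for_clustering",
    "hierarchical_cluster",
    "centroid_classify",
    "integrate_clusters",
    "mean_silhouette",
    "silhouette_scan",
]


@dataclass
class PlatformClustering:
    platform: str
    labels: pd.Series            # sample -> cluster label (1..K)
    k: int
    method: dict = field(default_factory=dict)
    linkage_matrix: np.ndarray | None = None
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")


@dataclass
class IntegrativeClusterResult:
    labels: pd.Series            # sample -> integrated cluster label
    method: str                  # COCA | SuperCluster
    weights: dict[str, float]    # platform -> block scale factor
    missing: dict[str, list[str]] = field(default_factory=dict)  # platform -> samples absent


@dataclass
class CentroidSet:
    """Subtype centroids over one shared gene list."""

    centroids: pd.DataFrame      # genes x subtypes
    source: str = ""

    def __post_init__(self) -> None:
        if self.centroids.index.duplicated().any():
            raise ValueError("duplicate genes in centroid set")


# ---------------------------------------------------------------------------
# feature selection and transforms
# ---------------------------------------------------------------------------

def select_features(
    m: OmicsMatrix,
    fraction: float = 0.25,
    min_mean: float = 10.0,
    criterion: str = "variance",
    top_n: int | None = None,
    fraction_of: str = "all",
) -> list[str]:
    """Most-variable features above a mean-expression floor.

    Features with mean > ``min_mean`` (linear scale) are ranked by
    ``criterion`` ("variance" or "cv", the coefficient of variation)
    and the top ``fraction`` retained.  ``fraction_of`` sets the basis
    of the fraction: "all" (default) counts all features in the matrix,
    capped at the number passing the mean filter; "passing" counts only
    features that pass.  ``top_n`` overrides the fractional rule with a
    fixed count (the convention used for miRNA strand selection).
    """
    if criterion not in ("variance", "cv"):
        raise ValueError("criterion must be 'variance' or 'cv'")
    values = m.values
    means = values.mean(axis=1)
    passing = values[means > min_mean]
    if passing.empty:
        raise ValueError(f"no feature has mean > {min_mean}")
    if criterion == "variance":
        rank_stat = passing.var(axis=1, ddof=1)
    else:
        mu = passing.mean(axis=1)
        rank_stat = passing.std(axis=1, ddof=1) / mu
    ordered = rank_stat.sort_values(ascending=False).index
    if top_n is not None:
        n_keep = top_n
    elif fraction_of == "all":
        n_keep = int(round(fraction * len(values)))
    elif fraction_of == "passing":
        n_keep = int(round(fraction * len(passing)))
    else:
        raise ValueError("fraction_of must be 'all' or 'passing'")
    if n_keep > len(ordered):
        logger.warning(
            "requested %d features but only %d pass the mean filter; "
            "returning all qualifying features", n_keep, len(ordered))
        n_keep = len(ordered)
    return list(ordered[:n_keep])


def transform_for_clustering(
    m: OmicsMatrix, base: str = "log10p1", row_scale: bool = True,
) -> OmicsMatrix:
    """log10(x+1) transform, then optional per-row z-scoring.

    Constant rows become all-zeros rather than NaN, so downstream
    distances stay defined.
    """
    if base != "log10p1":
        raise ValueError("only the log10(x+1) transform is supported")
    values = m.values.to_numpy()
    if np.any(values < 0):
        raise ValueError("transform requires non-negative input")
    logged = np.log10(values + 1.0)
    if row_scale:
        mu = logged.mean(axis=1, keepdims=True)
        sd = logged.std(axis=1, ddof=0, keepdims=True)
        # rows constant up to rounding count as constant
        ok = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
        out = np.where(ok, (logged - mu) / np.where(ok, sd, 1.0), 0.0)
    else:
        out = logged
    return OmicsMatrix(pd.DataFrame(out, index=m.row_ids, columns=m.col_ids),
                       "zscore")


# ---------------------------------------------------------------------------
# hierarchical clustering (ward.D2 on correlation dissimilarity)
# ---------------------------------------------------------------------------

def _sample_dissimilarity(values: np.ndarray, metric: str) -> np.ndarray:
    """Condensed dissimilarity between sample columns."""
    if metric == "correlation":
        r = np.corrcoef(values.T)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2, 0.0, None)
        return squareform(d, checks=False)
    if metric == "euclidean":
        from scipy.spatial.distance import pdist
        return pdist(values.T, metric="euclidean")
    raise ValueError(f"unsupported metric {metric!r}")


def hierarchical_cluster(
    m: OmicsMatrix,
    k: int,
    col_distance: str = "correlation",
    linkage: str = "ward_d2",
    platform: str = "expression",
) -> PlatformClustering:
    """Ward (ward.D2 convention) agglomeration of samples, cut at k.

    Sample dissimilarity is 1 - Pearson correlation by default.
    Zero-variance sample columns make correlations undefined; they are
    excluded with a warning and reported in ``excluded_samples``.
    """
    if linkage != "ward_d2":
        raise ValueError("only ward.D2 linkage is supported")
    values = m.values.to_numpy()
    cols = list(m.col_ids)
    if col_distance == "correlation":
        sd = values.std(axis=0)
        bad = [c for c, s in zip(cols, sd) if s == 0]
        if bad:
            logger.warning("excluding zero-variance sample column(s): %s", bad)
            keep = [c for c in cols if c not in bad]
            values = m.values[keep].to_numpy()
            cols = keep
    else:
        bad = []
    if k > len(cols):
        raise ValueError(f"k={k} exceeds the {len(cols)} clusterable samples")
    d = _sample_dissimilarity(values, col_distance)
    # scipy's 'ward' applies the Lance-Williams update to squared input
    # dissimilarities, which is exactly the ward.D2 convention.
    z = hierarchy.linkage(d, method="ward")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return PlatformClustering(
        platform=platform,
        labels=pd.Series(labels, index=cols),
        k=k,
        method={"col_distance": col_distance, "linkage": "ward.D2"},
        linkage_matrix=z,
        excluded_samples=bad,
    )


# ---------------------------------------------------------------------------
# centroid classification
# ---------------------------------------------------------------------------

def centroid_classify(
    m: OmicsMatrix,
    centroids: CentroidSet,
    min_shared_genes: int = 10,
    low_confidence_r: float = 0.0,
) -> pd.DataFrame:
    """Assign each sample the centroid with maximal Pearson correlation.

    The matrix is restricted to genes shared with the centroid set,
    log2(x+1)-transformed and per-gene median-centred across samples
    before correlating.  Ties break lexicographically (flagged);
    samples whose best correlation falls below ``low_confidence_r``
    are flagged low-confidence.
    """
    shared = m.values.index.intersection(centroids.centroids.index)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared with the centroids "
            f"(floor {min_shared_genes})")
    x = np.log2(m.values.loc[shared] + 1.0)
    x = x.sub(x.median(axis=1), axis=0)
    cent = centroids.centroids.loc[shared]
    subtypes = sorted(cent.columns)
    rows = []
    for sample in x.columns:
        v = x[sample].to_numpy()
        rs = {}
        for s in subtypes:
            c = cent[s].to_numpy()
            if np.std(v) == 0 or np.std(c) == 0:
                rs[s] = np.nan
            else:
                rs[s] = float(np.corrcoef(v, c)[0, 1])
        best_r = np.nanmax(list(rs.values()))
        winners = [s for s in subtypes if np.isclose(rs[s], best_r, atol=0.0, rtol=0.0)
                   or rs[s] == best_r]
        rows.append({
            "sample": sample,
            "subtype": winners[0],
            "correlation": best_r,
            "tie": len(winners) > 1,
            "low_confidence": bool(best_r < low_confidence_r),
        })
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# COCA / SuperCluster integration
# ---------------------------------------------------------------------------

def _one_hot_block(labels: pd.Series, samples: pd.Index) -> pd.DataFrame:
    block = pd.get_dummies(labels.astype(str)).astype(float)
    return block.reindex(samples, fill_value=0.0)


def integrate_clusters(
    platform_clusterings: list[PlatformClustering],
    method: str = "COCA",
    k: int = 3,
) -> IntegrativeClusterResult:
    """Cluster samples on the weighted one-hot encoding of platform labels.

    SuperCluster scales each platform block by
    1/sqrt(sum of its indicator-column variances) so each platform
    contributes equal total variance; COCA scales by 1/sqrt(K_p).
    The weighted indicator matrix is clustered hierarchically
    (Euclidean distance, ward.D2) and cut at ``k``.  Samples missing
    from a platform get an all-zero row in that block and are reported
    in ``missing``.
    """
    if method not in ("COCA", "SuperCluster"):
        raise ValueError("method must be 'COCA' or 'SuperCluster'")
    if len(platform_clusterings) < 2:
        raise ValueError("need >= 2 platform clusterings")
    all_samples = pd.Index(sorted(set().union(
        *[set(pc.labels.index) for pc in platform_clusterings])))
    if all(pc.k == 1 for pc in platform_clusterings):
        raise ValueError("every platform has K=1; nothing to integrate")
    blocks = []
    weights: dict[str, float] = {}
    missing: dict[str, list[str]] = {}
    for pc in platform_clusterings:
        if pc.k == 1:
            logger.warning("platform %r has K=1 and contributes nothing", pc.platform)
        block = _one_hot_block(pc.labels, all_samples)
        absent = [s for s in all_samples if s not in pc.labels.index]
        if absent:
            missing[pc.platform] = absent
        if method == "SuperCluster":
            total_var = float(block.var(axis=0, ddof=0).sum())
            w = 1.0 / np.sqrt(total_var) if total_var > 0 else 0.0
        else:  # COCA
            w = 1.0 / np.sqrt(pc.k)
        weights[pc.platform] = w
        block = block * w
        block.columns = [f"{pc.platform}:{c}" for c in block.columns]
        blocks.append(block)
    indicator = pd.concat(blocks, axis=1)
    mat = OmicsMatrix(indicator.T, "zscore")  # features = indicator columns
    pc_int = hierarchical_cluster(mat, k=k, col_distance="euclidean",
                                  platform=f"integrated-{method}")
    return IntegrativeClusterResult(
        labels=pc_int.labels, method=method, weights=weights, missing=missing)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def mean_silhouette(d_square: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from a square dissimilarity matrix."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return 0.0
    n = len(labels)
    sil = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        a = d_square[i, own].mean() if own.any() else 0.0
        b = np.inf
        for c in uniq:
            if c == labels[i]:
                continue
            other = labels == c
            if other.any():
                b = min(b, d_square[i, other].mean())
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sil.mean())


def silhouette_scan(
    m: OmicsMatrix,
    k_range=range(2, 11),
    col_distance: str = "correlation",
) -> pd.DataFrame:
    """Mean silhouette width for each candidate cluster count."""
    values = m.values.to_numpy()
    d = squareform(_sample_dissimilarity(values, col_distance))
    rows = []
    for k in k_range:
        if k > values.shape[1]:
            break
        pc = hierarchical_cluster(m, k, col_distance=col_distance)
        rows.append({"k": k, "mean_silhouette":
                     mean_silhouette(d, pc.labels.to_numpy())})
    return pd.DataFrame(rows).set_index("k")
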