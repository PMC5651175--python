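"""Epigenetic-silencing calls from paired promoter methylation and expression.

A gene is called epigenetically silenced in a sample when its promoter
probe is hypermethylated (beta >= ``beta_high``, default 0.3) *and* its
expression falls at or below a low quantile (default the 25th
percentile) of the expression seen in samples with essentially
unmethylated promoters (beta < ``low_beta_ref``, default 0.1).  The
unmethylated samples provide the gene's own expression reference, which
is what makes the rule a reproducible surrogate for the classic
methylation-versus-expression scatterplot read-out; a gene with fewer
than ``min_reference`` unmethylated samples is uncallable.

This module also houses the exact two-sided Fisher test used for every
2x2 contingency comparison in the toolkit (silencing-by-subtype counts,
mutation enrichment by cohort, and so on), computed by full
hypergeometric enumeration under the minimum-likelihood convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import OmicsMatrix

logger = logging.getLogger("esomix")

__all__ = [
    "ContingencyTable2x2",
    "SilencingCallSet",
    "fisher_exact_2x2",
    "call_silencing",
    "call_silencing_matrix",
    "select_probe_per_gene",
    "silencing_subtype_association",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts (a, b; c, d): rows = condition, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SilencingCallSet:
    """Per-gene, per-sample boolean silencing calls plus provenance."""

    calls: pd.DataFrame           # genes x samples, boolean
    probe_used: dict[str, str]    # gene -> probe id
    beta_high: float
    low_beta_ref: float
    expr_quantile: float
    uncallable: dict[str, str] = field(default_factory=dict)  # gene -> reason


def fisher_exact_2x2(table: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Exact two-sided Fisher p for a 2x2 table.

    Enumerate every table with the observed margins; the two-sided p is
    the sum of hypergeometric point probabilities not exceeding that of
    the observed table (minimum-likelihood convention), compared with a
    1e-7 relative tolerance so ties of equal probability on the other
    tail are included despite floating-point rounding.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is implemented")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        raise ValueError("empty table")
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # hypergeometric pmf via log-gamma (vectorized, low call overhead)
    logpmf = (
        gammaln(row1 + 1) - gammaln(support + 1) - gammaln(row1 - support + 1)
        + gammaln(n - row1 + 1) - gammaln(col1 - support + 1)
        - gammaln(n - row1 - col1 + support + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    keep = pmf <= p_obs * (1 + 1e-7)
    return float(min(1.0, pmf[keep].sum()))


# ---------------------------------------------------------------------------
# silencing calls
# ---------------------------------------------------------------------------

def call_silencing(
    beta: pd.Series,
    expr: pd.Series,
    beta_high: float = 0.3,
    low_beta_ref: float = 0.1,
    expr_quantile: float = 0.25,
    min_reference: int = 5,
) -> pd.Series:
    """Silencing calls for one gene across samples.

    ``beta`` holds promoter-probe beta values, ``expr`` expression on
    the log2(RPKM+1) scale, indexed by sample.  Only samples present in
    both series are called.
    """
    common = beta.index.intersection(expr.index)
    b = beta.loc[common].astype(float)
    e = expr.loc[common].astype(float)
    reference = e[b < low_beta_ref]
    if len(reference) < min_reference:
        raise ValueError(
            f"gene uncallable: only {len(reference)} sample(s) with "
            f"beta < {low_beta_ref} (need >= {min_reference})"
        )
    cutoff = reference.quantile(expr_quantile)
    return (b >= beta_high) & (e <= cutoff)


def select_probe_per_gene(
    beta: OmicsMatrix,
    expr_log: pd.DataFrame,
    probe_map: pd.DataFrame,
) -> dict[str, str]:
    """Pick one promoter probe per gene: the probe whose methylation is
    most negatively correlated with the gene's expression.

    ``probe_map`` has columns ``probe`` and ``gene``.
    """
    chosen: dict[str, str] = {}
    beta_df = beta.values
    samples = beta_df.columns.intersection(expr_log.columns)
    for gene, sub in probe_map.groupby("gene"):
        probes = [p for p in sub["probe"] if p in beta_df.index]
        if not probes or gene not in expr_log.index:
            continue
        if len(probes) == 1:
            chosen[gene] = probes[0]
            continue
        e = expr_log.loc[gene, samples].to_numpy(dtype=float)
        best, best_r = probes[0], np.inf
        for p in probes:
            bvals = beta_df.loc[p, samples].to_numpy(dtype=float)
            if np.std(bvals) == 0 or np.std(e) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(bvals, e)[0, 1])
            if r < best_r:
                best, best_r = p, r
        chosen[gene] = best
    return chosen


def call_silencing_matrix(
    beta: OmicsMatrix,
    expr: OmicsMatrix,
    probe_map: pd.DataFrame,
    beta_high: float = 0.3,
    low_beta_ref: float = 0.1,
    expr_quantile: float = 0.25,
    min_reference: int = 5,
) -> SilencingCallSet:
    """Cohort-level silencing calls for every mappable gene.

    Expression on a linear RPKM scale is transformed to log2(RPKM+1)
    here; matrices already on a log scale pass through unchanged.
    """
    if expr.scale in ("RPKM", "RPM", "RSEM"):
        expr_log = np.log2(expr.values + 1.0)
    else:
        expr_log = expr.values.copy()
    samples = beta.values.columns.intersection(expr_log.columns)
    probe_for = select_probe_per_gene(beta, expr_log, probe_map)
    rows, index = [], []
    uncallable: dict[str, str] = {}
    for gene, probe in probe_for.items():
        try:
            calls = call_silencing(
                beta.values.loc[probe, samples],
                expr_log.loc[gene, samples],
                beta_high, low_beta_ref, expr_quantile, min_reference,
            )
        except ValueError as exc:
            uncallable[gene] = str(exc)
            logger.info("gene %s uncallable: %s", gene, exc)
            continue
        rows.append(calls.reindex(samples, fill_value=False))
        index.append(gene)
    calls_df = (pd.DataFrame(rows, index=index) if rows
                else pd.DataFrame(columns=samples, dtype=bool))
    return SilencingCallSet(
        calls=calls_df.astype(bool),
        probe_used={g: probe_for[g] for g in index},
        beta_high=beta_high, low_beta_ref=low_beta_ref,
        expr_quantile=expr_quantile, uncallable=uncallable,
    )


def silencing_subtype_association(
    call_set: SilencingCallSet | pd.DataFrame,
    subtypes: pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Fisher test of silencing frequency between two subtypes.

    For each gene a 2x2 table (silenced / not x subtype) is tested
    two-sided; genes with p < ``alpha`` are flagged, and Bonferroni
    significance is flagged separately at alpha / (number of callable
    genes).
    """
    calls = call_set.calls if isinstance(call_set, SilencingCallSet) else call_set
    subtypes = pd.Series(subtypes)
    labels = sorted(pd.unique(subtypes.dropna()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 subtype labels, got {labels}")
    ga, gb = labels
    samples_a = subtypes.index[subtypes == ga].intersection(calls.columns)
    samples_b = subtypes.index[subtypes == gb].intersection(calls.columns)
    n_genes = len(calls.index)
    rows = []
    for gene in calls.index:
        sa = int(calls.loc[gene, samples_a].sum())
        sb = int(calls.loc[gene, samples_b].sum())
        if sa == 0 and sb == 0:
            p = 1.0
        else:
            p = fisher_exact_2x2(ContingencyTable2x2(
                sa, len(samples_a) - sa, sb, len(samples_b) - sb))
        rows.append({
            "gene": gene,
            f"n_silenced_{ga}": sa, f"n_{ga}": len(samples_a),
            f"n_silenced_{gb}": sb, f"n_{gb}": len(samples_b),
            "fisher_p": p,
            "significant": p < alpha,
            "bonferroni_sig": n_genes > 0 and p < alpha / n_genes,
        })
    return pd.DataFrame(rows).set_index("gene")
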