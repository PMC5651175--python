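"""96-context mutation catalogs and ARD Bayesian NMF signature extraction.

Single-base substitutions are binned by the standard 96-channel
convention: six pyrimidine-strand substitution classes (C>A, C>G, C>T,
T>A, T>C, T>G) times the 4x4 flanking-base combinations.  Mutations
reported on the purine strand are reverse-complemented first, so a
G>T call in context TGT lands in the A[C>A]A channel.

Signatures are extracted by non-negative matrix factorization of the
catalog V (96 x samples) under a Kullback-Leibler objective with
automatic relevance determination (ARD): each candidate signature k
carries a relevance scale lambda_k shared by its profile column W[:,k]
and exposure row H[k,:], under exponential priors.  Maximum a
posteriori multiplicative updates shrink superfluous signatures toward
zero; components whose share of the reconstruction collapses below a
threshold are pruned, and the surviving count is the selected rank.
The best of several random restarts (by final objective) is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pathway_score import kruskal_wallis_p

logger = logging.getLogger("esomix")

__all__ = [
    "CONTEXT_BINS",
    "MutationCatalog",
    "SignatureDecomposition",
    "build_catalog",
    "ard_nmf",
    "signature_fractions",
    "group_fraction_tests",
    "context_fraction",
    "APOBEC_BINS",
    "C_TO_A_BINS",
    "AA_DINUCLEOTIDE_AC_BINS",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]

#: canonical 96 channel labels, e.g. "A[C>A]A"
CONTEXT_BINS: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
]
_BIN_INDEX = {b: i for i, b in enumerate(CONTEXT_BINS)}

#: APOBEC-associated channels: C>T and C>G in a TpC context, W = A/T 3'
APOBEC_BINS = [f"T[C>{alt}]{w}" for alt in ("T", "G") for w in ("A", "T")]
C_TO_A_BINS = [b for b in CONTEXT_BINS if "[C>A]" in b]
#: A>C at an AA dinucleotide maps, after pyrimidine-strand collapse, to
#: T>G channels with a 3' T (original 5' A).
AA_DINUCLEOTIDE_AC_BINS = [f"{five}[T>G]T" for five in BASES]


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def pyrimidine_bin(ref: str, alt: str, context: str) -> str:
    """Map a substitution + trinucleotide context to its 96-channel label.

    Raises ``ValueError`` when the context middle base disagrees with
    the reference allele or any base is not ACGT.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        raise ValueError(f"invalid trinucleotide context {context!r}")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if context[1] != ref:
        raise ValueError(
            f"context middle base {context[1]!r} does not match ref {ref!r}")
    if ref in ("G", "A"):
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationCatalog:
    """96 channels x samples integer counts."""

    counts: pd.DataFrame                      # index = CONTEXT_BINS
    rejected: dict[str, int] = field(default_factory=dict)  # reason -> count

    def __post_init__(self) -> None:
        if list(self.counts.index) != CONTEXT_BINS:
            raise ValueError("catalog rows must be the canonical 96 channels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SignatureDecomposition:
    """ARD-NMF result: profiles, exposures, selected rank and trace."""

    w: pd.DataFrame              # signatures x 96, rows sum to 1
    h: pd.DataFrame              # samples x signatures
    k: int
    objective_trace: list[float]
    seed: int
    converged: bool = True

    def __post_init__(self) -> None:
        if (self.w.to_numpy() < 0).any() or (self.h.to_numpy() < 0).any():
            raise ValueError("factors must be non-negative")
        sums = self.w.sum(axis=1).to_numpy()
        if self.k and not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("signature profiles must sum to 1")


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

def build_catalog(mutations) -> MutationCatalog:
    """Count SNVs with valid context into the 96-channel catalog.

    Accepts :class:`~esomix.mutation_ensemble.MergedMutation` or plain
    :class:`~esomix.io_formats.VariantCall` records.  Records without a
    context, or whose context disagrees with the reference allele, go
    into the reject tally instead of the catalog.
    """
    per_sample: dict[str, np.ndarray] = {}
    rejected: dict[str, int] = {}
    for rec in mutations:
        v = getattr(rec, "variant", rec)
        if v.context is None:
            rejected["missing_context"] = rejected.get("missing_context", 0) + 1
            continue
        if len(v.ref) != 1 or len(v.alt) != 1:
            rejected["not_snv"] = rejected.get("not_snv", 0) + 1
            continue
        try:
            b = pyrimidine_bin(v.ref, v.alt, v.context)
        except ValueError:
            rejected["invalid_context"] = rejected.get("invalid_context", 0) + 1
            continue
        if v.sample_id not in per_sample:
            per_sample[v.sample_id] = np.zeros(96, dtype=int)
        per_sample[v.sample_id][_BIN_INDEX[b]] += 1
    counts = pd.DataFrame(per_sample, index=CONTEXT_BINS).fillna(0).astype(int)
    return MutationCatalog(counts, rejected)


# ---------------------------------------------------------------------------
# ARD-NMF
# ---------------------------------------------------------------------------

def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    mask = v > 0
    return float(np.sum(v[mask] * np.log(v[mask] / wh[mask])) - v.sum() + wh.sum())


def _ard_objective(v, w, h, lam, a, b) -> float:
    f, n = v.shape
    penalty = np.sum((w.sum(axis=0) + h.sum(axis=1) + b) / lam)
    penalty += (f + n + a + 1) * np.sum(np.log(lam))
    return _kl_divergence(v, w @ h + 1e-12) + penalty


def _ard_nmf_single(
    v: np.ndarray,
    k_max: int,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    a: float,
    prune_rel: float,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    f, n = v.shape
    mean_v = v.mean()
    # prior scale chosen so the exponential prior matches the data scale
    b = np.sqrt((a - 1) * (a - 2) * mean_v / k_max)
    scale = np.sqrt(mean_v / k_max)
    w = rng.random((f, k_max)) * scale + 1e-6
    h = rng.random((k_max, n)) * scale + 1e-6
    lam = (w.sum(axis=0) + h.sum(axis=1) + b) / (f + n + a + 1)
    eps = 1e-12
    trace = []
    prev = np.inf
    converged = False
    ones_f = np.ones((f, 1))
    ones_n = np.ones((1, n))
    for it in range(max_iter):
        wh = w @ h + eps
        w *= (v / wh) @ h.T / (ones_f @ h.sum(axis=1)[None, :] + 1.0 / lam[None, :] + eps)
        wh = w @ h + eps
        h *= w.T @ (v / wh) / (w.sum(axis=0)[:, None] @ ones_n + 1.0 / lam[:, None] + eps)
        lam = (w.sum(axis=0) + h.sum(axis=1) + b) / (f + n + a + 1)
        obj = _ard_objective(v, w, h, lam, a, b)
        trace.append(obj)
        if prev - obj < tol * max(1.0, abs(prev)) and it > 20:
            converged = True
            break
        prev = obj
    # prune signatures whose reconstruction share has collapsed
    contrib = w.sum(axis=0) * h.sum(axis=1)
    total = contrib.sum()
    keep = contrib > prune_rel * total if total > 0 else np.zeros(k_max, bool)
    return w[:, keep], h[keep, :], trace, converged


def ard_nmf(
    catalog: MutationCatalog,
    k_max: int = 20,
    tol: float = 1e-7,
    max_iter: int = 3000,
    seed: int = 0,
    n_restarts: int = 10,
    a: float = 10.0,
    prune_rel: float = 1e-3,
) -> SignatureDecomposition:
    """Extract signatures by KL ARD-NMF; best of ``n_restarts`` runs.

    ``a`` is the relevance-prior shape (larger = stronger shrinkage of
    superfluous signatures); ``prune_rel`` is the minimum share of the
    reconstruction a signature must retain to survive pruning.
    """
    v = catalog.counts.to_numpy(dtype=float)
    if catalog.counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if v.sum() == 0:
        raise ValueError("catalog is all zeros")
    master = np.random.default_rng(seed)
    best = None
    best_obj = np.inf
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        w, h, trace, converged = _ard_nmf_single(
            v, k_max, tol, max_iter, rng, a, prune_rel)
        if trace[-1] < best_obj:
            best_obj = trace[-1]
            best = (w, h, trace, converged)
    w, h, trace, converged = best
    if not converged:
        logger.warning("ARD-NMF did not converge within max_iter")
    k = w.shape[1]
    # move profile mass into simplex-normalized rows of W; rescale H
    col_sums = w.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    w_norm = (w / col_sums).T                     # k x 96
    h_scaled = (h * col_sums[:, None]).T          # samples x k
    sig_names = [f"S{i+1}" for i in range(k)]
    return SignatureDecomposition(
        w=pd.DataFrame(w_norm, index=sig_names, columns=CONTEXT_BINS),
        h=pd.DataFrame(h_scaled, index=catalog.sample_ids, columns=sig_names),
        k=k,
        objective_trace=trace,
        seed=seed,
        converged=converged,
    )


def signature_fractions(d: SignatureDecomposition) -> pd.DataFrame:
    """Per-sample exposure fractions; rows sum to 1 (zero-exposure
    samples are dropped)."""
    totals = d.h.sum(axis=1)
    keep = totals > 0
    return d.h.loc[keep].div(totals[keep], axis=0)


def group_fraction_tests(
    fractions: pd.Series,
    labels: pd.Series,
    test: str = "wilcoxon_rank_sum",
) -> float:
    """Rank test of a signature-fraction (or any scalar) between groups.

    ``wilcoxon_rank_sum`` (two groups, two-sided, normal approximation
    with tie correction) or ``kruskal_wallis`` (>= 2 groups).  Fully
    tied data returns p = 1.
    """
    common = fractions.index.intersection(labels.index)
    x = fractions.loc[common].to_numpy(dtype=float)
    g = labels.loc[common]
    uniq = pd.unique(g)
    if any((g == u).sum() == 0 for u in uniq) or len(uniq) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if test == "kruskal_wallis":
        return kruskal_wallis_p(x, g.to_numpy())
    if test != "wilcoxon_rank_sum":
        raise ValueError("test must be 'wilcoxon_rank_sum' or 'kruskal_wallis'")
    if len(uniq) != 2:
        raise ValueError("the rank-sum test needs exactly 2 groups")
    x1 = x[(g == uniq[0]).to_numpy()]
    x2 = x[(g == uniq[1]).to_numpy()]
    if np.all(x == x[0]):
        return 1.0
    res = stats.mannwhitneyu(x1, x2, alternative="two-sided", method="asymptotic")
    return float(min(1.0, res.pvalue))


def context_fraction(catalog: MutationCatalog, bins) -> pd.Series:
    """Per-sample fraction of mutations falling in the given channels."""
    totals = catalog.counts.sum(axis=0)
    sub = catalog.counts.loc[list(bins)].sum(axis=0)
    frac = sub / totals.replace(0, np.nan)
    return frac.dropna()
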