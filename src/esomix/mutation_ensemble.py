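"""Ensemble merging and filtering of multi-caller somatic SNV call sets.

Call sets from independent mutation callers are unioned on
(sample, chromosome, position, ref, alt), then passed through
reason-accumulating filters:

* germline site blacklist (1000 Genomes-style) and panel-of-normals
  blacklist, matched by (chromosome, position, alt);
* normal-sample evidence: reference coverage < 8x, more than one
  variant-supporting read, or variant allele fraction (VAF) above 1%;
* tumour-sample evidence: fewer than 2 supporting reads or VAF below
  5% (both tumour requirements read as inclusive minima);
* oxoG artifact orientation bias for C>A / G>T substitutions.

Filters never short-circuit: every decision carries the complete set
of reasons, so reject tables are fully auditable and the evaluation
order cannot change the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io_formats import VariantCall

__all__ = [
    "MergedMutation",
    "FilterDecision",
    "FilterParams",
    "merge_call_sets",
    "filter_variant",
    "apply_site_blacklists",
    "oxog_filter",
    "run_ensemble",
]

FILTER_REASONS = (
    "germline_1000G",
    "normal_low_ref_coverage",
    "normal_alt_reads",
    "normal_vaf",
    "tumor_alt_reads",
    "tumor_vaf",
    "oxog_orientation",
    "panel_of_normals",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class MergedMutation:
    """A unioned variant with provenance: which callers reported it.

    Read counts come from the reporting caller with the greatest total
    (tumour + normal) depth, on the view that the deepest record is the
    best-measured one.
    """

    variant: VariantCall
    callers: tuple[str, ...]

    @property
    def key(self):
        return self.variant.key


@dataclass
class FilterDecision:
    key: tuple
    kept: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.reasons) - set(FILTER_REASONS)
        if bad:
            raise ValueError(f"unknown filter reasons: {sorted(bad)}")
        if self.kept != (not self.reasons):
            raise ValueError("kept flag inconsistent with reasons")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the normal/tumour evidence filters.

    ``normal_alt_or_vaf`` selects how the two normal-evidence
    conditions combine: ``"or"`` (default, stricter — either condition
    rejects) or ``"and"``.
    """

    min_normal_ref_coverage: int = 8
    max_normal_alt_reads: int = 1
    max_normal_vaf: float = 0.01
    min_tumor_alt_reads: int = 2
    min_tumor_vaf: float = 0.05
    normal_alt_or_vaf: str = "or"
    oxog_max_orientation_fraction: float = 0.9
    oxog_min_alt_reads: int = 3


def merge_call_sets(
    call_sets: list[list[VariantCall]],
    min_callers: int = 1,
) -> list[MergedMutation]:
    """Union per-caller call sets, keyed by (sample, chrom, pos, ref, alt).

    Variants reported by fewer than ``min_callers`` callers are dropped.
    Conflicting reference alleles at one (sample, chrom, pos) are an
    error: the callers disagree about the genome itself.
    """
    if not call_sets:
        raise ValueError("need at least one call set")
    merged: dict[tuple, VariantCall] = {}
    callers: dict[tuple, list[str]] = {}
    ref_seen: dict[tuple, str] = {}
    for call_set in call_sets:
        for v in call_set:
            site = (v.sample_id, v.chromosome, v.position)
            if site in ref_seen and ref_seen[site] != v.ref:
                raise ValueError(
                    f"conflicting reference alleles at {site}: "
                    f"{ref_seen[site]!r} vs {v.ref!r}"
                )
            ref_seen[site] = v.ref
            k = v.key
            if k not in merged:
                merged[k] = v
                callers[k] = [v.caller]
            else:
                if v.caller not in callers[k]:
                    callers[k].append(v.caller)
                old = merged[k]
                depth_old = (old.t_ref_count + old.t_alt_count
                             + old.n_ref_count + old.n_alt_count)
                depth_new = (v.t_ref_count + v.t_alt_count
                             + v.n_ref_count + v.n_alt_count)
                if depth_new > depth_old:
                    merged[k] = v
    out = []
    for k in sorted(merged):
        if len(callers[k]) >= min_callers:
            out.append(MergedMutation(merged[k], tuple(sorted(callers[k]))))
    return out


def filter_variant(v: VariantCall, params: FilterParams = FilterParams()) -> FilterDecision:
    """Evaluate the normal- and tumour-evidence rules on one variant.

    Reasons accumulate; nothing short-circuits.  A normal sample with
    zero total depth fails the coverage requirement.
    """
    reasons: list[str] = []
    if v.n_ref_count < params.min_normal_ref_coverage:
        reasons.append("normal_low_ref_coverage")
    alt_hit = v.n_alt_count > params.max_normal_alt_reads
    n_depth = v.n_ref_count + v.n_alt_count
    vaf_hit = n_depth > 0 and (v.n_alt_count / n_depth) > params.max_normal_vaf
    if params.normal_alt_or_vaf == "or":
        if alt_hit:
            reasons.append("normal_alt_reads")
        if vaf_hit:
            reasons.append("normal_vaf")
    elif params.normal_alt_or_vaf == "and":
        if alt_hit and vaf_hit:
            reasons.extend(["normal_alt_reads", "normal_vaf"])
    else:
        raise ValueError("normal_alt_or_vaf must be 'or' or 'and'")
    if v.t_alt_count < params.min_tumor_alt_reads:
        reasons.append("tumor_alt_reads")
    t_depth = v.t_ref_count + v.t_alt_count
    if t_depth == 0 or (v.t_alt_count / t_depth) < params.min_tumor_vaf:
        reasons.append("tumor_vaf")
    return FilterDecision(v.key, kept=not reasons, reasons=reasons)


def _site_match(v: VariantCall, sites: set[tuple[str, int, str]]) -> bool:
    return ((v.chromosome, v.position, v.alt) in sites
            or (v.chromosome, v.position, "*") in sites)


def apply_site_blacklists(
    variants: list[VariantCall],
    germline_sites: set[tuple[str, int, str]] | None = None,
    pon_sites: set[tuple[str, int, str]] | None = None,
) -> list[FilterDecision]:
    """Flag variants at known germline-SNP or panel-of-normals sites."""
    germline_sites = germline_sites or set()
    pon_sites = pon_sites or set()
    decisions = []
    for v in variants:
        reasons = []
        if _site_match(v, germline_sites):
            reasons.append("germline_1000G")
        if _site_match(v, pon_sites):
            reasons.append("panel_of_normals")
        decisions.append(FilterDecision(v.key, kept=not reasons, reasons=reasons))
    return decisions


def oxog_filter(v: VariantCall, params: FilterParams = FilterParams()) -> FilterDecision:
    """Orientation-bias test for 8-oxoguanine artifacts.

    Applies only to C>A (artifact orientation F2R1) and G>T (F1R2)
    substitutions with orientation counts present; flagged when the
    artifact-consistent orientation holds at least
    ``oxog_max_orientation_fraction`` of the oriented alt reads and
    there are at least ``oxog_min_alt_reads`` of them.
    """
    reasons: list[str] = []
    pair = (v.ref, v.alt)
    if pair in (("C", "A"), ("G", "T")) and v.alt_f1r2 is not None and v.alt_f2r1 is not None:
        artifact = v.alt_f2r1 if pair == ("C", "A") else v.alt_f1r2
        total = v.alt_f1r2 + v.alt_f2r1
        if total >= params.oxog_min_alt_reads and total > 0:
            if artifact / total >= params.oxog_max_orientation_fraction:
                reasons.append("oxog_orientation")
    return FilterDecision(v.key, kept=not reasons, reasons=reasons)


def run_ensemble(
    call_sets: list[list[VariantCall]],
    germline_sites: set[tuple[str, int, str]] | None = None,
    pon_sites: set[tuple[str, int, str]] | None = None,
    params: FilterParams = FilterParams(),
    min_callers: int = 1,
) -> tuple[list[MergedMutation], dict[tuple, FilterDecision]]:
    """Merge, blacklist-filter and evidence-filter the call sets.

    Returns the surviving merged mutations and one combined
    :class:`FilterDecision` per merged variant (reasons pooled across
    all rules; a variant is kept iff its reason set is empty).
    """
    merged = merge_call_sets(call_sets, min_callers=min_callers)
    variants = [m.variant for m in merged]
    reason_map: dict[tuple, list[str]] = {m.key: [] for m in merged}
    for d in apply_site_blacklists(variants, germline_sites, pon_sites):
        reason_map[d.key].extend(d.reasons)
    for v in variants:
        reason_map[v.key].extend(filter_variant(v, params).reasons)
        reason_map[v.key].extend(oxog_filter(v, params).reasons)
    decisions = {
        k: FilterDecision(k, kept=not rs, reasons=sorted(set(rs)))
        for k, rs in ((k, rs) for k, rs in reason_map.items())
    }
    survivors = [m for m in merged if decisions[m.key].kept]
    return survivors, decisions
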