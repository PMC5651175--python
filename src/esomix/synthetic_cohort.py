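"""Synthetic multi-platform cohort generator with known ground truth.

Every analysis stage in this toolkit is exercised against cohorts
drawn from this module: subtype-structured arm-level gains and losses,
inverse methylation-expression coupling for silenced genes,
multi-caller somatic variant sets with planted false positives,
trinucleotide-context mutation catalogs drawn from signature mixtures,
and pathway-coherent subtype-differential expression.  The generator
records the full ground truth (subtype labels, arm events, CIN labels,
silenced pairs, true variants, exposure fractions, differential
pathways) so recovery can be measured exactly.

Default effect sizes sit well away from the decision boundaries the
callers use (arm events at log2 +/-0.3 versus the 0.15 call threshold,
events covering 95% of an arm versus the 80% rule), so recovery
experiments are stable; boundary behaviour is probed with dedicated
deterministic fixtures, not random draws.

One master seed drives independent per-platform substreams, so adding
or re-running one platform never perturbs another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ArmDefinition,
    GeneSetCollection,
    GenomicSegment,
    OmicsMatrix,
    SegmentedCopyNumberProfile,
    VariantCall,
    builtin_arm_table,
)
from .mutation_signatures import (
    APOBEC_BINS,
    CONTEXT_BINS,
    C_TO_A_BINS,
    _COMPLEMENT,
    _revcomp,
)

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "SyntheticCohort",
    "default_signature_definitions",
    "simulate_copy_number",
    "simulate_methylation_expression",
    "simulate_mutation_callsets",
    "simulate_expression_subtypes",
    "simulate_cohort",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible per-platform random stream."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


def default_signature_definitions() -> pd.DataFrame:
    """Three synthetic 96-channel signatures (rows sum to 1).

    * ``APOBEC-like`` — concentrated in T[C>T]W / T[C>G]W channels;
    * ``CA-heavy`` — spread over the C>A channels (tobacco-like);
    * ``CpG-CtoT`` — C>T at NpCpG (deamination/ageing-like).
    """
    sigs = pd.DataFrame(0.0, index=["APOBEC-like", "CA-heavy", "CpG-CtoT"],
                        columns=CONTEXT_BINS)
    sigs.loc["APOBEC-like", APOBEC_BINS] = 0.8 / len(APOBEC_BINS)
    sigs.loc["CA-heavy", C_TO_A_BINS] = 0.8 / len(C_TO_A_BINS)
    cpg = [b for b in CONTEXT_BINS if "[C>T]G" in b]
    sigs.loc["CpG-CtoT", cpg] = 0.8 / len(cpg)
    sigs += 0.2 / 96  # flat background so every channel is reachable
    return sigs.div(sigs.sum(axis=1), axis=0)


def _default_arm_events() -> dict[str, dict[str, tuple[float, float]]]:
    # subtype -> arm -> (gain probability, loss probability)
    return {
        "S1": {"17p": (0.0, 0.9), "9p": (0.0, 0.6), "3q": (0.7, 0.0),
               "18q": (0.0, 0.5)},
        "S2": {"18q": (0.0, 0.4), "18p": (0.0, 0.3), "13q": (0.3, 0.0)},
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_samples_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"S1": 100, "S2": 100})
    n_genes: int = 1000
    # copy number
    arm_event_probs: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_arm_events)
    background_event_prob: float = 0.01    # per arm per direction
    event_log2: float = 0.3
    log2_noise_sd: float = 0.03
    event_cover_fraction: float = 0.95
    segments_per_arm_mean: float = 3.0
    min_segment_length: int = 100_000
    # methylation / expression coupling
    n_silenced_genes: int = 10
    silencing_rate: float = 0.1
    differential_silenced_rates: tuple[float, float] = (0.4, 0.05)
    beta_low_params: tuple[float, float] = (2.0, 40.0)
    beta_high_params: tuple[float, float] = (12.0, 4.0)
    suppression_factor: float = 0.05
    n_methylation_markers: int = 50
    # mutations
    callers: tuple[str, ...] = ("broad", "washu", "ucsc", "bcca")
    mutations_per_sample: float = 100.0
    vaf_beta_params: tuple[float, float] = (2.0, 5.0)
    tumor_depth: float = 200.0
    normal_depth: float = 130.0
    normal_error_rate: float = 0.001
    caller_dropout: float = 0.05
    fp_low_evidence_rate: float = 5.0      # per sample per caller
    fp_blacklist_rate: float = 3.0
    fp_oxog_rate: float = 2.0
    n_germline_sites: int = 200
    n_pon_sites: int = 100
    # expression subtypes
    n_differential_pathways: int = 3
    differential_pathway_size: int = 30
    n_null_pathways: int = 20
    differential_effect_log10: float = 1.0
    expression_noise_sd_log10: float = 0.3
    signature_concentration: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = ([self.background_event_prob, self.caller_dropout,
                  self.silencing_rate, self.normal_error_rate]
                 + [p for sub in self.arm_event_probs.values()
                    for pair in sub.values() for p in pair]
                 + list(self.differential_silenced_rates))
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def subtypes(self) -> list[str]:
        return list(self.n_samples_per_subtype)

    @property
    def sample_ids(self) -> list[str]:
        return [f"{st}-{i:03d}"
                for st in self.subtypes
                for i in range(self.n_samples_per_subtype[st])]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class CohortTruth:
    """Ground truth indexed by the declared samples and features."""

    sample_ids: list[str]
    subtype: dict[str, str]
    arm_events: dict[str, dict[str, str]] = field(default_factory=dict)
    cin_label: dict[str, str] = field(default_factory=dict)
    silenced_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_variants: dict[str, list] = field(default_factory=dict)
    exposures: dict[str, dict[str, float]] = field(default_factory=dict)
    differential_pathways: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        declared = set(self.sample_ids)
        for name, keys in [("subtype", self.subtype), ("arm_events", self.arm_events),
                           ("cin_label", self.cin_label), ("exposures", self.exposures),
                           ("true_variants", self.true_variants)]:
            extra = set(keys) - declared
            if extra:
                raise ValueError(f"truth field {name} indexes undeclared samples {extra}")
        for s, ex in self.exposures.items():
            if abs(sum(ex.values()) - 1.0) > 1e-9:
                raise ValueError(f"exposures of {s} do not sum to 1")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["silenced_pairs"] = [list(p) for p in self.silenced_pairs]
        payload["true_variants"] = {
            s: [[v.chromosome, v.position, v.ref, v.alt] for v in vs]
            for s, vs in self.true_variants.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    truth: CohortTruth
    arm_table: list[ArmDefinition]
    profiles: list[SegmentedCopyNumberProfile]
    call_sets: dict[str, list[VariantCall]]
    germline_sites: set
    pon_sites: set
    expression: OmicsMatrix
    beta: OmicsMatrix
    probe_map: pd.DataFrame
    gene_sets: GeneSetCollection
    signatures: pd.DataFrame


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def _tile_arm(rng, arm: ArmDefinition, mean_log2: float, noise_sd: float,
              n_segments: int, min_len: int) -> list[GenomicSegment]:
    """Split an arm into contiguous segments centred at ``mean_log2``."""
    n_segments = max(1, min(n_segments, arm.length // min_len))
    cuts = np.sort(rng.choice(
        np.arange(arm.start + min_len, arm.end - min_len + 1, min_len),
        size=n_segments - 1, replace=False)) if n_segments > 1 else np.array([], int)
    bounds = [arm.start, *cuts.tolist(), arm.end]
    segs = []
    for s, e in zip(bounds, bounds[1:]):
        log2 = mean_log2 + rng.normal(0.0, noise_sd)
        segs.append(GenomicSegment(arm.chromosome, int(s), int(e), float(log2),
                                   n_probes=max(2, (e - s) // 50_000)))
    return segs


def simulate_copy_number(
    config: SimulationConfig,
    truth: CohortTruth,
    arm_table: list[ArmDefinition] | None = None,
) -> list[SegmentedCopyNumberProfile]:
    """Arm-event-structured segmented profiles; fills arm/CIN truth.

    A planted event covers ``event_cover_fraction`` of the arm with
    segments at log2 +/- ``event_log2`` (plus Gaussian segment noise);
    the rest of the arm, and all neutral arms, sit at log2 0 plus
    noise.  Segments tile each arm without gaps or overlap.
    """
    arms = arm_table if arm_table is not None else builtin_arm_table()
    for arm in arms:
        if arm.length < 2 * config.min_segment_length:
            raise ValueError(
                f"arm {arm.arm_name} shorter than twice the minimum segment length")
    rng = _substream(config.seed, "copy_number")
    excluded = {"18p", "18q", "21p", "21q"}
    profiles = []
    for sample in config.sample_ids:
        st = truth.subtype[sample]
        probs = config.arm_event_probs.get(st, {})
        segs: list[GenomicSegment] = []
        events: dict[str, str] = {}
        for arm in arms:
            p_gain, p_loss = probs.get(
                arm.arm_name,
                (config.background_event_prob, config.background_event_prob))
            u = rng.random()
            if not arm.callable:
                event = "neutral"  # never plant events on non-callable arms
            elif u < p_gain:
                event = "gain"
            elif u < p_gain + p_loss:
                event = "loss"
            else:
                event = "neutral"
            events[arm.arm_name] = event
            n_seg = 1 + rng.poisson(config.segments_per_arm_mean - 1)
            if event == "neutral":
                segs.extend(_tile_arm(rng, arm, 0.0, config.log2_noise_sd,
                                      n_seg, config.min_segment_length))
            else:
                sign = 1.0 if event == "gain" else -1.0
                split = arm.start + int(arm.length * config.event_cover_fraction)
                ev_arm = ArmDefinition(arm.arm_name, arm.chromosome,
                                       arm.start, split, arm.callable)
                segs.extend(_tile_arm(rng, ev_arm, sign * config.event_log2,
                                      config.log2_noise_sd, n_seg,
                                      config.min_segment_length))
                if arm.end - split >= config.min_segment_length:
                    segs.append(GenomicSegment(
                        arm.chromosome, split, arm.end,
                        float(rng.normal(0.0, config.log2_noise_sd)),
                        n_probes=max(2, (arm.end - split) // 50_000)))
        truth.arm_events[sample] = events
        qualifying = [a for a, e in events.items()
                      if e == "loss" and a not in excluded]
        truth.cin_label[sample] = "SCNA_high" if qualifying else "SCNA_low"
        profiles.append(SegmentedCopyNumberProfile(sample, segs))
    return profiles


# ---------------------------------------------------------------------------
# methylation / expression coupling
# ---------------------------------------------------------------------------

def simulate_methylation_expression(
    config: SimulationConfig,
    truth: CohortTruth,
    expression: OmicsMatrix | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.DataFrame]:
    """Promoter beta values inversely coupled to expression.

    Non-silenced (gene, sample) pairs draw beta from a low component
    concentrated under 0.15; silenced pairs draw from a high component
    concentrated above 0.5 and have their expression multiplied by the
    suppression factor.  Returns (beta matrix, expression matrix,
    probe map); silenced pairs are recorded in the truth object.
    """
    rng = _substream(config.seed, "methylation")
    genes = config.gene_ids
    samples = config.sample_ids
    if expression is None:
        expression = simulate_expression_subtypes(config, truth)
    expr = expression.values.copy()
    if any(g not in expr.index for g in genes[:1]):
        raise ValueError("expression matrix lacks the configured genes")

    n_sil = config.n_silenced_genes
    if n_sil > len(genes):
        raise ValueError("more silenced genes configured than genes exist")
    silenced_genes = genes[:n_sil]  # deterministic, disjoint from pathway genes below
    a_lo, b_lo = config.beta_low_params
    a_hi, b_hi = config.beta_high_params

    beta = pd.DataFrame(
        rng.beta(a_lo, b_lo, size=(len(genes), len(samples))),
        index=[f"cg_{g}" for g in genes], columns=samples)
    truth.silenced_pairs = []
    r_hi, r_lo = config.differential_silenced_rates
    subtypes = config.subtypes
    for gi, gene in enumerate(silenced_genes):
        differential = gi == 0 and len(subtypes) >= 2
        for sample in samples:
            if differential:
                rate = r_hi if truth.subtype[sample] == subtypes[0] else r_lo
            else:
                rate = config.silencing_rate
            if rng.random() < rate:
                beta.loc[f"cg_{gene}", sample] = rng.beta(a_hi, b_hi)
                expr.loc[gene, sample] *= config.suppression_factor
                truth.silenced_pairs.append((gene, sample))
    # subtype-differential marker probes: hypermethylated in one subtype,
    # unmethylated in the rest; mapped to no gene, so they carry platform
    # structure without touching the silencing calls
    if config.n_methylation_markers and len(subtypes) >= 2:
        rows = []
        for i in range(config.n_methylation_markers):
            hyper_in = subtypes[i % len(subtypes)]
            row = [rng.beta(a_hi, b_hi) if truth.subtype[s] == hyper_in
                   else rng.beta(a_lo, b_lo) for s in samples]
            rows.append(row)
        markers = pd.DataFrame(
            rows, index=[f"cgM_{i:04d}" for i in range(config.n_methylation_markers)],
            columns=samples)
        beta = pd.concat([beta, markers])
    probe_map = pd.DataFrame({"probe": [f"cg_{g}" for g in genes], "gene": genes})
    return (OmicsMatrix(beta, "beta"),
            OmicsMatrix(expr, expression.scale),
            probe_map)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def _draw_context(rng, sig_probs: np.ndarray) -> tuple[str, str, str]:
    """Draw a channel from a 96-vector; return (ref, alt, context) on a
    random strand (50% purine-strand to exercise the collapse)."""
    idx = rng.choice(96, p=sig_probs)
    label = CONTEXT_BINS[idx]
    five, rest = label.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    context = five + ref + three
    if rng.random() < 0.5:
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    return ref, alt, context


def _random_site(rng, arms: list[ArmDefinition]) -> tuple[str, int]:
    arm = arms[rng.integers(len(arms))]
    return arm.chromosome, int(rng.integers(arm.start, arm.end))


def simulate_mutation_callsets(
    config: SimulationConfig,
    truth: CohortTruth,
    arm_table: list[ArmDefinition] | None = None,
    signatures: pd.DataFrame | None = None,
) -> tuple[dict[str, list[VariantCall]], set, set]:
    """Per-caller variant call sets with planted false positives.

    True variants draw a VAF from a Beta distribution, binomial read
    counts at the configured depths, and a trinucleotide context from
    the sample's signature-mixture exposure.  Each caller misses a true
    variant with the dropout probability and adds three classes of
    false positives: low-evidence records (alt count 1-2 at full
    depth), germline-blacklist-site records and oxoG-artifact-like
    orientation-biased C>A records — each removable by the matching
    ensemble filter.  Returns (call sets, germline sites, panel-of-
    normals sites).
    """
    if len(config.callers) < 2:
        raise ValueError("need >= 2 callers configured")
    if config.tumor_depth <= 0 or config.normal_depth <= 0:
        raise ValueError("depths must be positive")
    arms = arm_table if arm_table is not None else builtin_arm_table()
    sigs = signatures if signatures is not None else default_signature_definitions()
    rng = _substream(config.seed, "mutations")

    germline_sites = {(*_random_site(rng, arms), "*")
                      for _ in range(config.n_germline_sites)}
    pon_sites = {(*_random_site(rng, arms), "*")
                 for _ in range(config.n_pon_sites)}
    blacklist_positions = sorted(germline_sites | pon_sites)
    blocked = {(c, p) for c, p, _ in blacklist_positions}
    # fixed allele per blacklist site, so callers never disagree on ref
    uniform = np.full(96, 1.0 / 96)
    site_allele = {(c, p): _draw_context(rng, uniform)
                   for c, p, _ in blacklist_positions}

    sig_names = list(sigs.index)
    a_v, b_v = config.vaf_beta_params
    call_sets: dict[str, list[VariantCall]] = {c: [] for c in config.callers}

    for sample in config.sample_ids:
        st = truth.subtype[sample]
        mix = np.array([truth.exposures[sample][s] for s in sig_names])
        probs = mix @ sigs.to_numpy()
        probs = probs / probs.sum()
        n_true = rng.poisson(config.mutations_per_sample)
        truth.true_variants[sample] = []
        seen_sites: set[tuple[str, int]] = set()
        for _ in range(n_true):
            chrom, pos = _random_site(rng, arms)
            while (chrom, pos) in blocked or (chrom, pos) in seen_sites:
                chrom, pos = _random_site(rng, arms)
            seen_sites.add((chrom, pos))
            ref, alt, context = _draw_context(rng, probs)
            vaf = rng.beta(a_v, b_v)
            t_depth = max(1, rng.poisson(config.tumor_depth))
            t_alt = int(rng.binomial(t_depth, vaf))
            n_depth = max(1, rng.poisson(config.normal_depth))
            n_alt = int(rng.binomial(n_depth, config.normal_error_rate))
            f1r2 = int(rng.binomial(t_alt, 0.5))
            v = VariantCall(
                sample_id=sample, chromosome=chrom, position=pos,
                ref=ref, alt=alt,
                t_ref_count=t_depth - t_alt, t_alt_count=t_alt,
                n_ref_count=n_depth - n_alt, n_alt_count=n_alt,
                caller="truth", context=context,
                alt_f1r2=f1r2, alt_f2r1=t_alt - f1r2,
            )
            truth.true_variants[sample].append(v)
            for caller in config.callers:
                if rng.random() >= config.caller_dropout:
                    call_sets[caller].append(
                        VariantCall(**{**asdict(v), "caller": caller}))
        # planted false positives, per caller
        bl_list = blacklist_positions
        fp_sites: set[tuple[str, int]] = set()
        for caller in config.callers:
            for _ in range(rng.poisson(config.fp_low_evidence_rate)):
                chrom, pos = _random_site(rng, arms)
                if (chrom, pos) in seen_sites or (chrom, pos) in fp_sites:
                    continue
                fp_sites.add((chrom, pos))
                ref, alt, context = _draw_context(rng, probs)
                t_depth = max(10, rng.poisson(config.tumor_depth))
                t_alt = int(rng.integers(1, 3))  # 1-2 reads: below every minimum
                call_sets[caller].append(VariantCall(
                    sample_id=sample, chromosome=chrom, position=pos,
                    ref=ref, alt=alt,
                    t_ref_count=t_depth - t_alt, t_alt_count=t_alt,
                    n_ref_count=max(1, rng.poisson(config.normal_depth)),
                    n_alt_count=0, caller=caller, context=context))
            for _ in range(rng.poisson(config.fp_blacklist_rate)):
                chrom, pos, _ = bl_list[rng.integers(len(bl_list))]
                ref, alt, context = site_allele[(chrom, pos)]
                t_depth = max(10, rng.poisson(config.tumor_depth))
                t_alt = int(rng.binomial(t_depth, 0.5))
                if t_alt < 2:
                    t_alt = 2
                call_sets[caller].append(VariantCall(
                    sample_id=sample, chromosome=chrom, position=pos,
                    ref=ref, alt=alt,
                    t_ref_count=t_depth - t_alt, t_alt_count=t_alt,
                    n_ref_count=max(1, rng.poisson(config.normal_depth)),
                    n_alt_count=0, caller=caller, context=context))
            for _ in range(rng.poisson(config.fp_oxog_rate)):
                chrom, pos = _random_site(rng, arms)
                if ((chrom, pos) in seen_sites or (chrom, pos) in blocked
                        or (chrom, pos) in fp_sites):
                    continue
                fp_sites.add((chrom, pos))
                t_depth = max(10, rng.poisson(config.tumor_depth))
                t_alt = int(rng.integers(8, 15))
                call_sets[caller].append(VariantCall(
                    sample_id=sample, chromosome=chrom, position=pos,
                    ref="C", alt="A",
                    t_ref_count=t_depth - t_alt, t_alt_count=t_alt,
                    n_ref_count=max(1, rng.poisson(config.normal_depth)),
                    n_alt_count=0, caller=caller, context="ACA",
                    alt_f1r2=0, alt_f2r1=t_alt))
    return call_sets, germline_sites, pon_sites


# ---------------------------------------------------------------------------
# expression subtypes
# ---------------------------------------------------------------------------

def simulate_expression_subtypes(
    config: SimulationConfig,
    truth: CohortTruth,
) -> tuple[OmicsMatrix, GeneSetCollection] | OmicsMatrix:
    """RPKM matrix with pathway-coherent subtype shifts.

    Genes of a planted differential pathway share a common shift
    (``differential_effect_log10`` on the log10 scale) between the
    first subtype and the rest; all other genes are exchangeable
    between groups.  Pathways (differential and null) are recorded on
    the cohort's gene-set collection, which is attached to the return
    value as ``.gene_sets``.
    """
    rng = _substream(config.seed, "expression")
    genes = config.gene_ids
    samples = config.sample_ids
    baseline = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=len(genes))
    noise = rng.lognormal(mean=0.0,
                          sigma=config.expression_noise_sd_log10 * np.log(10),
                          size=(len(genes), len(samples)))
    values = baseline[:, None] * noise

    # reserve the first n_silenced_genes for the methylation module;
    # pathway genes start after them so the two plants never collide
    start = config.n_silenced_genes
    k = config.differential_pathway_size
    sets: dict[str, list[str]] = {}
    truth.differential_pathways = {}
    for i in range(config.n_differential_pathways):
        members = genes[start + i * k: start + (i + 1) * k]
        if len(members) < k:
            raise ValueError("not enough genes for the configured pathways")
        name = f"DIFF_PATHWAY_{i+1}"
        sets[name] = members
        truth.differential_pathways[name] = config.differential_effect_log10
    pool_start = start + config.n_differential_pathways * k
    for i in range(config.n_null_pathways):
        size = int(rng.integers(10, 51))
        members = [genes[pool_start + int(j)]
                   for j in rng.choice(len(genes) - pool_start, size, replace=False)]
        sets[f"NULL_PATHWAY_{i+1}"] = members

    first = config.subtypes[0]
    shifted = [s for s in samples if truth.subtype[s] == first]
    col_idx = [samples.index(s) for s in shifted]
    factor = 10.0 ** config.differential_effect_log10
    for name in truth.differential_pathways:
        row_idx = [genes.index(g) for g in sets[name]]
        values[np.ix_(row_idx, col_idx)] *= factor

    expr = OmicsMatrix(pd.DataFrame(values, index=genes, columns=samples), "RPKM")
    expr.gene_sets = GeneSetCollection(
        sets, {n: "synthetic planted pathway" for n in sets})
    return expr


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate all platforms of one cohort under a single master seed."""
    config = config or SimulationConfig()
    samples = config.sample_ids
    truth = CohortTruth(
        sample_ids=samples,
        subtype={s: s.rsplit("-", 1)[0] for s in samples},
    )
    rng = _substream(config.seed, "exposures")
    sigs = default_signature_definitions()
    mixtures = {
        st: np.roll(np.array([0.6, 0.2, 0.2]), i)[: len(sigs)]
        for i, st in enumerate(config.subtypes)
    }
    for s in samples:
        alpha = mixtures[truth.subtype[s]] * config.signature_concentration
        ex = rng.dirichlet(alpha)
        ex = ex / ex.sum()
        truth.exposures[s] = dict(zip(sigs.index, (float(x) for x in ex)))

    arm_table = builtin_arm_table()
    profiles = simulate_copy_number(config, truth, arm_table)
    expr = simulate_expression_subtypes(config, truth)
    gene_sets = expr.gene_sets
    beta, expr, probe_map = simulate_methylation_expression(config, truth, expr)
    call_sets, germline, pon = simulate_mutation_callsets(
        config, truth, arm_table, sigs)
    truth.validate()
    return SyntheticCohort(
        config=config, truth=truth, arm_table=arm_table, profiles=profiles,
        call_sets=call_sets, germline_sites=germline, pon_sites=pon,
        expression=expr, beta=beta, probe_map=probe_map,
        gene_sets=gene_sets, signatures=sigs,
    )
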