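"""End-to-end orchestration of the analysis stages on one cohort.

The pipeline is a thin composition: each stage is the same function a
user would call directly, with the same parameters, and any stage
whose inputs are absent is skipped without affecting the others.
Every output file carries a provenance header (tool version, seed,
stage parameters) and the log reports counts in and out of each
filtering stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    GeneSetCollection,
    OmicsMatrix,
    read_arm_table,
    read_gmt,
    read_maf,
    read_matrix,
    read_seg,
    read_site_list,
    write_arm_table,
    write_gmt,
    write_maf,
    write_matrix,
    write_seg,
    builtin_arm_table,
)
from .cin_classifier import cohort_cin
from .mutation_ensemble import FilterParams, run_ensemble
from .mutation_signatures import (
    APOBEC_BINS,
    ard_nmf,
    build_catalog,
    context_fraction,
    C_TO_A_BINS,
    group_fraction_tests,
    signature_fractions,
)
from .pathway_score import score_all_pathways
from .silencing_caller import (
    ContingencyTable2x2,
    call_silencing_matrix,
    fisher_exact_2x2,
    silencing_subtype_association,
)
from .subtype_cluster import (
    hierarchical_cluster,
    integrate_clusters,
    select_features,
    transform_for_clustering,
)
from .synthetic_cohort import SimulationConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger("esomix")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_cohort"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """File paths per platform plus stage parameters.

    Leave a platform's path ``None`` to skip the stages that need it.
    ``simulate`` generates the full synthetic cohort into ``out_dir``
    first and uses those files as inputs.
    """

    out_dir: str = "esomix-out"
    seed: int = 0
    simulate: bool = False
    seg: str | None = None
    arms: str | None = None
    mafs: list[str] = field(default_factory=list)
    germline_sites: str | None = None
    pon_sites: str | None = None
    expression: str | None = None
    beta: str | None = None
    probe_map: str | None = None
    gmt: str | None = None
    groups: str | None = None            # 2-column TSV: sample, label
    n_clusters: int = 2
    n_permutations: int = 10_000
    integration_method: str = "COCA"
    k_max: int = 20
    nmf_restarts: int = 10
    filter_params: FilterParams = field(default_factory=FilterParams)


def _provenance(config: PipelineConfig, stage: str, **params) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return (f" esomix v{__version__} | stage={stage} | seed={config.seed}"
            + (f" | {items}" if items else ""))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write every platform of a synthetic cohort as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "seg": out / "cohort.seg",
        "arms": out / "arms.tsv",
        "expression": out / "expression.tsv",
        "beta": out / "beta.tsv",
        "probe_map": out / "probe_map.tsv",
        "gmt": out / "pathways.gmt",
        "groups": out / "groups.tsv",
        "germline": out / "germline_sites.bed",
        "pon": out / "pon_sites.bed",
        "truth": out / "truth.json",
    }
    write_seg(cohort.profiles, paths["seg"])
    write_arm_table(cohort.arm_table, paths["arms"])
    write_matrix(cohort.expression, paths["expression"])
    write_matrix(cohort.beta, paths["beta"])
    cohort.probe_map.to_csv(paths["probe_map"], sep="\t", index=False)
    write_gmt(cohort.gene_sets, paths["gmt"])
    with open(paths["groups"], "w") as fh:
        fh.write("sample\tlabel\n")
        for s in cohort.truth.sample_ids:
            fh.write(f"{s}\t{cohort.truth.subtype[s]}\n")
    for key, sites in [("germline", cohort.germline_sites), ("pon", cohort.pon_sites)]:
        with open(paths[key], "w") as fh:
            for chrom, pos, alt in sorted(sites):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{alt}\n")
    cohort.truth.to_json(paths["truth"])
    for caller, calls in cohort.call_sets.items():
        p = out / f"calls_{caller}.maf"
        write_maf(calls, p)
        paths[f"maf_{caller}"] = p
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are present; return a report bundle.

    Stage order: simulate (optional) -> CIN calling -> mutation
    ensemble -> signatures -> pathway scoring -> silencing -> per-
    platform clustering -> integration -> summary.  A stage failure
    aborts its dependants with a :class:`PipelineError` naming the
    stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    if config.simulate:
        try:
            cohort = simulate_cohort(SimulationConfig(seed=config.seed))
            paths = write_cohort(cohort, out / "simulated")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", exc) from exc
        config.seg = str(paths["seg"])
        config.arms = str(paths["arms"])
        config.expression = str(paths["expression"])
        config.beta = str(paths["beta"])
        config.probe_map = str(paths["probe_map"])
        config.gmt = str(paths["gmt"])
        config.groups = str(paths["groups"])
        config.germline_sites = str(paths["germline"])
        config.pon_sites = str(paths["pon"])
        config.mafs = [str(paths[k]) for k in paths if k.startswith("maf_")]
        report["stages"].append("simulate")

    groups = None
    if config.groups:
        g = pd.read_csv(config.groups, sep="\t")
        groups = pd.Series(g.iloc[:, 1].to_numpy(), index=g.iloc[:, 0].astype(str))

    summary = pd.DataFrame()
    platform_clusterings = []

    # --- CIN -------------------------------------------------------------
    if config.seg:
        try:
            profiles = read_seg(config.seg)
            arm_table = (read_arm_table(config.arms) if config.arms
                         else builtin_arm_table())
            cin_calls, arm_freq = cohort_cin(profiles, arm_table)
            header = _provenance(config, "cin")
            with open(out / "cin_calls.tsv", "w") as fh:
                fh.write(f"#{header}\n")
                cin_calls.to_csv(fh, sep="\t")
            arm_freq.to_csv(out / "arm_frequencies.tsv", sep="\t")
            summary["cin_label"] = cin_calls["label"]
            report["stages"].append("cin")
            report["n_scna_high"] = int((cin_calls["label"] == "SCNA_high").sum())
            logger.info("CIN: %d/%d samples SCNA-high",
                        report["n_scna_high"], len(cin_calls))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cin", exc) from exc

    # --- mutation ensemble + signatures ---------------------------------
    merged = None
    if config.mafs:
        try:
            call_sets = [read_maf(p) for p in sorted(config.mafs)]
            germ = read_site_list(config.germline_sites) if config.germline_sites else set()
            pon = read_site_list(config.pon_sites) if config.pon_sites else set()
            merged, decisions = run_ensemble(call_sets, germ, pon,
                                             config.filter_params)
            n_in = len(decisions)
            write_maf([m.variant for m in merged], out / "merged.maf",
                      extra_columns={"callers": [";".join(m.callers) for m in merged]},
                      header_comment=_provenance(config, "merge"))
            rejects = [(k, ";".join(d.reasons))
                       for k, d in decisions.items() if not d.kept]
            with open(out / "rejects.tsv", "w") as fh:
                fh.write("sample\tchromosome\tposition\tref\talt\treasons\n")
                for (s, c, p, r, a), reasons in rejects:
                    fh.write(f"{s}\t{c}\t{p + 1}\t{r}\t{a}\t{reasons}\n")
            logger.info("ensemble: %d variants in, %d kept, %d rejected",
                        n_in, len(merged), len(rejects))
            report["stages"].append("ensemble")
            report["n_merged"] = n_in
            report["n_kept"] = len(merged)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("ensemble", exc) from exc

    if merged is not None:
        try:
            catalog = build_catalog(merged)
            if catalog.counts.shape[1] >= 2 and catalog.counts.to_numpy().sum() > 0:
                decomp = ard_nmf(catalog, k_max=config.k_max, seed=config.seed,
                                 n_restarts=config.nmf_restarts)
                fractions = signature_fractions(decomp)
                decomp.w.T.to_csv(out / "signatures_W.tsv", sep="\t")
                decomp.h.to_csv(out / "signatures_H.tsv", sep="\t")
                fractions.to_csv(out / "signature_fractions.tsv", sep="\t")
                for sig in fractions.columns:
                    summary[f"fraction_{sig}"] = fractions[sig]
                summary["apobec_context_fraction"] = context_fraction(
                    catalog, APOBEC_BINS)
                summary["c_to_a_fraction"] = context_fraction(catalog, C_TO_A_BINS)
                report["stages"].append("signatures")
                report["n_signatures"] = decomp.k
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("signatures", exc) from exc

    # --- expression stages -----------------------------------------------
    expr = None
    if config.expression:
        expr = read_matrix(config.expression, "RPKM")
    if expr is not None and config.gmt and groups is not None:
        try:
            gmt = read_gmt(config.gmt)
            results = score_all_pathways(expr, groups, gmt,
                                         n_perm=config.n_permutations,
                                         seed=config.seed)
            df = pd.DataFrame([{
                "pathway": r.pathway, "k": r.k, "S": r.score,
                "P_s": r.p_s, "n_perm": r.n_permutations} for r in results])
            with open(out / "pathway_scores.tsv", "w") as fh:
                fh.write(f"#{_provenance(config, 'pathway', n_perm=config.n_permutations)}\n")
                df.to_csv(fh, sep="\t", index=False)
            report["stages"].append("pathway")
            report["n_significant_pathways"] = int((df["P_s"] < 1e-3).sum())
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("pathway", exc) from exc

    if expr is not None and config.beta and config.probe_map:
        try:
            beta = read_matrix(config.beta, "beta")
            probe_map = pd.read_csv(config.probe_map, sep="\t")
            calls = call_silencing_matrix(beta, expr, probe_map)
            calls.calls.astype(int).to_csv(out / "silencing_calls.tsv", sep="\t")
            report["stages"].append("silencing")
            report["n_silencing_calls"] = int(calls.calls.to_numpy().sum())
            if groups is not None and groups.nunique() == 2:
                assoc = silencing_subtype_association(calls, groups)
                assoc.to_csv(out / "silencing_association.tsv", sep="\t")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("silencing", exc) from exc

    # --- clustering + integration ----------------------------------------
    if expr is not None:
        try:
            feats = select_features(expr)
            trans = transform_for_clustering(expr.subset_rows(feats))
            pc = hierarchical_cluster(trans, k=config.n_clusters,
                                      platform="mrna")
            platform_clusterings.append(pc)
            summary["mrna_cluster"] = pc.labels
            if config.beta:
                beta = read_matrix(config.beta, "beta")
                pcm = hierarchical_cluster(
                    OmicsMatrix(beta.values, "zscore"),
                    k=config.n_clusters, platform="methylation")
                platform_clusterings.append(pcm)
                summary["methylation_cluster"] = pcm.labels
            if len(platform_clusterings) >= 2:
                integ = integrate_clusters(platform_clusterings,
                                           method=config.integration_method,
                                           k=config.n_clusters)
                summary["integrated_cluster"] = integ.labels
                report["stages"].append("integrate")
            report["stages"].append("cluster")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cluster", exc) from exc

    # --- summary + subtype enrichment ------------------------------------
    if groups is not None and not summary.empty:
        summary["group"] = groups.reindex(summary.index)
        if "cin_label" in summary and summary["group"].nunique() == 2:
            ct = pd.crosstab(summary["group"], summary["cin_label"])
            if ct.shape == (2, 2):
                p = fisher_exact_2x2(ContingencyTable2x2(
                    *ct.to_numpy().ravel().tolist()))
                report["cin_group_fisher_p"] = p
        frac_cols = [c for c in summary if c.startswith("fraction_")]
        if frac_cols and summary["group"].nunique() >= 2:
            report["fraction_group_tests"] = {
                c: group_fraction_tests(summary[c].dropna(),
                                        summary["group"].dropna(),
                                        test="kruskal_wallis")
                for c in frac_cols
            }
    with open(out / "summary.tsv", "w") as fh:
        fh.write(f"#{_provenance(config, 'summary')}\n")
        summary.to_csv(fh, sep="\t", index_label="sample")
    report["summary_path"] = str(out / "summary.tsv")
    return report
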