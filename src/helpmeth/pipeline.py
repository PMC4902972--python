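"""End-to-end orchestration: quantify -> filter -> batch-adjust -> composition
prune -> PCA attribution -> differential methylation -> variance screen,
with per-stage outputs, site accounting and a machine-readable manifest."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellcomp, covassoc, io, varscreen
from .clinical import summarize_cohort
from .combat import combat, group_design
from .config import PipelineConfig
from .dm import fit_models, model_overlap
from .filters import apply_filters, flag_repeats, flag_snp_flank
from .quantify import quantify

log = logging.getLogger("helpmeth")

STAGES = ["quantify", "filter", "combat", "cellcomp", "pca", "dm", "varscan"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run report (also written as JSON).

    Inputs are read from the paths in ``config``; each stage writes its
    output table under ``config.outdir``.  The manifest records the
    seed, every stage parameter and the number of sites surviving each
    stage, which is sufficient to reproduce any stage in isolation.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    accounting: dict[str, int] = {}
    completed: list[str] = []

    def _stage(name):
        log.info("stage %s", name)
        completed.append(name)

    sites = io.read_site_table(config.sites)
    hpaii = io.read_matrix_tsv(config.hpaii)
    mspi = io.read_mspi_tsv(config.mspi)
    meta = io.read_metadata(config.metadata)
    accounting["input"] = len(sites)

    # --- quantify ---------------------------------------------------
    _stage("quantify")
    meth = quantify(hpaii, mspi, min_mspi=config.min_mspi)
    io.write_matrix_tsv(meth, outdir / "methylation_raw.tsv")

    # --- filter -----------------------------------------------------
    _stage("filter")
    snps = io.read_positions_bed(config.snps)
    repeats = io.read_bed(config.repeats)
    sites = flag_snp_flank(sites, snps, flank=config.flank)
    sites = flag_repeats(sites, repeats)
    sites["mspi_count"] = mspi.reindex(sites.index).fillna(0).astype(int)
    retained_sites, report = apply_filters(sites, min_mspi=config.min_mspi)
    meth = meth.loc[retained_sites.index]
    accounting["filter"] = len(meth)
    (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    retained_sites.index.to_series().to_csv(
        outdir / "retained_sites.tsv", sep="\t", index=False
    )

    # --- batch adjustment -------------------------------------------
    _stage("combat")
    adjusted, model = combat(meth, meta["batch"], protect=group_design(meta["group"]))
    io.write_matrix_tsv(adjusted, outdir / "methylation_combat.tsv")
    accounting["combat"] = len(adjusted)

    # --- cell-composition pruning -----------------------------------
    _stage("cellcomp")
    wgbs_ae = io.read_coverage(config.wgbs_ae)
    wgbs_as = io.read_coverage(config.wgbs_as)
    comp = cellcomp.composition_prune(
        adjusted,
        retained_sites,
        wgbs_ae,
        wgbs_as,
        meta,
        dmr_p=config.dmr_p,
        candidate_window=config.candidate_window,
        pheno_alpha=config.pheno_alpha,
        rho_threshold=config.rho_threshold,
    )
    pruned = adjusted.loc[comp.retained]
    comp.candidates.to_csv(outdir / "reporter_candidates.tsv", sep="\t")
    accounting["cellcomp"] = len(pruned)

    # --- PCA covariate attribution ----------------------------------
    _stage("pca")
    k = min(config.n_pcs, len(meta) - 1, len(pruned))
    pcs = covassoc.pca(pruned, k=k)
    heat = covassoc.pc_covariate_matrix(
        pcs,
        meta[[c for c in ("group", "maxSBP", "maxDBP", "proteinuria_grade",
                          "batch", "sex", "mgso4", "maternal_age",
                          "gestational_week") if c in meta.columns]],
    )
    heat.pvalues.to_csv(outdir / "pc_covariate_p.tsv", sep="\t")
    heat.joint.to_csv(outdir / "covariate_joint_p.tsv", sep="\t")
    covassoc.plot_heatmap(heat, str(outdir / "pc_covariate_heatmap.png"))
    accounting["pca"] = len(pruned)

    # --- differential methylation ------------------------------------
    _stage("dm")
    dm_results = fit_models(pruned, meta, fdr=config.fdr, delta=config.delta)
    dm_results.to_csv(outdir / "dm_results.tsv", sep="\t")
    overlap = model_overlap(dm_results)
    (outdir / "dm_overlap.json").write_text(json.dumps(overlap, indent=2))
    accounting["dm"] = len(dm_results)

    # --- variance screen ---------------------------------------------
    _stage("varscan")
    var_results = varscreen.call_var_hpaii(
        pruned, meta["group"], q_threshold=config.var_q,
        ratio_threshold=config.var_ratio,
    )
    var_results.to_csv(outdir / "var_results.tsv", sep="\t")
    genes = io.read_genes_bed(config.genes)
    site_genes = varscreen.assign_genes(
        retained_sites.loc[retained_sites.index.isin(pruned.index)],
        genes,
        window=config.gene_window,
    )
    gene_counts = varscreen.per_gene_counts(var_results, site_genes)
    gene_counts.rename("n_var_sites").to_csv(outdir / "var_gene_counts.tsv", sep="\t")

    # --- clinical summary (not a matrix stage) -----------------------
    clin = summarize_cohort(meta)
    clin.to_csv(outdir / "cohort_characteristics.tsv", sep="\t")

    manifest = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": completed,
        "site_accounting": accounting,
        "filter_report": report.to_dict(),
        "reporter": comp.reporter,
        "dm_overlap": overlap,
        "n_dm": {m: int(dm_results[f"dm_{m}"].sum()) for m in ("model1", "model2", "model3")},
        "n_var": int(var_results["var_flag"].sum()),
        "runtime_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
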