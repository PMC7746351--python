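"""Full-workflow orchestration: simulate (or load) inputs, then run
deconvolution, consensus clustering, differential expression, TME-score
construction, survival comparison and ROC, mutational signatures and CNV
scoring in dependency order, producing TSV outputs and a JSON run manifest.

Stage seeds derive from one master seed by stable hashing of the stage name,
so adding a stage never perturbs the randomness of existing ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cnv_gistic import arm_level, gscore, make_bins
from .consensus import consensus_cluster
from .deconvolution import deconvolve
from .dge import deg_intersection, filter_low_expression, pairwise_contrasts, voom_transform
from .io_core import (
    ClinicalTable,
    ExpressionMatrix,
    read_clinical,
    read_expression,
    read_maf,
    read_seg,
    write_clinical,
    write_expression,
    write_maf,
    write_seg,
)
from .mutsig import (
    apobec_enrichment,
    build_catalogue,
    cluster_exposures,
    compute_tmb,
    cosine_match,
    extract_signatures,
    load_reference_signatures,
)
from .survival import cell_network, cox_fit, delong_compare, logrank_test, roc_auc
from .synthetic import SimConfig, simulate_cnv, simulate_cohort, simulate_mutations, toy_genome
from .tme_signature import (
    assign_directions,
    cluster_signature_genes,
    compute_tme_score,
    dichotomize,
    rf_reduce,
    score_gene_clusters,
)

logger = logging.getLogger("tmepipe")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: sha256(stage name || master seed) mod 2^31."""
    h = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: dict, outdir) -> dict:
    """Execute the full workflow from one config mapping; returns the manifest.

    Config keys (all optional except ``seed``): ``simulate`` (bool, default
    True), ``n_samples``, input paths (``expression``, ``clinical``, ``maf``,
    ``seg``) when not simulating, and per-stage parameter overrides
    (``n_permutations``, ``n_resamples``, ``maxstat_perms``, ``cnv_perms``,
    ``nmf_restarts``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config["seed"])
    manifest: dict = {"config": {k: v for k, v in config.items()},
                      "version": __version__, "master_seed": master_seed,
                      "stages": {}}
    summary: dict = {}

    def record(stage, outputs, t0, seed=None):
        manifest["stages"][stage] = {
            "outputs": {str(p.name): _hash_file(p) for p in outputs},
            "wall_time_s": round(time.time() - t0, 3),
            "seed": seed,
        }

    def run_stage(stage, fn):
        t0 = time.time()
        try:
            outputs, seed = fn()
        except Exception as exc:  # preserve partial outputs, name the stage
            raise PipelineError(stage, exc) from exc
        record(stage, outputs, t0, seed)
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

    # --- inputs -----------------------------------------------------------
    state: dict = {}

    def stage_inputs():
        seed = stage_seed(master_seed, "simulate")
        if config.get("simulate", True):
            sim = SimConfig(seed=seed, n_samples=int(config.get("n_samples", 300)))
            expr, clin, truth = simulate_cohort(sim)
            muts, expo, sigs = simulate_mutations(sim)
            segs, cnv_truth = simulate_cnv(sim)
            truth_json = {
                "pattern": truth.pattern.to_dict(),
                "planted_degs": truth.planted_degs,
            }
            (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
            state.update(expr=expr, clin=clin, muts=muts, segs=segs, truth=truth)
        else:
            for key, reader in (("expression", read_expression), ("clinical", read_clinical),
                                ("maf", read_maf), ("seg", read_seg)):
                if key not in config:
                    raise ValueError(f"config missing input path {key!r}")
            state.update(
                expr=read_expression(config["expression"]),
                clin=read_clinical(config["clinical"]),
                muts=read_maf(config["maf"]),
                segs=read_seg(config["seg"]),
                truth=None,
            )
        write_expression(state["expr"], outdir / "expression.tsv")
        write_clinical(state["clin"], outdir / "clinical.tsv")
        write_maf(state["muts"], outdir / "mutations.tsv")
        write_seg(state["segs"], outdir / "segments.tsv")
        return [outdir / f for f in
                ("expression.tsv", "clinical.tsv", "mutations.tsv", "segments.tsv")], seed

    run_stage("inputs", stage_inputs)

    # --- deconvolution ----------------------------------------------------
    def stage_deconvolve():
        seed = stage_seed(master_seed, "deconvolve")
        from .io_core import read_signature_matrix
        from .synthetic import default_reference

        ref = (read_signature_matrix(config["reference"])
               if config.get("reference")
               else default_reference(state["expr"].shape[0]))
        cf = deconvolve(state["expr"], ref,
                        n_permutations=int(config.get("n_permutations", 100)),
                        seed=seed)
        out = cf.fractions.copy()
        out["rmse"] = cf.rmse
        out["pearson_r"] = cf.pearson_r
        out["permutation_p"] = cf.permutation_p
        out.to_csv(outdir / "cell_fractions.tsv", sep="\t")
        state["fractions"] = cf.fractions
        return [outdir / "cell_fractions.tsv"], seed

    run_stage("deconvolve", stage_deconvolve)

    # --- consensus clustering --------------------------------------------
    def stage_cluster():
        seed = stage_seed(master_seed, "cluster")
        res = consensus_cluster(state["fractions"],
                                n_resamples=int(config.get("n_resamples", 250)),
                                seed=seed)
        if config.get("k_override"):
            res.chosen_k = int(config["k_override"])
        labels = res.final_labels
        labels.to_frame().to_csv(outdir / "tme_clusters.tsv", sep="\t")
        pd.DataFrame({"K": sorted(res.cdf_area),
                      "cdf_area": [res.cdf_area[k] for k in sorted(res.cdf_area)],
                      "delta": [res.delta_area[k] for k in sorted(res.cdf_area)]}
                     ).to_csv(outdir / "consensus_cdf.tsv", sep="\t", index=False)
        state["clusters"] = labels
        summary["chosen_K"] = res.chosen_k
        summary["cluster_sizes"] = labels.value_counts().to_dict()
        return [outdir / "tme_clusters.tsv", outdir / "consensus_cdf.tsv"], seed

    run_stage("cluster", stage_cluster)

    # --- survival of clusters + cell network ------------------------------
    def stage_survival():
        clin: ClinicalTable = state["clin"]
        t, e = clin.os_time, clin.os_event
        chi2, df, p = logrank_test(t, e, state["clusters"].loc[clin.sample_ids])
        summary["cluster_logrank_p"] = p
        net = cell_network(state["fractions"], clin)
        net.impact.to_csv(outdir / "cell_impact.tsv", sep="\t")
        net.edges.to_csv(outdir / "cell_edges.tsv", sep="\t", index=False)
        return [outdir / "cell_impact.tsv", outdir / "cell_edges.tsv"], None

    run_stage("survival", stage_survival)

    # --- differential expression -----------------------------------------
    def stage_dge():
        filtered = filter_low_expression(state["expr"])
        logcpm = voom_transform(filtered)
        state["logcpm"] = logcpm
        res = pairwise_contrasts(logcpm, state["clusters"])
        for (a, b), r in res.items():
            r.table.to_csv(outdir / f"dge_{a}_vs_{b}.tsv", sep="\t")
        common = deg_intersection(res, rule=config.get("common_rule", "two"))
        (outdir / "common_degs.txt").write_text("\n".join(common) + "\n")
        state["common_degs"] = common
        summary["deg_counts"] = {f"{a}v{b}": len(r.significant_genes)
                                 for (a, b), r in res.items()}
        summary["n_common_degs"] = len(common)
        return [outdir / "common_degs.txt"], None

    run_stage("dge", stage_dge)

    # --- TME score --------------------------------------------------------
    def stage_tmescore():
        seed = stage_seed(master_seed, "tmescore")
        logcpm: ExpressionMatrix = state["logcpm"]
        degs = state["common_degs"]
        if len(degs) < 10:
            raise ValueError(f"only {len(degs)} common DEGs; cannot build signature")
        imp = rf_reduce(logcpm.subset_genes(degs), state["clusters"],
                        n_trees=int(config.get("rf_trees", 500)), seed=seed)
        sig_genes = list(imp.index[imp["kept"]])
        (outdir / "signature_genes.txt").write_text("\n".join(sig_genes) + "\n")
        gene_res = cluster_signature_genes(
            logcpm, sig_genes, seed=stage_seed(master_seed, "geneclusters"),
            n_resamples=int(config.get("gene_resamples", 100)))
        clusters = score_gene_clusters(logcpm,
                                       gene_res.final_labels)
        clusters = assign_directions(clusters, state["clin"])
        score = compute_tme_score(clusters)
        res = dichotomize(score, state["clin"],
                          n_perm=int(config.get("maxstat_perms", 200)),
                          seed=stage_seed(master_seed, "maxstat"))
        out = pd.DataFrame({"tme_score": res.score, "tme_group": res.group})
        out.to_csv(outdir / "tme_score.tsv", sep="\t")
        clusters.scores.to_csv(outdir / "gene_cluster_scores.tsv", sep="\t")
        state["tme"] = res
        summary["tme_cutpoint"] = res.cutpoint
        summary["tme_group_sizes"] = res.group.value_counts().to_dict()
        summary["maxstat_p"] = res.permutation_p
        return [outdir / "tme_score.tsv", outdir / "signature_genes.txt",
                outdir / "gene_cluster_scores.tsv"], seed

    run_stage("tmescore", stage_tmescore)

    # --- score survival + ROC vs TMB -------------------------------------
    def stage_roc():
        clin = state["clin"]
        res = state["tme"]
        grp = res.group.loc[clin.sample_ids]
        chi2, df, p = logrank_test(clin.os_time, clin.os_event,
                                   (grp == "low").astype(int))
        fit = cox_fit(clin.os_time, clin.os_event,
                      pd.DataFrame({"low_group": (grp == "low").astype(float)}))
        summary["group_logrank_p"] = p
        summary["cox_hr_low_vs_high"] = float(fit.hr[0])
        tmb = compute_tmb(state["muts"]).reindex(clin.sample_ids).fillna(0)
        outcome = clin.table["response"].to_numpy(int) \
            if "response" in clin.table.columns else None
        outputs = []
        if outcome is not None:
            score = res.score.loc[clin.sample_ids].to_numpy()
            auc1 = roc_auc(score, outcome)
            auc2 = roc_auc(tmb["n_nonsilent"].to_numpy(), outcome)
            d, z, pp = delong_compare(score, tmb["n_nonsilent"].to_numpy(), outcome)
            summary["auc_tme_score"] = auc1
            summary["auc_tmb"] = auc2
            summary["delong_p"] = pp
        tmb.to_csv(outdir / "tmb.tsv", sep="\t")
        outputs.append(outdir / "tmb.tsv")
        return outputs, None

    run_stage("roc", stage_roc)

    # --- mutational signatures -------------------------------------------
    def stage_mutsig():
        seed = stage_seed(master_seed, "mutsig")
        cat = build_catalogue(state["muts"])
        cat.counts.to_csv(outdir / "catalogue96.tsv", sep="\t")
        decomp = extract_signatures(cat, n_restarts=int(config.get("nmf_restarts", 10)),
                                    seed=seed)
        decomp.W.to_csv(outdir / "signatures_W.tsv", sep="\t")
        decomp.H.to_csv(outdir / "exposures_H.tsv", sep="\t")
        matches = cosine_match(decomp.W, load_reference_signatures())
        matches.to_csv(outdir / "signature_matches.tsv", sep="\t")
        apo = apobec_enrichment(state["muts"])
        apo.to_csv(outdir / "apobec.tsv", sep="\t")
        summary["n_signatures"] = decomp.chosen_k
        summary["signature_matches"] = matches["best_match"].to_dict()
        summary["n_apobec_enriched"] = int((apo["apobec_class"] == "enriched").sum())
        if decomp.chosen_k >= 2:
            expo_clusters = cluster_exposures(decomp.H, seed=seed)
            expo_clusters.to_csv(outdir / "exposure_clusters.tsv", sep="\t")
        return [outdir / "catalogue96.tsv", outdir / "signatures_W.tsv",
                outdir / "exposures_H.tsv", outdir / "apobec.tsv"], seed

    run_stage("mutsig", stage_mutsig)

    # --- CNV --------------------------------------------------------------
    def stage_cnv():
        seed = stage_seed(master_seed, "cnv")
        arms = toy_genome()
        at = arm_level(state["segs"], arms)
        at.to_csv(outdir / "arm_level.tsv", sep="\t")
        bins = make_bins(arms)
        prof = gscore(state["segs"], bins,
                      n_perm=int(config.get("cnv_perms", 200)), seed=seed)
        prof.bins.to_csv(outdir / "gscore_bins.tsv", sep="\t", index=False)
        prof.peaks.to_csv(outdir / "cnv_peaks.tsv", sep="\t", index=False)
        summary["n_cnv_peaks"] = len(prof.peaks)
        return [outdir / "arm_level.tsv", outdir / "gscore_bins.tsv",
                outdir / "cnv_peaks.tsv"], seed

    run_stage("cnv", stage_cnv)

    manifest["summary"] = summary
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return manifest
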