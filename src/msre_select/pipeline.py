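"""End-to-end orchestration: simulate -> global stats -> DMRs -> targets ->
MSRE scan -> amplicon design -> annotation -> assay analysis -> panel model.

Every stage derives its random stream from the global seed plus a stage tag,
so inserting a stage never perturbs another stage's draws, and identical
configurations reproduce identical outputs (the manifest records SHA-256
hashes of every artifact).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate as ann
from . import assay as assay_mod
from . import design as design_mod
from . import dmr as dmr_mod
from . import io as io_mod
from . import model as model_mod
from . import msre as msre_mod
from . import simulate as sim
from . import targets as targets_mod

log = logging.getLogger("msre_select")

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "msre_run"
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    dmr: dmr_mod.DMRParams = field(default_factory=dmr_mod.DMRParams)
    selector: targets_mod.SelectorParams = field(default_factory=targets_mod.SelectorParams)
    design: design_mod.DesignConstraints = field(default_factory=design_mod.DesignConstraints)
    annotation: ann.AnnotationParams = field(default_factory=ann.AnnotationParams)
    model: model_mod.ModelSpec = field(default_factory=model_mod.ModelSpec)
    design_flank_nt: int = 150  # padding around targets when hunting primers

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = io_mod.load_config(path)
        kwargs = {}
        blocks = {
            "simulation": sim.SimulationConfig,
            "dmr": dmr_mod.DMRParams,
            "selector": targets_mod.SelectorParams,
            "design": design_mod.DesignConstraints,
            "annotation": ann.AnnotationParams,
            "model": model_mod.ModelSpec,
        }
        for key, val in raw.items():
            if key in blocks:
                kwargs[key] = blocks[key](**val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, writing artifacts and a manifest under
    ``config.outdir``; returns the summary dictionary."""
    cfg = config
    out = cfg.outdir
    os.makedirs(out, exist_ok=True)
    summary: dict = {"seed": cfg.seed}
    artifacts: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.time()

    def done(name):
        timings[name] = round(time.time() - timings[name], 3)

    # --- simulate genome -------------------------------------------------
    stage("simulate_genome")
    genome = sim.simulate_genome(cfg.simulation, seed=cfg.seed)
    io_mod.write_fasta(genome.sequence, f"{out}/genome.fa")
    io_mod.write_bed_intervals(genome.cpg_islands, f"{out}/cpg_islands.bed")
    io_mod.write_gene_models(genome.genes, f"{out}/genes.gff3")
    artifacts += [f"{out}/genome.fa", f"{out}/cpg_islands.bed", f"{out}/genes.gff3"]
    done("simulate_genome")

    # --- simulate methylomes ---------------------------------------------
    stage("simulate_methylomes")
    cohort, truth = sim.simulate_methylomes(genome, cfg.simulation, seed=cfg.seed)
    os.makedirs(f"{out}/coverage", exist_ok=True)
    for s in cohort.samples:
        io_mod.write_coverage(s, f"{out}/coverage/{s.sample_id}.cov")
        artifacts.append(f"{out}/coverage/{s.sample_id}.cov")
    sim.write_ground_truth(truth, regions_bed=f"{out}/planted_regions.bed")
    artifacts.append(f"{out}/planted_regions.bed")
    done("simulate_methylomes")

    # --- global methylation characteristics -------------------------------
    stage("global_stats")
    glob = pd.DataFrame(
        {
            "sample": [s.sample_id for s in cohort.samples],
            "group": [s.group for s in cohort.samples],
            "global_methylation": [dmr_mod.global_methylation(s) for s in cohort.samples],
        }
    ).set_index("sample")
    glob.to_csv(f"{out}/global_methylation.tsv", sep="\t")
    corr = dmr_mod.pairwise_correlation(cohort)
    corr.to_csv(f"{out}/pairwise_correlation.tsv", sep="\t")
    u_stat, p_global = dmr_mod.compare_group_methylation(cohort)
    normals = glob[glob["group"] == "normal"]["global_methylation"]
    cancers = glob[glob["group"] == "cancer"]["global_methylation"]
    norm_ids = [s.sample_id for s in cohort.normal]
    canc_ids = [s.sample_id for s in cohort.cancer]
    summary["global"] = {
        "mean_normal_pct": float(100 * normals.mean()),
        "mean_cancer_pct": float(100 * cancers.mean()),
        "group_test_U": u_stat,
        "group_test_p": p_global,
        "mean_pearson_r_normal": float(np.nanmean(corr.loc[norm_ids, norm_ids].to_numpy()[np.triu_indices(len(norm_ids), 1)])),
        "mean_pearson_r_cancer": float(np.nanmean(corr.loc[canc_ids, canc_ids].to_numpy()[np.triu_indices(len(canc_ids), 1)])),
    }
    artifacts += [f"{out}/global_methylation.tsv", f"{out}/pairwise_correlation.tsv"]
    done("global_stats")

    # --- DMR calling -------------------------------------------------------
    stage("call_dmrs")
    cm = dmr_mod.CohortMatrix(cohort)
    dmrs = dmr_mod.call_dmrs(cohort, cfg.dmr)
    io_mod.write_regions_bed(dmrs, f"{out}/dmrs.bed")
    hyper, hypo = targets_mod.split_by_direction(dmrs)
    summary["dmrs"] = {
        "n_total": len(dmrs),
        "n_hyper": len(hyper),
        "n_hypo": len(hypo),
        "hypo_fraction_pct": float(100 * len(hypo) / len(dmrs)) if dmrs else float("nan"),
        "mean_length_nt": float(np.mean([d.length for d in dmrs])) if dmrs else float("nan"),
        "mean_n_cpgs": float(np.mean([d.n_cpgs for d in dmrs])) if dmrs else float("nan"),
    }
    artifacts.append(f"{out}/dmrs.bed")
    done("call_dmrs")

    # --- target selection --------------------------------------------------
    stage("select_targets")
    targets = targets_mod.select_targets(hyper, cm, cfg.selector)
    io_mod.write_regions_bed(targets, f"{out}/targets.bed")
    artifacts.append(f"{out}/targets.bed")
    if targets:
        _, tstats = targets_mod.region_statistics(targets, cm)
        matrix = targets_mod.region_methylation_matrix(targets, cm)
        matrix.to_csv(f"{out}/target_methylation_matrix.tsv", sep="\t", index_label="region")
        artifacts.append(f"{out}/target_methylation_matrix.tsv")
        summary["targets"] = {
            "n_targets": len(targets),
            "mean_length_nt": tstats["mean_length_nt"],
            "mean_n_cpgs": tstats["mean_n_cpgs"],
            "mean_normal_pct": 100 * tstats["mean_normal"],
            "mean_cancer_pct": 100 * tstats["mean_cancer"],
        }
    else:
        summary["targets"] = {"n_targets": 0}
    done("select_targets")

    # --- MSRE site inventory ----------------------------------------------
    stage("msre_scan")
    inv_rows = []
    for t in targets:
        seq = genome.sequence[t.chrom][t.start : t.end]
        n_cpg, n_in_sites = msre_mod.count_cpgs_and_site_cpgs(seq)
        n_sites = len(msre_mod.scan_sites(seq))
        inv_rows.append(
            {
                "region": f"{t.chrom}:{t.start}-{t.end}",
                "n_cpgs": n_cpg,
                "n_msre_sites": n_sites,
                "n_cpgs_in_sites": n_in_sites,
            }
        )
    inventory = pd.DataFrame(inv_rows)
    inventory.to_csv(f"{out}/msre_inventory.tsv", sep="\t", index=False)
    artifacts.append(f"{out}/msre_inventory.tsv")
    if len(inventory) >= 3 and inventory["n_cpgs"].nunique() > 1:
        slope, intercept, r2 = msre_mod.sites_vs_cpgs_regression(
            inventory["n_cpgs"], inventory["n_msre_sites"]
        )
        summary["msre"] = {
            "mean_sites_per_target": float(inventory["n_msre_sites"].mean()),
            "mean_cpgs_per_target": float(inventory["n_cpgs"].mean()),
            "sites_vs_cpgs_slope": slope,
            "sites_vs_cpgs_r2": r2,
        }
    done("msre_scan")

    # --- amplicon design ----------------------------------------------------
    stage("design_amplicons")
    amplicons = []
    for t in targets:
        padded = dataclasses.replace(
            t,
            start=max(0, t.start - cfg.design_flank_nt),
            end=min(len(genome.sequence[t.chrom]), t.end + cfg.design_flank_nt),
        )
        amps, _ = design_mod.design_amplicons(padded, genome, constraints=cfg.design)
        if amps:
            amplicons.append(amps[0])  # one amplicon per target
    if amplicons:
        design_mod.export_panel(amplicons, f"{out}/panel.tsv", f"{out}/primers.fa")
        artifacts += [f"{out}/panel.tsv", f"{out}/primers.fa"]
    summary["design"] = {
        "n_targets_with_amplicon": len(amplicons),
        "mean_amplicon_len": float(np.mean([a.length for a in amplicons])) if amplicons else float("nan"),
    }
    done("design_amplicons")

    # --- annotation ---------------------------------------------------------
    stage("annotate")
    if targets:
        annots = ann.annotate_regions(targets, genome, cfg.annotation)
        asum = ann.summarize_annotations(annots)
        with open(f"{out}/annotation_summary.json", "w") as fh:
            json.dump(asum, fh, indent=2)
        artifacts.append(f"{out}/annotation_summary.json")
        summary["annotation"] = {
            "promoter_pct": 100 * asum["gene_part"]["promoter"],
            "island_pct": 100 * asum["cpg_context"]["island"],
            "tss_overlap_pct": 100 * asum["tss_overlap_fraction"],
            "mean_distance_to_tss": asum["mean_distance_to_tss"],
            "n_closest_genes": len(ann.closest_gene_list(annots)),
        }
    done("annotate")

    # --- assay simulation and analysis --------------------------------------
    stage("assay")
    table, assay_truth = sim.simulate_assay_counts(cfg.simulation, seed=cfg.seed)
    io_mod.write_count_table(table, f"{out}/assay_counts.tsv", f"{out}/assay_metadata.tsv")
    sim.write_ground_truth(assay_truth, amplicons_tsv=f"{out}/informative_amplicons.tsv")
    artifacts += [f"{out}/assay_counts.tsv", f"{out}/assay_metadata.tsv", f"{out}/informative_amplicons.tsv"]

    train_table, test_table = model_mod.train_test_split(table, seed=cfg.seed)
    filtered, removed = assay_mod.filter_low_count(train_table)
    norm_train, failed = assay_mod.normalize(filtered)
    qc = assay_mod.digestion_qc(norm_train)
    stats_table = assay_mod.amplicon_statistics(
        norm_train.drop(index=[filtered.control_norm, filtered.control_digest]), filtered
    )
    stats_table.to_csv(f"{out}/amplicon_stats.tsv", sep="\t")
    artifacts.append(f"{out}/amplicon_stats.tsv")
    significant = list(stats_table.index[stats_table["q"] < 0.05])
    if significant:
        assay_mod.export_heatmap_matrix(
            norm_train, filtered, significant, f"{out}/heatmap_matrix.tsv"
        )
        artifacts.append(f"{out}/heatmap_matrix.tsv")
    summary["assay"] = {
        "n_amplicons_tested": int(len(stats_table)),
        "n_removed_low_count": len(removed),
        "n_qc_failed_samples": len(failed) + int((~qc["pass"]).sum()),
        "n_over_2fold": int((stats_table["fold_change"] > 2).sum()),
        "n_over_10fold": int((stats_table["fold_change"] > 10).sum()),
        "n_significant_q05": len(significant),
    }
    done("assay")

    # --- panel model ---------------------------------------------------------
    stage("fit_panel")
    spec = dataclasses.replace(cfg.model, seed=cfg.seed)
    feature_rows = [a for a in norm_train.index if a not in (table.control_norm, table.control_digest)]
    panel = model_mod.fit_lasso_logistic(filtered, norm_train.loc[feature_rows], spec)
    test_filtered = dataclasses.replace(
        test_table, counts=test_table.counts.loc[filtered.counts.index]
    )
    norm_test, _ = assay_mod.normalize(test_filtered)
    test_auc, test_ci = model_mod.evaluate(panel, test_filtered, norm_test.loc[feature_rows])
    panel.to_json(f"{out}/panel_model.json")
    artifacts.append(f"{out}/panel_model.json")
    summary["model"] = {
        "n_markers": len(panel.support),
        "support": panel.support,
        "train_auc": panel.train_auc,
        "train_auc_ci": list(panel.train_auc_ci),
        "test_auc": test_auc,
        "test_auc_ci": list(test_ci),
    }
    done("fit_panel")

    manifest = {
        "seed": cfg.seed,
        "timings_s": timings,
        "artifacts": {os.path.relpath(a, out): _sha256(a) for a in sorted(artifacts)},
    }
    with open(f"{out}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(f"{out}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


_REPORT_SECTIONS = [
    ("global", "Global methylation"),
    ("dmrs", "Differentially methylated regions"),
    ("targets", "Target regions"),
    ("msre", "MSRE site inventory"),
    ("design", "Amplicon design"),
    ("annotation", "Genomic annotation"),
    ("assay", "Multiplex assay statistics"),
    ("model", "Panel classifier"),
]


def report(run_dir: str) -> str:
    """Render the run summary as a human-readable document; returns its path."""
    summary_path = os.path.join(run_dir, "summary.json")
    if not os.path.exists(summary_path):
        raise FileNotFoundError(f"incomplete run: missing {summary_path}")
    with open(summary_path) as fh:
        summary = json.load(fh)
    missing = [key for key, _ in _REPORT_SECTIONS if key not in summary]
    lines = [f"# MSRE-PCR pipeline report (seed {summary.get('seed')})", ""]
    if missing:
        lines.append(f"Missing stages: {', '.join(missing)}")
        lines.append("")
    for key, title in _REPORT_SECTIONS:
        if key not in summary:
            continue
        lines.append(f"## {title}")
        for k, v in summary[key].items():
            if isinstance(v, float):
                v = round(v, 4)
            lines.append(f"- {k}: {v}")
        lines.append("")
    path = os.path.join(run_dir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    return path
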