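"""End-to-end orchestration of the integrative analysis.

``run_full`` executes the stages in dependency order — simulate (or load
inputs), preprocess, differential expression, target support, network
induction, mixed circuits, pathway enrichment, survival screening — from a
single config with one global seed, writing every intermediate table under
the run directory plus a machine-readable ``report.json`` containing stage
parameters, input file hashes, the feature/relation/component/circuit count
funnel and, for simulated runs, recovery metrics against the planted truth.
Reports contain no timestamps: a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, preprocess, sam_de, target_support, networks, pathways, survival
from .synthetic_data import (
    CohortConfig,
    generate_cohort,
    generate_gene_sets,
    generate_survival,
    generate_target_predictions,
    generate_tf_layer,
)

log = logging.getLogger("mircircuitnet.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},
    "preprocess": {
        "min_detected": 20,
        "detection_floor": 1.0,
        "drop_fraction": 0.30,
        "signal_floor": 5.0,
        "fc_threshold": 1.0,
        "n_clusters": 3,
    },
    "diffexp": {
        "n_permutations": 200,
        "fdr_target": 0.01,
        "fc_threshold": 3.0,
        "background": 5.0,
        "design": "unpaired",
    },
    "support": {"q_max": 0.01, "direction": "negative", "method": "bh"},
    "network": {"top_gene_fraction": 0.75, "q_max": 0.05, "circuit_p_max": 0.05},
    "pathways": {"alpha": 0.05, "n_random_sets": 10, "set_size": 20},
    "survival": {"family_alpha": 0.05, "default_beta": 0.4},
}


def load_config(source) -> dict:
    """Merge a YAML/JSON file or dict over the pipeline defaults."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text()
        user = yaml.safe_load(text) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(config=None, outdir="run", seed: int | None = None) -> dict:
    """Run the whole analysis; returns the report dict (also written as JSON)."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg, "stages": {}, "funnel": {}, "recovery": {}}

    # ------------------------------------------------------------------ simulate
    log.info("stage simulate")
    sim_cfg = dict(cfg.get("simulate") or {})
    sim_cfg.setdefault("seed", cfg["seed"])
    cohort = CohortConfig(**sim_cfg)
    if cfg["survival"].get("default_beta") and not cohort.survival_betas:
        # plant the survival effect on the first T-vs-N DEM
        cohort.survival_betas = {"miR-001": float(cfg["survival"]["default_beta"])}
    mirna, genes, sheet, truth = generate_cohort(cohort)
    interactions, genes = generate_tf_layer(truth, cohort, mirna, genes)
    predictions = generate_target_predictions(truth, cohort)
    gene_sets = generate_gene_sets(
        truth, cohort,
        n_random_sets=cfg["pathways"]["n_random_sets"],
        set_size=cfg["pathways"]["set_size"],
    )
    screen_list = sorted(
        set(truth.dems["TvN"]["feature_id"][:20]) | set(truth.survival_betas)
    )[:26]
    surv_records = generate_survival(truth, cohort, screen_mirnas=screen_list)

    io_formats.write_expression_matrix(mirna, outdir / "mirna_matrix.tsv")
    io_formats.write_expression_matrix(genes, outdir / "gene_matrix.tsv")
    io_formats.write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    io_formats.write_target_predictions(predictions, outdir / "target_predictions.tsv")
    io_formats.write_interactions(interactions, outdir / "tf_interactions.tsv")
    io_formats.write_gene_sets(gene_sets, outdir / "gene_sets.gmt")
    io_formats.write_survival(surv_records, outdir / "survival.tsv")
    truth.repressions.to_csv(outdir / "truth_repressions.tsv", sep="\t", index=False)
    truth.circuits.to_csv(outdir / "truth_circuits.tsv", sep="\t", index=False)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    report["stages"]["simulate"] = {
        "n_mirnas": mirna.n_features, "n_genes": genes.n_features,
        "n_mirna_samples": mirna.n_samples, "n_gene_samples": genes.n_samples,
        "n_predictions": int(len(predictions)),
        "n_interactions": int(len(interactions)),
        "clip_events": truth.clip_events,
        "input_hashes": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*.tsv")) if p.name.startswith(("mirna", "gene", "sample"))
        },
    }

    # ---------------------------------------------------------------- preprocess
    log.info("stage preprocess")
    pp = cfg["preprocess"]
    mirna_detected = preprocess.filter_mirnas_by_detection(
        mirna, sheet, min_detected=pp["min_detected"], detection_floor=pp["detection_floor"]
    )
    mirna_expressed = preprocess.filter_by_mean_signal(mirna_detected, floor=pp["signal_floor"])
    genes_variable = preprocess.filter_genes_by_variability(genes, drop_fraction=pp["drop_fraction"])
    transitions = preprocess.transition_pattern_counts(
        mirna_expressed, sheet, fc_threshold=pp["fc_threshold"]
    )
    clustering = preprocess.cluster_samples(mirna_expressed, n_clusters=pp["n_clusters"])
    pairing = preprocess.patient_pairing_score(clustering, sheet)
    io_formats.write_expression_matrix(mirna_expressed, outdir / "mirna_filtered.tsv")
    io_formats.write_expression_matrix(genes_variable, outdir / "gene_filtered.tsv")
    transitions.counts.to_csv(outdir / "transition_counts.tsv", sep="\t")
    report["stages"]["preprocess"] = {
        "mirnas_after_detection": mirna_detected.n_features,
        "mirnas_after_signal_floor": mirna_expressed.n_features,
        "genes_after_variability": genes_variable.n_features,
        "transition_counts": transitions.counts.to_dict(),
        "patient_pairing_score": pairing,
    }

    # ------------------------------------------------------------------ diffexp
    log.info("stage diffexp")
    de = cfg["diffexp"]
    sam_cfg = sam_de.SamConfig(
        design=de["design"], n_permutations=de["n_permutations"],
        fdr_target=de["fdr_target"], seed=cfg["seed"],
    )
    sam_tn = sam_de.sam_fdr(mirna_expressed, sheet, "TvN", sam_cfg)
    sam_mt = sam_de.sam_fdr(mirna_expressed, sheet, "MvT", sam_cfg)
    dems_tn = sam_de.select_dems(sam_tn, fc_threshold=de["fc_threshold"],
                                 background=de["background"])
    dems_mt = sam_de.select_dems(sam_mt, fc_threshold=de["fc_threshold"],
                                 background=de["background"])
    sam_genes = sam_de.sam_fdr(genes_variable, sheet, "TvN", sam_cfg)
    degs_tn = sam_genes.table.loc[sam_genes.table["called"]].reset_index(drop=True)
    sam_tn.table.to_csv(outdir / "sam_mirna_TvN.tsv", sep="\t", index=False)
    sam_mt.table.to_csv(outdir / "sam_mirna_MvT.tsv", sep="\t", index=False)
    sam_tn.delta_table.to_csv(outdir / "sam_delta_TvN.tsv", sep="\t", index=False)
    dems_tn.to_csv(outdir / "dems_TvN.tsv", sep="\t", index=False)
    dems_mt.to_csv(outdir / "dems_MvT.tsv", sep="\t", index=False)
    degs_tn.to_csv(outdir / "degs_TvN.tsv", sep="\t", index=False)
    report["stages"]["diffexp"] = {
        "s0_TvN": sam_tn.s0, "delta_TvN": sam_tn.delta, "pi0_TvN": sam_tn.pi0,
        "n_called_TvN": int(sam_tn.table["called"].sum()),
        "n_called_MvT": int(sam_mt.table["called"].sum()),
        "n_dems_TvN": int(len(dems_tn)), "n_dems_MvT": int(len(dems_mt)),
        "n_degs_TvN": int(len(degs_tn)),
    }

    # ------------------------------------------------------------------ support
    log.info("stage support")
    sp = cfg["support"]
    relations, support_report = target_support.support_targets(
        mirna_expressed, genes, sheet, predictions,
        q_max=sp["q_max"], direction=sp["direction"], method=sp["method"],
    )
    summary = target_support.summarize_support(relations)
    relations.to_csv(outdir / "supported_relations.tsv", sep="\t", index=False)
    report["stages"]["support"] = {
        **support_report,
        "n_supported": summary.n_relations,
        "n_mirnas": summary.n_mirnas,
        "n_genes": summary.n_genes,
        "mean_targets_per_mirna": summary.mean_targets_per_mirna,
        "conserved_fraction": summary.conserved_fraction,
    }

    # ------------------------------------------------------------------ network
    log.info("stage network")
    dem_net = networks.induce_dem_network(relations, dems_tn, degs_tn)
    components = networks.connected_components(dem_net)
    io_formats.write_network(dem_net, outdir / "dem_network_edges.tsv",
                             outdir / "dem_network.graphml")
    pd.DataFrame(
        [{"component": i, "n_nodes": len(c)} for i, c in enumerate(components)]
    ).to_csv(outdir / "dem_network_components.tsv", sep="\t", index=False)
    by_dir = networks.split_by_dem_direction(dem_net)
    report["stages"]["network"] = {
        "n_nodes": dem_net.number_of_nodes(),
        "n_edges": dem_net.number_of_edges(),
        "n_components": len(components),
        "n_up_dem_nodes": by_dir["up"].number_of_nodes(),
        "n_down_dem_nodes": by_dir["down"].number_of_nodes(),
    }

    # ------------------------------------------------------------------ circuits
    log.info("stage circuits")
    nw = cfg["network"]
    mixed, mixed_report = networks.build_mixed_network(
        mirna_expressed, genes, sheet, relations, interactions,
        top_gene_fraction=nw["top_gene_fraction"], q_max=nw["q_max"],
    )
    circuits = networks.enumerate_circuits(mixed)
    significant = [c for c in circuits if c.combined_p <= nw["circuit_p_max"]]
    networks.circuits_to_frame(circuits).to_csv(outdir / "circuits.tsv", sep="\t", index=False)
    io_formats.write_network(mixed, outdir / "mixed_network_edges.tsv",
                             outdir / "mixed_network.graphml")
    report["stages"]["circuits"] = {
        **mixed_report,
        "n_mixed_nodes": mixed.number_of_nodes(),
        "n_mixed_edges": mixed.number_of_edges(),
        "n_circuits": len(circuits),
        "n_significant_circuits": len(significant),
    }

    # ------------------------------------------------------------------ pathways
    log.info("stage pathways")
    pw = cfg["pathways"]
    gene_stats = pathways.gene_level_statistics(genes, sheet, "TvN")
    results_a = pathways.enrich_pathways(relations, dems_tn, degs_tn, gene_sets,
                                         gene_stats, strategy="A", alpha=pw["alpha"])
    results_b = pathways.enrich_pathways(relations, dems_tn, degs_tn, gene_sets,
                                         gene_stats, strategy="B", alpha=pw["alpha"])
    frame = pd.concat(
        [pathways.results_to_frame(results_a), pathways.results_to_frame(results_b)],
        ignore_index=True,
    )
    frame.to_csv(outdir / "pathway_results.tsv", sep="\t", index=False)
    report["stages"]["pathways"] = {
        "n_sets": len(gene_sets),
        "n_tested_A": int(sum(r.testable for r in results_a)),
        "n_significant_A": int(sum(r.significant for r in results_a)),
        "n_tested_B": int(sum(r.testable for r in results_b)),
        "n_significant_B": int(sum(r.significant for r in results_b)),
    }

    # ------------------------------------------------------------------ survival
    log.info("stage survival")
    sv = cfg["survival"]
    fits = survival.screen_mirnas(surv_records, screen_list, family_alpha=sv["family_alpha"])
    fits.to_csv(outdir / "survival_fits.tsv", sep="\t", index=False)
    top = fits.iloc[0] if len(fits) else None
    report["stages"]["survival"] = {
        "n_screened": int(len(fits)),
        "per_test_alpha": survival.bonferroni_alpha(sv["family_alpha"], max(len(fits), 1)),
        "top_covariate": None if top is None else str(top["covariate_name"]),
        "top_hr": None if top is None else float(top["hr"]),
        "top_p_adjusted": None if top is None else float(top["p_adjusted"]),
    }

    # ------------------------------------------------------------------ funnel
    report["funnel"] = {
        "mirnas_profiled": mirna.n_features,
        "mirnas_selected": mirna_expressed.n_features,
        "genes_profiled": genes.n_features,
        "genes_selected": genes_variable.n_features,
        "predictions": int(len(predictions)),
        "supported_relations": summary.n_relations,
        "dems_TvN": int(len(dems_tn)),
        "network_components": len(components),
        "circuits": len(circuits),
        "significant_circuits": len(significant),
    }

    # ----------------------------------------------------------------- recovery
    report["recovery"] = _recovery_metrics(truth, dems_tn, relations, significant, fits)

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_safe))
    log.info("report written to %s", report_path)
    return report


def _recovery_metrics(truth, dems_tn, relations, significant_circuits, fits) -> dict:
    """Sensitivity / false-discovery metrics per stage against the planted truth."""
    out: dict = {}
    true_dems = set(truth.dems["TvN"]["feature_id"])
    called = set(dems_tn["feature_id"]) if len(dems_tn) else set()
    out["dem_sensitivity"] = (len(called & true_dems) / len(true_dems)) if true_dems else None
    out["dem_false_discoveries"] = int(len(called - true_dems))

    true_pairs = set(map(tuple, truth.repressions[["mirna_id", "gene_id"]].to_numpy()))
    found = (set(map(tuple, relations[["mirna_id", "gene_id"]].to_numpy()))
             if len(relations) else set())
    out["relation_sensitivity"] = (len(found & true_pairs) / len(true_pairs)) if true_pairs else None
    out["relation_fdr"] = (len(found - true_pairs) / len(found)) if found else 0.0

    true_circ = set(
        map(tuple, truth.circuits[["circuit_type", "tf_id", "mirna_id", "gene_id"]].to_numpy())
    )
    found_circ = {(c.circuit_type, c.tf, c.mirna, c.gene) for c in significant_circuits}
    out["circuit_sensitivity"] = (len(found_circ & true_circ) / len(true_circ)) if true_circ else None
    out["circuit_false_discoveries"] = int(len(found_circ - true_circ))

    planted_surv = set(truth.survival_betas)
    if planted_surv and len(fits):
        out["survival_top_hit_planted"] = bool(str(fits.iloc[0]["covariate_name"]) in planted_surv)
    else:
        out["survival_top_hit_planted"] = None
    return out


def _json_safe(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
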