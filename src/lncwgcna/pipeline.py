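"""End-to-end synthetic pipeline: simulate -> reannotate -> QC -> network ->
module/hub screening -> downstream statistics.

Every intermediate table is written to the output directory through the
package's own writers and read back through its readers, so a pipeline run
also exercises the interchange formats.  Because the inputs are synthetic,
the run ends with a truth-comparison report (module recovery ARI, hub
sensitivity/specificity, reannotation precision/recall).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .config import PipelineConfig
from .io import (
    read_attributes_tsv,
    read_expression_tsv,
    read_probe_tsv,
    read_stage_tsv,
    read_transcripts,
    write_expression_tsv,
    write_fasta,
    write_gmt,
    write_stage_tsv,
)
from .network import (
    adjacency,
    average_linkage,
    detect_modules,
    pick_power,
    power_scan,
    tom_similarity,
)
from .qc import quantile_normalize, sample_network_qc
from .reannotate import aggregate_to_lncrna, filter_mappings, index_transcripts, map_probes
from .simulate import (
    STAGE_ORDER,
    ProbeUniverseConfig,
    SimulationConfig,
    probe_level_expression,
    simulate_expression,
    simulate_probe_universe,
    simulate_survival,
)
from .stats import (
    GeneSetCollection,
    hypergeometric_enrichment,
    km_curve,
    logrank_test,
    median_split,
)
from .traits import (
    identify_hubs,
    module_eigengenes,
    module_significance,
    screening_stats,
    select_significant_module,
    stage_anova,
    trait_scores,
)

__all__ = ["run_full_pipeline"]

log = logging.getLogger("lncwgcna")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 fanned out from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_full_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    sim_config: SimulationConfig | None = None,
    survival_hazard_ratio: float = 2.0,
    survival_n_per_group: tuple[int, int] = (90, 90),
    survival_censor_rate: float = 0.3,
) -> dict:
    """Run the synthetic end-to-end analysis and write all artifacts.

    Returns a report dict (also written as JSON) with the chosen power,
    module summary, selected module, hub list, downstream statistics, and
    the comparison against the planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 5)
    log.info("pipeline start: seed=%d outdir=%s", config.seed, outdir)

    # --- simulate ---------------------------------------------------------
    sim_config = sim_config or SimulationConfig(seed=seeds[0])
    dataset, truth = simulate_expression(sim_config)
    universe_cfg = ProbeUniverseConfig(
        n_clean_lncrna=len(dataset.matrix.index),
        clean_gene_ids=tuple(dataset.matrix.index),
        probe_length=config.probe_length,
        seed=seeds[1],
    )
    universe, universe_truth = simulate_probe_universe(universe_cfg)
    probe_matrix = probe_level_expression(
        dataset, universe, universe_truth, seed=seeds[2]
    )
    write_expression_tsv(probe_matrix, outdir / "probe_expression.tsv")
    write_stage_tsv(dataset.stages, outdir / "stages.tsv")
    write_fasta(universe.transcripts, outdir / "transcripts.fasta")
    universe.attributes.to_csv(outdir / "transcript_attributes.tsv", sep="\t", index=False)
    universe.probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    log.info(
        "simulated %d genes x %d samples; %d probes, %d transcripts",
        *dataset.matrix.shape, len(universe.probes), len(universe.transcripts),
    )

    # --- reannotate (from the files, exercising the readers) --------------
    probe_matrix = read_expression_tsv(outdir / "probe_expression.tsv")
    stages = read_stage_tsv(outdir / "stages.tsv")
    attrs = read_attributes_tsv(outdir / "transcript_attributes.tsv")
    records = read_transcripts(outdir / "transcripts.fasta", attrs)
    probes = read_probe_tsv(outdir / "probes.tsv")

    if config.quantile_normalize:
        probe_matrix = quantile_normalize(probe_matrix)
    index = index_transcripts(records, config.probe_length)
    mappings = map_probes(probes, index)
    annotation = filter_mappings(mappings, attrs, min_probes=config.min_probes)
    annotation.to_csv(outdir / "lncrna_annotation.tsv", sep="\t", index=False)
    matrix = aggregate_to_lncrna(probe_matrix, annotation)
    write_expression_tsv(matrix, outdir / "lncrna_expression.tsv")
    log.info("reannotation retained %d lncRNA genes", len(matrix))

    # --- sample QC --------------------------------------------------------
    qc_report = sample_network_qc(matrix, zk_cut=config.zk_cut, zc_cut=config.zc_cut)
    qc_report.to_csv(outdir / "sample_qc.tsv", sep="\t")
    keep = qc_report.index[~qc_report["outlier"]]
    if len(keep) < matrix.shape[1]:
        log.warning("dropping %d outlier sample(s)", matrix.shape[1] - len(keep))
    matrix = matrix[keep]
    stages = stages.loc[keep]

    # --- network ----------------------------------------------------------
    scan = power_scan(matrix, powers=config.power_grid)
    scan.to_csv(outdir / "power_scan.tsv", sep="\t", index=False)
    power = config.power or pick_power(scan, r2_threshold=config.r2_threshold)
    log.info("using soft-threshold power %d", power)
    adj = adjacency(matrix, power)
    tom = tom_similarity(adj)
    tree = average_linkage(1.0 - tom)
    assignment = detect_modules(
        tree, matrix.index,
        min_module_size=config.min_module_size,
        cut_quantile=config.cut_quantile,
    )
    assignment.to_frame().to_csv(outdir / "modules.tsv", sep="\t")
    log.info("detected %d modules; sizes %s", assignment.n_modules,
             assignment.module_sizes.to_dict())

    # --- module-trait and hub screening -----------------------------------
    trait = trait_scores(stages, STAGE_ORDER)
    eigengenes, varexp = module_eigengenes(matrix, assignment)
    mt_stats = module_significance(matrix, trait, assignment, eigengenes)
    mt_stats.to_csv(outdir / "module_trait.tsv", sep="\t")
    selected = select_significant_module(mt_stats)
    stats = screening_stats(matrix, trait, assignment, eigengenes, config.mix_weight)
    stats.to_csv(outdir / "screening_stats.tsv", sep="\t")
    hubs = identify_hubs(stats, selected, threshold=config.hub_threshold)
    hubs.to_csv(outdir / "hubs.tsv", sep="\t")
    anova = stage_anova(matrix, stages)
    anova.to_csv(outdir / "stage_anova.tsv", sep="\t")
    log.info("selected module %d (size %d); %d hub gene(s)",
             selected, int(mt_stats.loc[selected, "size"]), len(hubs))

    # --- downstream: enrichment of the selected module ---------------------
    collection = _truth_gene_sets(truth, seeds[3])
    write_gmt(collection, outdir / "gene_sets.gmt")
    query = list(assignment.genes_in(selected))
    enrichment = hypergeometric_enrichment(
        query, list(matrix.index), collection, fdr_cutoff=config.fdr_cutoff
    )
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # --- downstream: survival ----------------------------------------------
    survival = simulate_survival(
        survival_n_per_group, survival_hazard_ratio,
        censor_rate=survival_censor_rate, seed=seeds[4],
    )
    survival.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    curves = km_curve(survival["time"], survival["event"], survival["group"])
    curves.to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    lr = logrank_test(survival["time"], survival["event"], survival["group"])

    # --- truth comparison ---------------------------------------------------
    comparison = _truth_comparison(truth, universe_truth, annotation, assignment,
                                   selected, hubs)
    report = {
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": _versions(),
        "n_probes": int(len(probes)),
        "n_lncrna": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "qc_outliers": qc_report.index[qc_report["outlier"]].tolist(),
        "power": int(power),
        "scale_free_r2": float(scan.set_index("power").loc[power, "r2"]),
        "n_modules": assignment.n_modules,
        "module_sizes": {int(k): int(v) for k, v in assignment.module_sizes.items()},
        "selected_module": int(selected),
        "selected_module_ms": float(mt_stats.loc[selected, "MS"]),
        "selected_module_me_trait_r": float(mt_stats.loc[selected, "me_trait_r"]),
        "selected_module_me_trait_p": float(mt_stats.loc[selected, "me_trait_p"]),
        "hubs": hubs.index.tolist(),
        "n_significant_sets": int(enrichment["significant"].sum()),
        "logrank_statistic": lr.statistic,
        "logrank_p": lr.p,
        "truth_comparison": comparison,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("pipeline done: ARI=%.3f hub_sensitivity=%.2f",
             comparison["module_ari"], comparison["hub_sensitivity"])
    return report


def _truth_gene_sets(truth, seed: int, n_random: int = 10) -> GeneSetCollection:
    """Gene sets for the synthetic enrichment step.

    One set per planted module (these should enrich when the matching module
    is selected) plus random decoy sets drawn from the whole gene pool.
    """
    rng = np.random.default_rng(seed)
    genes = truth.module_labels.index.to_numpy()
    sets, categories = {}, {}
    for m in sorted(set(truth.module_labels) - {0}):
        members = truth.module_labels.index[truth.module_labels == m]
        sets[f"planted_module_{m}"] = frozenset(members)
        categories[f"planted_module_{m}"] = "biological process"
    for i in range(n_random):
        size = int(rng.integers(20, 60))
        sets[f"random_set_{i + 1}"] = frozenset(
            rng.choice(genes, size=size, replace=False)
        )
        categories[f"random_set_{i + 1}"] = "pathway" if i % 2 else "disease"
    return GeneSetCollection(sets=sets, categories=categories)


def _truth_comparison(truth, universe_truth, annotation, assignment,
                      selected: int, hubs: pd.DataFrame) -> dict:
    # reannotation: retained genes vs planted clean lncRNA genes
    retained = set(annotation["gene_id"])
    clean = set(universe_truth.clean_lncrna_genes)
    precision = len(retained & clean) / len(retained) if retained else float("nan")
    recall = len(retained & clean) / len(clean) if clean else float("nan")

    # module recovery over planted (non-background) genes
    planted = truth.module_labels[truth.module_labels != 0]
    common = planted.index.intersection(assignment.labels.index)
    ari = float(
        adjusted_rand_score(planted.loc[common], assignment.labels.loc[common])
    )

    # does the selected module carry the strongest planted trait effect?
    target = max(truth.factor_trait_cor, key=lambda m: abs(truth.factor_trait_cor[m]))
    target_genes = truth.module_labels.index[truth.module_labels == target]
    target_genes = target_genes.intersection(assignment.labels.index)
    detected_for_target = (
        int(assignment.labels.loc[target_genes].mode().iloc[0])
        if len(target_genes)
        else -1
    )

    hub_set = set(hubs.index)
    planted_hubs = set(truth.hub_genes)
    non_hubs = set(assignment.labels.index) - planted_hubs
    sens = (
        len(hub_set & planted_hubs) / len(planted_hubs) if planted_hubs else float("nan")
    )
    spec = 1.0 - len(hub_set - planted_hubs) / len(non_hubs)
    return {
        "reannotation_precision": precision,
        "reannotation_recall": recall,
        "module_ari": ari,
        "selected_module_matches_planted": bool(selected == detected_for_target),
        "hub_sensitivity": sens,
        "hub_specificity": spec,
    }


def _versions() -> dict:
    import pandas
    import scipy

    return {
        "lncwgcna": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
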