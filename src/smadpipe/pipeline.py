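"""End-to-end orchestration of the analysis on the bundled synthetic study.

``run_all`` simulates the pattern-design study from the configured seed and
drives every stage — peak calling in both conditions, TSS annotation and
four-way pattern classification, differential-expression integration,
hub-TF network inference with permutation edges, and the clustering-based
survival signature — writing stage outputs and a machine-readable JSON
report. All randomness derives from the single config seed via stage-name
hashing, so the report is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as pio
from .annotation import (
    annotation_summary,
    assign_to_genes,
    classify_patterns,
    pattern_summary,
    tss_distance_histogram,
)
from .config import PipelineConfig
from .expression import differential_expression, integrate, strict_variant
from .network import annotate_edge_pvalues, build_network, find_hub_tfs
from .peaks import bin_reads, call_loci, estimate_fdr
from .study import cohort_spec, expression_genome, pattern_design
from .survival import random_signature_control, signature_scan
from .synthetic import (
    condition_peaks,
    generate_cohort,
    generate_expression,
    generate_locus_sequences,
    generate_pwm_library,
    generate_reads,
)

log = logging.getLogger("smadpipe")

FDR_LEVELS = [0.990, 0.993, 0.996, 0.999]


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {k: v for k, v in vars(config).items() if k != "outdir"}
    }

    design = pattern_design()
    genome = design.genome

    # --- stage 1: reads and peak calling, both conditions -----------------
    stage = "peaks"
    log.info("stage=%s seed=%d", stage, config.stage_seed(stage))
    loci = {}
    tracks = {}
    input_reads = generate_reads(
        genome, [], design.background_density,
        seed=config.stage_seed("input"), sample="input",
    )
    input_track = bin_reads(input_reads, config.bin_width)
    for condition in ("stimulated", "unstimulated"):
        reads = generate_reads(
            genome,
            condition_peaks(design.peaks, condition),
            design.background_density,
            seed=config.stage_seed(f"reads:{condition}"),
            sample=condition,
        )
        track = bin_reads(reads, config.bin_width)
        tracks[condition] = track
        loci[condition] = call_loci(
            track, input_track, config.acceptance_level, config.min_gap,
            condition=condition,
        )
        pio.write_loci_bed(loci[condition], outdir / f"loci_{condition}.bed")
        fdr = estimate_fdr(
            track, input_track, genome.chrom_sizes, FDR_LEVELS,
            seed=config.stage_seed(f"fdr:{condition}"),
            min_gap=config.min_gap,
        )
        fdr.to_csv(outdir / f"fdr_{condition}.tsv", sep="\t", index=False)
        report[f"n_loci_{condition}"] = len(loci[condition])
        report[f"fdr_at_level_{condition}"] = float(
            fdr.loc[fdr.level == config.acceptance_level, "fdr"].iloc[0]
        )

    # --- stage 2: annotation and pattern classification -------------------
    genes = list(genome.genes)
    assignments = {
        c: assign_to_genes(loci[c], genes, config.gene_window,
                           config.promoter_window)
        for c in loci
    }
    for c, asn in assignments.items():
        report[f"annotation_{c}"] = annotation_summary(asn)
        tss_distance_histogram(asn).to_csv(
            outdir / f"tss_hist_{c}.tsv", sep="\t", index=False
        )
    calls = classify_patterns(
        assignments["stimulated"], assignments["unstimulated"],
        config.shift_threshold,
    )
    for c in ("stimulated", "unstimulated"):
        summary = pattern_summary(calls, c)
        summary.to_csv(outdir / f"patterns_{c}.tsv", sep="\t", index=False)
        report[f"patterns_{c}"] = {
            str(row["category"]): {"count": int(row["count"]),
                                   "percent": float(row["percent"])}
            for _, row in summary.iterrows()
        }
    truth_recovery = _pattern_recovery(calls, design.truth_category)
    report["pattern_recovery"] = truth_recovery

    # --- stage 3: expression and integration ------------------------------
    expr = generate_expression(
        expression_genome(design), design.de_effects,
        noise_sd=0.3, n_replicates=3,
        seed=config.stage_seed("expression"),
    )
    labels = ["unstimulated"] * 3 + ["stimulated"] * 3
    de = differential_expression(expr, labels, config.fc_threshold,
                                 config.p_threshold)
    de.to_csv(outdir / "differential_expression.tsv", sep="\t")
    target_genes = {
        a.gene_id for a in assignments["stimulated"] if a.gene_id is not None
    }
    partition = integrate(de, target_genes)
    strict = strict_variant(de, target_genes, config.p_threshold_strict,
                            config.fc_threshold)
    report["integration"] = partition.summary()
    report["integration_strict"] = strict.summary()
    planted_de = set(design.de_effects)
    called_de = set(de.index[de["de"]])
    report["de_recovery"] = {
        "planted": len(planted_de),
        "recovered": len(planted_de & called_de),
        "recall": round(len(planted_de & called_de) / len(planted_de), 4),
    }

    # --- stage 4: network inference ---------------------------------------
    pwms = generate_pwm_library(10, length=8,
                                seed=config.stage_seed("pwm_library"))
    planted_pwm = pwms[0]
    de_and_locus = sorted(partition.de_and_locus)
    gene_loci_map = _loci_by_gene(assignments["stimulated"], de_and_locus)
    flat_loci = [l for gl in gene_loci_map.values() for l in gl]
    target_seqs = generate_locus_sequences(
        flat_loci, planted_pwm, planted_fraction=0.8,
        seed=config.stage_seed("target_seqs"),
    )
    background_seqs = generate_locus_sequences(
        flat_loci, planted_pwm, planted_fraction=0.0,
        seed=config.stage_seed("background_seqs"),
    )
    hub_table = find_hub_tfs(target_seqs, background_seqs, pwms,
                             config.score_fraction, config.hub_alpha)
    hub_table.to_csv(outdir / "hub_tfs.tsv", sep="\t", index=False)
    hubs = [p for p in pwms
            if p.motif_id in set(hub_table.loc[hub_table.hub, "motif_id"])]
    seq_ids = list(target_seqs)
    gene_seqs: dict[str, list[str]] = {}
    i = 0
    for gene, gl in gene_loci_map.items():
        gene_seqs[gene] = [target_seqs[seq_ids[i + j]] for j in range(len(gl))]
        i += len(gl)
    net = build_network(hubs, gene_seqs, de, config.score_fraction)
    net = annotate_edge_pvalues(
        net, gene_seqs, {p.motif_id: p for p in pwms},
        n_permutations=config.n_permutations,
        seed=config.stage_seed("permutation"),
        score_fraction=config.score_fraction,
    )
    pio.write_sif(net, outdir / "network.sif", outdir / "network_edges.tsv")
    edge_ps = [net.edges[e]["perm_p"] for e in net.edges]
    report["network"] = {
        "n_hubs": int(hub_table.hub.sum()),
        "planted_hub_rank": int(
            hub_table.loc[hub_table.motif_id == planted_pwm.motif_id, "rank"].iloc[0]
        ),
        "n_edges": net.number_of_edges(),
        "median_edge_perm_p": float(np.median(edge_ps)) if edge_ps else None,
    }

    # --- stage 5: survival signature --------------------------------------
    cohort = generate_cohort(cohort_spec(seed=config.stage_seed("cohort")))
    pio.write_matrix_tsv(cohort.matrix, outdir / "cohort_matrix.tsv")
    pio.write_survival_tsv(cohort.time, cohort.event, outdir / "cohort_survival.tsv")
    scan = signature_scan(cohort, k_gene=config.k_gene,
                          k_patient=config.k_patient)
    scan.per_group.to_csv(outdir / "signature_scan.tsv", sep="\t", index=False)
    selected = scan.selected_group
    best_p = float(scan.per_group["p"].min())
    planted = set(cohort.truth["prognostic_genes"])
    selected_genes = set(scan.selected_genes)
    jaccard = (
        len(planted & selected_genes) / len(planted | selected_genes)
        if planted | selected_genes else 0.0
    )
    pool = cohort.matrix.shape[0] - len(selected_genes)
    control_size = min(len(selected_genes) or 12, pool)
    _, _, control_p = random_signature_control(
        cohort, control_size, selected_genes,
        seed=config.stage_seed("control"), k_patient=config.k_patient,
    )
    report["survival"] = {
        "selected_gene_group": selected,
        "n_signature_genes": len(selected_genes),
        "best_pair_logrank_p": best_p,
        "planted_overlap_jaccard": round(jaccard, 4),
        "random_control_p": control_p,
        "note": scan.note,
    }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    log.info("wrote %s", report_path)
    return report


def _pattern_recovery(calls, truth_category: dict[str, str]) -> dict:
    """Fraction of planted genes whose called category matches the truth."""
    called: dict[str, str] = {}
    for c in calls:
        # a gene with several calls keeps its paired category if any
        if c.gene_id not in called or c.category in ("Basal", "Shift"):
            called[c.gene_id] = c.category
    planted = {g: c for g, c in truth_category.items() if c != "None"}
    hits = sum(1 for g, cat in planted.items() if called.get(g) == cat)
    return {
        "planted_genes": len(planted),
        "correct_category": hits,
        "accuracy": round(hits / len(planted), 4),
    }


def _loci_by_gene(assignments, genes: list[str]) -> dict[str, list]:
    out: dict[str, list] = {g: [] for g in genes}
    for a in assignments:
        if a.gene_id in out:
            out[a.gene_id].append(a.locus)
    return {g: v for g, v in out.items() if v}
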