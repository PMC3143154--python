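"""Hub-TF discovery and the permutation-tested regulatory network.

Builds locus sequences for the DE-and-locus genes (planted motif fraction
0.8 versus a length-matched random background), screens the PWM library by
Fisher exact enrichment with BH correction, wires hub->gene edges by
rescanning, and attaches dinucleotide-shuffle permutation p-values.
Outputs (SIF + edge attributes + hub table) land in results/05_network/.
"""

from pathlib import Path

from smadpipe import io as pio
from smadpipe.annotation import assign_to_genes
from smadpipe.config import PipelineConfig
from smadpipe.expression import differential_expression
from smadpipe.network import annotate_edge_pvalues, build_network, find_hub_tfs
from smadpipe.study import pattern_design
from smadpipe.synthetic import generate_locus_sequences

OUT = Path("results/05_network")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    design = pattern_design()

    pwms = pio.read_jaspar("results/01_inputs/pwms.jaspar")
    planted = pwms[0]
    de_and_locus = [
        line.strip() for line in
        Path("results/04_expression/de_and_locus_genes.txt").read_text().splitlines()
        if line.strip()
    ]
    loci = pio.read_loci_bed("results/02_peaks/loci_stimulated.bed",
                             condition="stimulated")
    assignments = assign_to_genes(loci, list(design.genome.genes),
                                  cfg.gene_window, cfg.promoter_window)
    gene_loci = {g: [] for g in de_and_locus}
    for a in assignments:
        if a.gene_id in gene_loci:
            gene_loci[a.gene_id].append(a.locus)
    gene_loci = {g: v for g, v in gene_loci.items() if v}
    flat = [l for v in gene_loci.values() for l in v]

    target_seqs = generate_locus_sequences(
        flat, planted, planted_fraction=0.8,
        seed=cfg.stage_seed("target_seqs"))
    background_seqs = generate_locus_sequences(
        flat, planted, planted_fraction=0.0,
        seed=cfg.stage_seed("background_seqs"))
    pio.write_fasta(target_seqs, OUT / "target_loci.fa")
    pio.write_fasta(background_seqs, OUT / "background_loci.fa")

    table = find_hub_tfs(target_seqs, background_seqs, pwms,
                         cfg.score_fraction, cfg.hub_alpha)
    table.to_csv(OUT / "hub_tfs.tsv", sep="\t", index=False)
    hubs = [p for p in pwms
            if p.motif_id in set(table.loc[table.hub, "motif_id"])]
    print(f"{len(hubs)} hub TFs of {len(pwms)} PWMs; planted motif "
          f"{planted.motif_id} ranked "
          f"{int(table.loc[table.motif_id == planted.motif_id, 'rank'].iloc[0])}")

    matrix = pio.read_matrix_tsv("results/01_inputs/expression.tsv")
    de = differential_expression(matrix,
                                 ["unstimulated"] * 3 + ["stimulated"] * 3)
    seq_ids = list(target_seqs)
    gene_seqs, i = {}, 0
    for g, v in gene_loci.items():
        gene_seqs[g] = [target_seqs[seq_ids[i + j]] for j in range(len(v))]
        i += len(v)
    net = build_network(hubs, gene_seqs, de, cfg.score_fraction)
    net = annotate_edge_pvalues(net, gene_seqs,
                                {p.motif_id: p for p in pwms},
                                n_permutations=cfg.n_permutations,
                                seed=cfg.stage_seed("permutation"),
                                score_fraction=cfg.score_fraction)
    pio.write_sif(net, OUT / "network.sif", OUT / "network_edges.tsv")
    sig = sum(1 for e in net.edges if net.edges[e]["perm_p"] < 0.05)
    print(f"network: {net.number_of_edges()} edges over "
          f"{len(gene_seqs)} genes; {sig} edges with permutation p < 0.05")


if __name__ == "__main__":
    main()
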