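"""File formats: BED6, TSV tables, FASTA, JASPAR PWMs, SIF networks."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel
from .network import PWM
from .peaks import BindingLocus, MappedReadSet

__all__ = [
    "write_reads_bed", "read_reads_bed",
    "write_loci_bed", "read_loci_bed",
    "write_genes_tsv", "read_genes_tsv",
    "write_fasta", "read_fasta",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_survival_tsv", "read_survival_tsv",
    "read_jaspar", "write_jaspar",
    "write_sif", "read_sif",
]


def write_reads_bed(reads: MappedReadSet, path) -> None:
    """Reads as BED6 (name = sample, score = 0)."""
    rows = []
    for chrom in reads.positions:
        pos = reads.positions[chrom]
        strand = reads.strands[chrom]
        for p, s in zip(pos, strand):
            rows.append((chrom, int(p), int(p) + reads.read_length, reads.sample, 0, s))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path, chrom_sizes: dict[str, int], sample: str = "",
                   read_length: int = 36) -> MappedReadSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    positions = {}
    strands = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        order = np.argsort(grp["start"].to_numpy())
        positions[str(chrom)] = grp["start"].to_numpy()[order]
        strands[str(chrom)] = grp["strand"].to_numpy().astype("<U1")[order]
    if not sample and len(df):
        sample = str(df["name"].iloc[0])
    return MappedReadSet(sample=sample, chrom_sizes=chrom_sizes,
                         positions=positions, strands=strands,
                         read_length=read_length)


def write_loci_bed(loci: list[BindingLocus], path) -> None:
    """Loci as BED6 plus summit and score columns (0-based half-open)."""
    rows = [
        (l.chrom, l.start, l.end, f"locus_{i+1}", 0, "+", l.summit, l.score)
        for i, l in enumerate(loci)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_loci_bed(path, level: float = 0.996, condition: str = "") -> list[BindingLocus]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "bedscore",
                            "strand", "summit", "score"])
    return [
        BindingLocus(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                     summit=int(r.summit), score=float(r.score),
                     level=level, condition=condition)
        for r in df.itertuples()
    ]


def write_genes_tsv(genes, path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tes) for g in genes],
        columns=["gene_id", "chrom", "strand", "tss", "tes"],
    ).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss), int(r.tes))
        for r in df.itertuples()
    ]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_survival_tsv(time: pd.Series, event: pd.Series, path) -> None:
    pd.DataFrame(
        {"patient_id": time.index, "time_months": time.to_numpy(),
         "event": event.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_survival_tsv(path) -> tuple[pd.Series, pd.Series]:
    df = pd.read_csv(path, sep="\t").set_index("patient_id")
    return df["time_months"], df["event"].astype(int)


def read_jaspar(path, pseudocount: float = 0.01) -> list[PWM]:
    """JASPAR-style text (>id, then A/C/G/T count rows) to PWM objects."""
    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
        out.append(PWM(m.matrix_id or m.name, counts, pseudocount=pseudocount))
    return out


def write_jaspar(pwms: list[PWM], path, scale: float = 100.0) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v * scale:.0f}" for v in p.probs[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


def write_sif(net: nx.DiGraph, sif_path, attr_path=None) -> None:
    """Edge list as SIF ('TF regulates gene') plus attribute TSV."""
    with open(sif_path, "w") as fh:
        for tf, gene in sorted(net.edges):
            fh.write(f"{tf}\tregulates\t{gene}\n")
    if attr_path is not None:
        rows = []
        for tf, gene in sorted(net.edges):
            data = net.edges[tf, gene]
            rows.append(
                (tf, gene, net.nodes[gene].get("direction", ""),
                 data.get("hits", ""), data.get("perm_p", ""))
            )
        pd.DataFrame(
            rows, columns=["tf", "gene", "direction", "hits", "perm_p"]
        ).to_csv(attr_path, sep="\t", index=False)


def read_sif(path) -> nx.DiGraph:
    net = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 3:
                src, _, dst = parts
                net.add_edge(src, dst)
    return net
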