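"""The bundled synthetic study: fixed conditions with planted ground truth.

Two ChIP designs are defined here. The *recovery* design measures the peak
caller's operating characteristics: a 2 × 6 Mb genome at 0.01 reads/bp
background (λ = 3 reads per 300 nt bin) with 140 planted single-bin peaks
at 15× enrichment, summits on bin centers. At the 0.996 level the caller
admits ≈ 0.4% of nonzero bins (≈ 152), so with 140 planted bins the false
calls are capped near 12 — recall 1 and true FDR ≤ ~0.08 by construction
(see docs/methods.md).

The *pattern* design drives the full pipeline: a 2 × 3 Mb genome with 80
genes, planted Basal / Shift / Stimulated-only / Unstimulated-only peak
structure (18 genes each), a 400-gene expression universe with planted DE
genes inside and outside the bound set, motif-planted locus sequences, and
a 60-patient cohort with a 12-gene prognostic group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import GeneModel
from .synthetic import (
    PlantedCohortSpec,
    PlantedPeakSpec,
    SyntheticGenome,
)

BIN = 300

__all__ = [
    "recovery_design",
    "pattern_design",
    "cohort_spec",
    "PatternDesign",
]


def _bin_center(pos: int) -> int:
    """Snap a position to the nearest 300 nt bin center."""
    return int(round((pos - BIN // 2) / BIN)) * BIN + BIN // 2


def recovery_design() -> tuple[SyntheticGenome, list[PlantedPeakSpec], float]:
    """Peak-recovery study: genome, planted peaks, background density."""
    genome = SyntheticGenome(chrom_sizes={"chr1": 6_000_000, "chr2": 6_000_000})
    peaks = []
    for chrom in ("chr1", "chr2"):
        for i in range(70):
            center = _bin_center(150_000 + i * 80_000)
            peaks.append(
                PlantedPeakSpec(chrom, center, enrichment=15.0, width=BIN,
                                condition="stimulated")
            )
    return genome, peaks, 0.01


@dataclass(frozen=True)
class PatternDesign:
    genome: SyntheticGenome
    peaks: list[PlantedPeakSpec]
    background_density: float
    truth_category: dict[str, str]  # gene id -> planted pattern category
    de_effects: dict[str, float]  # planted DE gene -> signed log2 effect
    expression_gene_ids: list[str]
    bound_de_genes: list[str]  # planted DE genes that also carry a stim peak


def pattern_design() -> PatternDesign:
    """Full-pipeline study with planted four-category binding structure."""
    chrom_sizes = {"chr1": 3_000_000, "chr2": 3_000_000}
    genes = []
    for ci, chrom in enumerate(("chr1", "chr2")):
        for i in range(40):
            gi = ci * 40 + i
            tss = 100_000 + i * 70_000
            strand = "+" if gi % 2 == 0 else "-"
            tes = tss + 20_000 if strand == "+" else tss - 20_000
            # keep - strand TES in bounds
            if strand == "-":
                tss, tes = tss + 20_000, tss
            genes.append(GeneModel(f"G{gi+1:03d}", chrom, strand, tss, tes))
    genome = SyntheticGenome(chrom_sizes=chrom_sizes, genes=tuple(genes))

    rng = np.random.default_rng(20110722)  # fixed layout, not a tunable
    categories = (
        ["Basal"] * 18 + ["Shift"] * 18 + ["StimulatedOnly"] * 18
        + ["UnstimulatedOnly"] * 18 + ["None"] * 8
    )
    order = rng.permutation(len(genes))
    truth: dict[str, str] = {}
    peaks: list[PlantedPeakSpec] = []
    for cat, idx in zip(categories, order):
        g = genes[idx]
        truth[g.gene_id] = cat
        if cat == "None":
            continue
        offset = int(rng.integers(-25_000, 25_000))
        center = _bin_center(g.tss + offset)
        if cat == "Basal":
            peaks.append(PlantedPeakSpec(g.chrom, center, 15.0, BIN, "both",
                                         pairing_offset=BIN, gene_id=g.gene_id))
        elif cat == "Shift":
            peaks.append(PlantedPeakSpec(g.chrom, center, 15.0, BIN, "both",
                                         pairing_offset=8 * BIN, gene_id=g.gene_id))
        elif cat == "StimulatedOnly":
            peaks.append(PlantedPeakSpec(g.chrom, center, 15.0, BIN,
                                         "stimulated", gene_id=g.gene_id))
        else:
            peaks.append(PlantedPeakSpec(g.chrom, center, 15.0, BIN,
                                         "unstimulated", gene_id=g.gene_id))

    # expression universe: the 80 genomic genes plus 320 array-only genes
    extra = [
        GeneModel(f"G{i+1:03d}", "chrE", "+", 10_000 + (i - 80) * 60_000,
                  10_000 + (i - 80) * 60_000 + 20_000)
        for i in range(80, 400)
    ]
    expression_gene_ids = [g.gene_id for g in genes] + [g.gene_id for g in extra]

    # planted DE: 24 of the stimulated-bound genes (Stim-only + Shift + Basal
    # pools) and 80 unbound genes, alternating up/down at |log2 effect| 2
    stim_bound = [g for g, c in truth.items()
                  if c in ("Basal", "Shift", "StimulatedOnly")]
    de_bound = sorted(stim_bound)[:24]
    de_unbound = [f"G{i+1:03d}" for i in range(80, 160)]
    de_effects = {
        g: (2.0 if j % 2 == 0 else -2.0)
        for j, g in enumerate(de_bound + de_unbound)
    }
    return PatternDesign(
        genome=genome,
        peaks=peaks,
        background_density=0.01,
        truth_category=truth,
        de_effects=de_effects,
        expression_gene_ids=expression_gene_ids,
        bound_de_genes=de_bound,
    )


def expression_genome(design: PatternDesign) -> SyntheticGenome:
    """Genome object spanning the full 400-gene expression universe."""
    chrom_sizes = dict(design.genome.chrom_sizes)
    chrom_sizes["chrE"] = 21_000_000
    extra = tuple(
        GeneModel(f"G{i+1:03d}", "chrE", "+", 10_000 + (i - 80) * 60_000,
                  10_000 + (i - 80) * 60_000 + 20_000)
        for i in range(80, 400)
    )
    return SyntheticGenome(chrom_sizes=chrom_sizes,
                           genes=design.genome.genes + extra)


def cohort_spec(seed: int = 0) -> PlantedCohortSpec:
    """Survival study conditions: 60 patients, 60 genes, 12 prognostic,
    effect 3 SD, hazard ratio 4, 20% censoring."""
    return PlantedCohortSpec(
        n_patients=60,
        n_genes=60,
        prognostic_genes=tuple(range(12)),
        effect_size=3.0,
        hazard_ratio=4.0,
        censoring_fraction=0.2,
        seed=seed,
    )
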