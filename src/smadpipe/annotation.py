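"""Gene assignment of binding loci and four-way binding-pattern calls.

A locus is assigned to the gene whose TSS is nearest to the locus summit,
provided that distance is within a window (default ±100 kb); distances are
signed in gene orientation (negative = upstream of the TSS). Between two
conditions, gene-assigned loci are classified as Basal (paired loci on the
same gene ≤ 1 kb apart), Shift (paired, > 1 kb apart), Stimulated Only or
Unstimulated Only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .peaks import BindingLocus

__all__ = [
    "GeneModel",
    "LocusAssignment",
    "PatternCall",
    "assign_to_genes",
    "tss_distance_histogram",
    "classify_patterns",
    "pattern_summary",
    "summarize_counts",
    "annotation_summary",
    "round_pct",
]

CATEGORIES = ("Basal", "Shift", "StimulatedOnly", "UnstimulatedOnly")


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates with strand-aware TSS (5' end) and TES (3' end)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError("TSS and TES must differ")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError("+ strand gene requires TSS < TES")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError("- strand gene requires TSS > TES")


@dataclass(frozen=True)
class LocusAssignment:
    locus: BindingLocus
    gene_id: str | None
    tss_distance: int | None  # signed, gene orientation; None if unassigned
    promoter: bool


@dataclass(frozen=True)
class PatternCall:
    gene_id: str
    category: str
    stim_locus: BindingLocus | None = None
    unstim_locus: BindingLocus | None = None
    distance: int | None = None  # summit distance for paired categories


def assign_to_genes(
    loci: list[BindingLocus],
    genes: list[GeneModel],
    window: int = 100_000,
    promoter_window: int = 8_000,
) -> list[LocusAssignment]:
    """Assign each locus to the nearest-TSS gene within ``window``.

    Ties in absolute distance are broken toward the smaller TSS coordinate,
    then the lexicographically smaller gene id. Loci on chromosomes absent
    from the gene annotation raise, as the two inputs are expected to share
    a chromosome namespace.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in glist]), glist)

    out: list[LocusAssignment] = []
    for locus in loci:
        if locus.chrom not in index:
            raise ValueError(f"locus on unknown chromosome {locus.chrom!r}")
        tss_arr, glist = index[locus.chrom]
        i = int(np.searchsorted(tss_arr, locus.summit))
        best: GeneModel | None = None
        best_abs = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(glist):
                g = glist[j]
                d = abs(locus.summit - g.tss)
                key = (d, g.tss, g.gene_id)
                if best is None or key < (best_abs, best.tss, best.gene_id):
                    best, best_abs = g, d
        if best is None or best_abs > window:
            out.append(LocusAssignment(locus, None, None, False))
            continue
        signed = locus.summit - best.tss
        if best.strand == "-":
            signed = -signed
        out.append(
            LocusAssignment(locus, best.gene_id, int(signed), abs(signed) <= promoter_window)
        )
    return out


def tss_distance_histogram(
    assignments: list[LocusAssignment], bin_width: int = 10_000
) -> pd.DataFrame:
    """Histogram of signed TSS distances of assigned loci.

    Bin edges are aligned at zero; unassigned loci are excluded. Returns a
    table with columns bin_left, bin_right, count.
    """
    if not assignments:
        raise ValueError("no assignments to histogram")
    d = np.array([a.tss_distance for a in assignments if a.gene_id is not None])
    if d.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = int(np.floor(d.min() / bin_width)) * bin_width
    hi = int(np.floor(d.max() / bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def classify_patterns(
    stim: list[LocusAssignment],
    unstim: list[LocusAssignment],
    shift_threshold: int = 1_000,
) -> list[PatternCall]:
    """Classify gene-assigned loci of two conditions into binding patterns.

    Per gene, stimulated and unstimulated loci are paired greedily
    nearest-first by summit distance (ties toward the leftmost stimulated
    summit). A pair at distance ≤ ``shift_threshold`` is Basal, above it
    Shift; leftover loci become StimulatedOnly / UnstimulatedOnly. Every
    gene-assigned locus lands in exactly one call.
    """
    genes: dict[str, tuple[list[BindingLocus], list[BindingLocus]]] = {}
    for a in stim:
        if a.gene_id is not None:
            genes.setdefault(a.gene_id, ([], []))[0].append(a.locus)
    for a in unstim:
        if a.gene_id is not None:
            genes.setdefault(a.gene_id, ([], []))[1].append(a.locus)

    calls: list[PatternCall] = []
    for gene_id in sorted(genes):
        s_loci, u_loci = genes[gene_id]
        pairs = sorted(
            (
                (abs(s.summit - u.summit), s.summit, u.summit, si, ui)
                for si, s in enumerate(s_loci)
                for ui, u in enumerate(u_loci)
            )
        )
        used_s: set[int] = set()
        used_u: set[int] = set()
        for dist, _, _, si, ui in pairs:
            if si in used_s or ui in used_u:
                continue
            used_s.add(si)
            used_u.add(ui)
            category = "Basal" if dist <= shift_threshold else "Shift"
            calls.append(
                PatternCall(gene_id, category, s_loci[si], u_loci[ui], int(dist))
            )
        for si, s in enumerate(s_loci):
            if si not in used_s:
                calls.append(PatternCall(gene_id, "StimulatedOnly", stim_locus=s))
        for ui, u in enumerate(u_loci):
            if ui not in used_u:
                calls.append(PatternCall(gene_id, "UnstimulatedOnly", unstim_locus=u))
    return calls


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in reports."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator for a percentage")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Category counts → percentages of their total (one condition's loci)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no loci to summarize")
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "total": total,
            "percent": [round_pct(v, total) for v in counts.values()],
        }
    )


def pattern_summary(calls: list[PatternCall], condition: str) -> pd.DataFrame:
    """Per-condition category counts and percentages.

    ``condition`` is ``"stimulated"`` or ``"unstimulated"``; each paired
    call (Basal/Shift) contributes one locus to either condition, and the
    condition-only category applicable to that condition contributes its
    loci. Percentages are of that condition's gene-assigned loci, rounded
    half-up to one decimal.
    """
    if not calls:
        raise ValueError("no pattern calls to summarize")
    if condition not in ("stimulated", "unstimulated"):
        raise ValueError("condition must be 'stimulated' or 'unstimulated'")
    only = "StimulatedOnly" if condition == "stimulated" else "UnstimulatedOnly"
    counts = {only: 0, "Shift": 0, "Basal": 0}
    for call in calls:
        if call.category in counts:
            counts[call.category] += 1
    return summarize_counts(counts)


def annotation_summary(
    assignments: list[LocusAssignment],
) -> dict[str, float | int]:
    """Genome-wide assignment summary for one condition.

    Percentages use the total locus count as denominator, matching how the
    assigned fraction and the promoter fraction are conventionally reported
    for a peak set.
    """
    total = len(assignments)
    assigned = sum(1 for a in assignments if a.gene_id is not None)
    promoter = sum(1 for a in assignments if a.promoter)
    return {
        "total_loci": total,
        "assigned": assigned,
        "assigned_pct": round_pct(assigned, total),
        "promoter": promoter,
        "promoter_pct": round_pct(promoter, total),
    }
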