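"""Synthetic inputs with planted ground truth for the whole pipeline.

Every input the analysis consumes — mapped ChIP/input reads, gene
annotation, triplicate expression matrices, binding-locus sequences, PWM
libraries, and a patient cohort — can be generated here with known planted
structure (enriched regions with Basal/Shift/condition-specific layout,
differentially expressed genes, embedded motif instances, and a prognostic
gene group separating good- from poor-survival patients), so each stage is
testable against its own ground truth with no external download.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .network import PWM, _BASES
from .peaks import MappedReadSet
from .survival import CohortData

__all__ = [
    "SyntheticGenome",
    "PlantedPeakSpec",
    "PlantedCohortSpec",
    "generate_reads",
    "generate_expression",
    "generate_locus_sequences",
    "generate_cohort",
    "generate_pwm_library",
    "condition_peaks",
]


@dataclass(frozen=True)
class SyntheticGenome:
    """Chromosome sizes plus a universe of gene models."""

    chrom_sizes: dict[str, int]
    genes: tuple[GeneModel, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids must be unique")
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome")
            size = self.chrom_sizes[g.chrom]
            if not (0 <= min(g.tss, g.tes) and max(g.tss, g.tes) <= size):
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")

    @property
    def length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class PlantedPeakSpec:
    """A ground-truth enrichment region.

    ``condition`` is "stimulated", "unstimulated" or "both"; for "both",
    the unstimulated window sits at ``center`` and the stimulated window at
    ``center + pairing_offset``, so the offset is the planted inter-summit
    distance (≤ 1 kb plants a Basal pair, > 1 kb a Shift pair).
    """

    chrom: str
    center: int
    enrichment: float
    width: int = 300
    condition: str = "stimulated"
    pairing_offset: int = 0
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.enrichment <= 1:
            raise ValueError("enrichment factor must exceed 1")
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.condition not in ("stimulated", "unstimulated", "both"):
            raise ValueError(f"bad condition {self.condition!r}")


@dataclass(frozen=True)
class PlantedCohortSpec:
    """Ground truth for a synthetic patient cohort.

    ``effect_size`` separates the two latent patient groups in the
    prognostic genes, in SDs of the expression noise. Survival times are
    exponential with ``baseline_hazard`` (per month) in the good-prognosis
    group and ``baseline_hazard * hazard_ratio`` in the poor one;
    censoring hits a ``censoring_fraction`` of patients independently,
    uniformly before their event time.
    """

    n_patients: int
    n_genes: int
    prognostic_genes: tuple[int, ...]
    effect_size: float = 3.0
    baseline_hazard: float = float(np.log(2) / 63.0)  # median 63 months
    hazard_ratio: float = 4.0
    censoring_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if not 0 <= self.censoring_fraction <= 1:
            raise ValueError("censoring fraction must be in [0, 1]")
        if self.prognostic_genes and (
            min(self.prognostic_genes) < 0
            or max(self.prognostic_genes) >= self.n_genes
        ):
            raise ValueError("prognostic gene indices out of range")


def condition_peaks(
    specs: list[PlantedPeakSpec], condition: str
) -> list[PlantedPeakSpec]:
    """Resolve per-condition effective peak windows from planted specs."""
    out = []
    for s in specs:
        if s.condition == condition:
            out.append(s)
        elif s.condition == "both":
            center = s.center + (s.pairing_offset if condition == "stimulated" else 0)
            out.append(
                PlantedPeakSpec(
                    s.chrom, center, s.enrichment, s.width, condition,
                    gene_id=s.gene_id,
                )
            )
    return out


def generate_reads(
    genome: SyntheticGenome,
    peaks: list[PlantedPeakSpec],
    background_density: float,
    n_reads: int | None = None,
    seed: int = 0,
    sample: str = "chip",
    read_length: int = 36,
) -> MappedReadSet:
    """Draw single-end read starts with uniform background plus spikes.

    Read starts fall uniformly at ``background_density`` reads/bp, except
    inside each planted peak window (``center ± width/2``) where the
    density is multiplied by the peak's enrichment factor. When ``n_reads``
    is omitted it is set so the background density is attained exactly in
    expectation; when given, it fixes the total and the density argument
    only shapes the relative weights.
    """
    if background_density <= 0:
        raise ValueError("background_density must be positive")
    rng = np.random.default_rng(seed)
    # per-chromosome piecewise-constant weights
    segments: list[tuple[str, int, int, float]] = []
    for chrom, size in genome.chrom_sizes.items():
        chrom_peaks = sorted(
            (p for p in peaks if p.chrom == chrom), key=lambda p: p.center
        )
        pos = 0
        for p in chrom_peaks:
            start = p.center - p.width // 2
            end = start + p.width
            if start < 0 or end > size:
                raise ValueError(
                    f"planted peak at {chrom}:{p.center} outside chromosome bounds"
                )
            if start < pos:
                raise ValueError("overlapping planted peak windows")
            if start > pos:
                segments.append((chrom, pos, start, 1.0))
            segments.append((chrom, start, end, float(p.enrichment)))
            pos = end
        if pos < size:
            segments.append((chrom, pos, size, 1.0))

    weights = np.array([(e - s) * w for _, s, e, w in segments])
    if n_reads is None:
        n_reads = int(round(background_density * weights.sum()))
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    counts = rng.multinomial(n_reads, weights / weights.sum())
    positions: dict[str, list[np.ndarray]] = {c: [] for c in genome.chrom_sizes}
    for (chrom, s, e, _), n in zip(segments, counts):
        if n:
            positions[chrom].append(rng.integers(s, e, size=int(n)))
    pos_arrays = {}
    strands = {}
    for chrom in genome.chrom_sizes:
        arr = (
            np.sort(np.concatenate(positions[chrom]))
            if positions[chrom]
            else np.array([], dtype=np.int64)
        )
        pos_arrays[chrom] = arr
        strands[chrom] = np.where(
            rng.random(arr.size) < 0.5, "+", "-"
        ).astype("<U1")
    return MappedReadSet(
        sample=sample,
        chrom_sizes=dict(genome.chrom_sizes),
        positions=pos_arrays,
        strands=strands,
        read_length=read_length,
    )


def generate_expression(
    genome: SyntheticGenome,
    de_gene_ids: set[str] | dict[str, float],
    log2_effect: float = 2.0,
    noise_sd: float = 0.3,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate-style two-condition log2 expression matrix.

    Non-DE genes share their mean across conditions; DE genes get
    ``log2_effect`` added to the stimulated mean (or a per-gene signed
    effect when ``de_gene_ids`` is a mapping). Gaussian noise with
    ``noise_sd`` is added independently per sample. Columns are
    ``unstim_1.. unstim_n, stim_1.. stim_n``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    gene_ids = [g.gene_id for g in genome.genes]
    known = set(gene_ids)
    effects = (
        dict(de_gene_ids)
        if isinstance(de_gene_ids, dict)
        else {g: log2_effect for g in de_gene_ids}
    )
    unknown = set(effects) - known
    if unknown:
        raise ValueError(f"unknown gene ids in de_gene_ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    base = rng.uniform(6.0, 12.0, size=len(gene_ids))
    effect_vec = np.array([effects.get(g, 0.0) for g in gene_ids])
    cols = [f"unstim_{i+1}" for i in range(n_replicates)] + [
        f"stim_{i+1}" for i in range(n_replicates)
    ]
    means = np.column_stack(
        [base] * n_replicates + [base + effect_vec] * n_replicates
    )
    noise = (
        rng.normal(0.0, noise_sd, size=means.shape) if noise_sd > 0 else 0.0
    )
    return pd.DataFrame(means + noise, index=pd.Index(gene_ids, name="gene_id"),
                        columns=cols)


def generate_locus_sequences(
    loci,
    pwm: PWM,
    planted_fraction: float,
    seed: int = 0,
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> dict[str, str]:
    """I.i.d. background sequences with motif instances planted in a subset.

    Each locus gets a sequence of its own length; a ``planted_fraction``
    subset receives one PWM-sampled motif instance at a random offset on a
    random strand. Returns a mapping from a locus id
    (``chrom:start-end``) to its sequence.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(loci)
    n_planted = int(round(planted_fraction * n))
    planted = set(rng.choice(n, size=n_planted, replace=False)) if n_planted else set()
    freqs = np.asarray(background_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    out: dict[str, str] = {}
    comp = str.maketrans("ACGT", "TGCA")
    for i, locus in enumerate(loci):
        length = locus.length
        seq = "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=freqs)])
        if i in planted:
            if len(pwm) > length:
                raise ValueError("motif longer than locus sequence")
            site = pwm.sample_site(rng)
            if rng.random() < 0.5:
                site = site.translate(comp)[::-1]
            off = int(rng.integers(0, length - len(pwm) + 1))
            seq = seq[:off] + site + seq[off + len(pwm):]
        out[f"{locus.chrom}:{locus.start}-{locus.end}"] = seq
    return out


def generate_pwm_library(
    n_motifs: int,
    length: int = 8,
    seed: int = 0,
    information: float = 0.95,
) -> list[PWM]:
    """Random PWM library: each motif has a consensus held at probability
    ``information`` per position, remaining mass spread over the other
    bases."""
    rng = np.random.default_rng(seed)
    library = []
    for i in range(n_motifs):
        consensus = rng.integers(0, 4, size=length)
        counts = np.full((length, 4), (1 - information) / 3 * 100)
        counts[np.arange(length), consensus] = information * 100
        library.append(PWM(f"MOTIF{i+1:03d}", counts))
    return library


def generate_cohort(spec: PlantedCohortSpec) -> CohortData:
    """Synthetic patient cohort with a planted prognostic gene group.

    Half the patients form a poor-prognosis latent group whose expression
    of the prognostic genes is shifted by ``effect_size`` noise-SDs;
    survival is exponential with the spec's hazards and censoring. The
    planted patient groups and gene indices are recorded in ``truth``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_patients, spec.n_genes
    patients = [f"P{i+1:03d}" for i in range(n)]
    genes = [f"SG{i+1:04d}" for i in range(m)]
    poor = np.zeros(n, dtype=bool)
    poor[rng.permutation(n)[: n // 2]] = True
    expr = rng.normal(0.0, 1.0, size=(m, n))
    prog = list(spec.prognostic_genes)
    expr[np.ix_(prog, np.flatnonzero(poor))] += spec.effect_size
    hazard = np.where(
        poor, spec.baseline_hazard * spec.hazard_ratio, spec.baseline_hazard
    )
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < spec.censoring_fraction
    time = np.where(censored, t_event * rng.random(n), t_event)
    event = (~censored).astype(int)
    time = np.maximum(time, 1e-6)  # survival times must be positive
    return CohortData(
        matrix=pd.DataFrame(expr, index=genes, columns=patients),
        time=pd.Series(time, index=patients, name="time_months"),
        event=pd.Series(event, index=patients, name="event"),
        truth={
            "poor_group": pd.Series(poor, index=patients),
            "prognostic_genes": [genes[i] for i in prog],
        },
    )
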