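"""Percentile-scoring ChIP-seq peak calling with simulated-read FDR.

The caller follows the BELT strategy: reads are counted in fixed-width bins
(default 300 nt), an enrichment threshold is taken as a high percentile of
the nonzero-bin count distribution (default the 0.996 level), significant
bins are required to exceed the depth-scaled input control, adjacent
significant bins are merged into binding loci, and the false discovery rate
at each percentile level is estimated by re-calling a uniformly simulated
read set of equal depth with the same thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MappedReadSet",
    "BinTrack",
    "BindingLocus",
    "bin_reads",
    "percentile_threshold",
    "call_loci",
    "estimate_fdr",
    "simulate_uniform_reads",
]


@dataclass
class MappedReadSet:
    """Per-chromosome sorted read start positions (0-based) with strand.

    ``positions`` maps chromosome name to an ascending int array of read
    starts; ``strands`` maps to a matching array of ``+``/``-`` characters.
    """

    sample: str
    chrom_sizes: dict[str, int]
    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray] = field(default_factory=dict)
    read_length: int = 36

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if chrom not in self.chrom_sizes:
                raise ValueError(f"reads on unknown chromosome {chrom!r}")
            if pos.size and (pos.min() < 0 or pos.max() >= self.chrom_sizes[chrom]):
                raise ValueError(f"read positions outside {chrom!r} bounds")
            if np.any(np.diff(pos) < 0):
                pos = np.sort(pos)
            self.positions[chrom] = pos
            if chrom not in self.strands:
                self.strands[chrom] = np.full(pos.size, "+", dtype="<U1")

    @property
    def total(self) -> int:
        return int(sum(p.size for p in self.positions.values()))


@dataclass
class BinTrack:
    """Fixed-width bin counts for one sample, one array per chromosome."""

    bin_width: int
    counts: dict[str, np.ndarray]
    sample: str = ""

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def same_geometry(self, other: "BinTrack") -> bool:
        return self.bin_width == other.bin_width and {
            c: v.size for c, v in self.counts.items()
        } == {c: v.size for c, v in other.counts.items()}

    def nonzero_counts(self) -> np.ndarray:
        parts = [c[c > 0] for c in self.counts.values()]
        if not parts:
            return np.array([], dtype=np.int64)
        return np.concatenate(parts)


@dataclass(frozen=True)
class BindingLocus:
    """A called peak; coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    level: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("locus start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the locus")

    @property
    def length(self) -> int:
        return self.end - self.start


def bin_reads(reads: MappedReadSet, bin_width: int) -> BinTrack:
    """Count read starts into fixed-width bins.

    A read starting at ``s`` falls in bin ``floor(s / bin_width)``; the
    trailing partial bin of each chromosome is kept, so every read is
    counted exactly once. Strand is ignored (no shift/extension model).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[str, np.ndarray] = {}
    for chrom, size in reads.chrom_sizes.items():
        n_bins = max(1, math.ceil(size / bin_width))
        pos = reads.positions.get(chrom, np.array([], dtype=np.int64))
        counts[chrom] = np.bincount(pos // bin_width, minlength=n_bins).astype(
            np.int64
        )
    return BinTrack(bin_width=bin_width, counts=counts, sample=reads.sample)


def percentile_threshold(track: BinTrack, percentile_level: float) -> int:
    """Enrichment threshold at a percentile level of the nonzero bins.

    Returns the smallest observed nonzero count ``c`` such that the
    fraction of nonzero bins with count >= ``c`` is at most
    ``1 - percentile_level``. When no observed count satisfies this (e.g. a
    constant track, where every bin ties), the maximum observed count is
    returned. Zero bins are excluded: most of the genome is empty, and
    including zeros would let any nonzero count pass.
    """
    if not 0.0 < percentile_level < 1.0:
        raise ValueError("percentile_level must be in (0, 1)")
    nz = track.nonzero_counts()
    if nz.size == 0:
        raise ValueError("all-zero track: no signal to threshold")
    values, tail = _tail_fractions(nz)
    admissible = tail <= (1.0 - percentile_level)
    if not admissible.any():
        return int(values[-1])
    return int(values[admissible.argmax()])


def _tail_fractions(nz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique nonzero counts (ascending) and P(count >= value)."""
    values, counts = np.unique(nz, return_counts=True)
    tail = counts[::-1].cumsum()[::-1] / nz.size
    return values, tail


def call_loci(
    chip: BinTrack,
    input_track: BinTrack,
    percentile_level: float = 0.996,
    min_gap: int = 1,
    condition: str | None = None,
) -> list[BindingLocus]:
    """Call binding loci from a ChIP track against an input control.

    The input is scaled by the library-size ratio (chip total / input
    total). A bin is significant when its chip count reaches the percentile
    threshold and exceeds the scaled input count; significant bins whose
    indices differ by at most ``min_gap`` are merged into one locus. The
    summit is the center of the merged locus's maximum-count bin (leftmost
    on ties) and the score is the summed chip count minus summed scaled
    input count over the merged bins.
    """
    if not chip.same_geometry(input_track):
        raise ValueError("chip and input tracks have different bin geometry")
    threshold = percentile_threshold(chip, percentile_level)
    return _call_with_threshold(
        chip, input_track, threshold, percentile_level, min_gap, condition
    )


def _call_with_threshold(
    chip: BinTrack,
    input_track: BinTrack,
    threshold: int,
    percentile_level: float,
    min_gap: int,
    condition: str | None,
) -> list[BindingLocus]:
    scale = chip.total / input_track.total if input_track.total > 0 else 0.0
    w = chip.bin_width
    loci: list[BindingLocus] = []
    label = condition if condition is not None else chip.sample
    for chrom in chip.counts:
        c = chip.counts[chrom]
        scaled_input = input_track.counts[chrom] * scale
        sig = np.flatnonzero((c >= threshold) & (c > scaled_input))
        if sig.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(sig) > min_gap)
        for run in np.split(sig, breaks + 1):
            first, last = int(run[0]), int(run[-1])
            block = np.arange(first, last + 1)
            max_bin = first + int(np.argmax(c[first : last + 1]))
            score = float(c[block].sum() - scaled_input[block].sum())
            loci.append(
                BindingLocus(
                    chrom=chrom,
                    start=first * w,
                    end=(last + 1) * w,
                    summit=max_bin * w + w // 2,
                    score=score,
                    level=percentile_level,
                    condition=label,
                )
            )
    return loci


def simulate_uniform_reads(
    chrom_sizes: dict[str, int], n_reads: int, seed: int, sample: str = "simulated"
) -> MappedReadSet:
    """Place ``n_reads`` read starts uniformly over the genome."""
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    per_chrom = rng.multinomial(n_reads, sizes / sizes.sum())
    positions = {
        chrom: np.sort(rng.integers(0, chrom_sizes[chrom], size=int(n)))
        for chrom, n in zip(chroms, per_chrom)
    }
    return MappedReadSet(sample=sample, chrom_sizes=dict(chrom_sizes), positions=positions)


def estimate_fdr(
    chip: BinTrack,
    input_track: BinTrack,
    chrom_sizes: dict[str, int],
    percentile_levels: list[float],
    seed: int,
    n_simulated_reads: int | None = None,
    min_gap: int = 1,
) -> pd.DataFrame:
    """Estimate per-level FDR from a uniformly simulated read background.

    A read set of the chip's depth (by default) is placed uniformly over
    the genome, binned with the chip geometry, and called with the chip's
    own per-level thresholds against the same input. The FDR at a level is
    the simulated locus count divided by the observed locus count (clipped
    to 1; zero observed loci give FDR 0 when nothing is simulated either).

    Returns a table with columns level, threshold, observed, simulated, fdr.
    """
    if n_simulated_reads is None:
        n_simulated_reads = chip.total
    sim_reads = simulate_uniform_reads(chrom_sizes, n_simulated_reads, seed)
    sim_track = bin_reads(sim_reads, chip.bin_width)
    rows = []
    for level in sorted(percentile_levels):
        threshold = percentile_threshold(chip, level)
        observed = len(
            _call_with_threshold(chip, input_track, threshold, level, min_gap, None)
        )
        simulated = len(
            _call_with_threshold(sim_track, input_track, threshold, level, min_gap, None)
        )
        fdr = min(1.0, simulated / max(observed, 1))
        rows.append(
            {
                "level": level,
                "threshold": threshold,
                "observed": observed,
                "simulated": simulated,
                "fdr": fdr,
            }
        )
    return pd.DataFrame(rows)
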