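"""Peak-calling unit and property tests against brute-force oracles."""

import numpy as np
import pytest

from smadpipe.peaks import (
    BinTrack,
    MappedReadSet,
    bin_reads,
    call_loci,
    estimate_fdr,
    percentile_threshold,
    simulate_uniform_reads,
)
from smadpipe.study import recovery_design
from smadpipe.synthetic import generate_reads

from oracles import call_loci_bruteforce, histogram_bins, percentile_threshold_bruteforce


def _readset(positions, size=3000, chrom="chr1"):
    return MappedReadSet(
        sample="t", chrom_sizes={chrom: size},
        positions={chrom: np.array(positions, dtype=np.int64)},
    )


def _track(counts, bin_width=300, chrom="chr1"):
    return BinTrack(bin_width=bin_width,
                    counts={chrom: np.array(counts, dtype=np.int64)})


class TestBinReads:
    def test_bin_boundaries(self):
        track = bin_reads(_readset([0, 299, 300]), 300)
        assert track.counts["chr1"][:2].tolist() == [2, 1]
        assert track.counts["chr1"][2:].sum() == 0

    def test_conserves_reads_and_matches_histogram_oracle(self, rng):
        pos = rng.integers(0, 1_000_000, size=10_000)
        reads = _readset(pos, size=1_000_000)
        track = bin_reads(reads, 300)
        assert track.total == 10_000
        oracle = histogram_bins(pos, 300, track.counts["chr1"].size)
        assert track.counts["chr1"].tolist() == oracle

    def test_empty_read_set_gives_zero_track(self):
        track = bin_reads(_readset([]), 300)
        assert track.total == 0
        assert track.counts["chr1"].sum() == 0


class TestPercentileThreshold:
    def test_constant_track(self):
        track = _track([5] * 50)
        for level in (0.5, 0.9, 0.996):
            assert percentile_threshold(track, level) == 5

    def test_ninety_ten_split(self):
        track = _track([1] * 90 + [10] * 10)
        assert percentile_threshold(track, 0.90) == 10

    def test_matches_bruteforce_and_monotone_in_level(self, rng):
        counts = rng.poisson(3, size=2000)
        track = _track(counts)
        prev = 0
        for level in (0.5, 0.8, 0.9, 0.99, 0.996, 0.999):
            t = percentile_threshold(track, level)
            assert t == percentile_threshold_bruteforce(counts, level)
            assert t >= prev
            prev = t

    def test_all_zero_track_raises(self):
        with pytest.raises(ValueError):
            percentile_threshold(_track([0] * 10), 0.9)


class TestCallLoci:
    def test_no_enrichment_no_loci(self):
        chip = _track([4] * 100)
        ctrl = _track([4] * 100)
        assert call_loci(chip, ctrl, 0.996) == []

    def test_single_spiked_bin(self):
        counts = [2] * 100
        counts[40] = 100
        chip = _track(counts)
        ctrl = _track([2] * 100)
        loci = call_loci(chip, ctrl, 0.99)
        assert len(loci) == 1
        (locus,) = loci
        assert (locus.start, locus.end) == (40 * 300, 41 * 300)
        assert locus.summit == 40 * 300 + 150

    def test_matches_bruteforce_on_small_genomes(self, rng):
        # genomes <= 10 kb: enumerate every bin and merge by scanning
        for trial in range(20):
            n_bins = int(rng.integers(5, 34))
            chip_counts = rng.poisson(3, size=n_bins)
            chip_counts[rng.integers(0, n_bins)] += 30
            input_counts = rng.poisson(3, size=n_bins)
            if chip_counts.sum() == 0 or input_counts.sum() == 0:
                continue
            chip, ctrl = _track(chip_counts), _track(input_counts)
            level, min_gap = 0.9, int(rng.integers(1, 4))
            thr = percentile_threshold(chip, level)
            loci = call_loci(chip, ctrl, level, min_gap=min_gap)
            oracle = call_loci_bruteforce(
                chip_counts.tolist(), input_counts.tolist(),
                int(chip_counts.sum()), int(input_counts.sum()),
                thr, min_gap, 300,
            )
            assert [(l.start, l.end, l.summit) for l in loci] == [
                (s, e, m) for s, e, m, _ in oracle
            ]
            for locus, (_, _, _, score) in zip(loci, oracle):
                assert locus.score == pytest.approx(score)

    def test_loci_sorted_nonoverlapping(self, rng):
        counts = rng.poisson(2, size=300)
        counts[[10, 11, 50, 200]] += 40
        loci = call_loci(_track(counts), _track(rng.poisson(2, size=300)), 0.95)
        for a, b in zip(loci, loci[1:]):
            assert a.end <= b.start

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError):
            call_loci(_track([1] * 10), _track([1] * 11), 0.9)


class TestPlantedRecovery:
    def test_twenty_planted_peaks_recovered(self, rng):
        genome_sizes = {"chr1": 3_000_000}
        from smadpipe.synthetic import PlantedPeakSpec, SyntheticGenome

        genome = SyntheticGenome(chrom_sizes=genome_sizes)
        peaks = [
            PlantedPeakSpec("chr1", 150 + i * 140_000 + 300 * 250, 15.0, 300)
            for i in range(20)
        ]
        chip = generate_reads(genome, peaks, 0.01, seed=11, sample="chip")
        ctrl = generate_reads(genome, [], 0.01, seed=12, sample="input")
        loci = call_loci(bin_reads(chip, 300), bin_reads(ctrl, 300), 0.996)
        recovered = sum(
            1 for p in peaks
            if any(l.chrom == p.chrom and abs(l.summit - p.center) <= 300
                   for l in loci)
        )
        assert recovered >= 18


class TestEstimateFdr:
    def test_fdr_zero_when_no_simulated_loci(self):
        counts = np.full(400, 3)
        counts[[50, 150, 250]] = 120
        chip = _track(counts)
        ctrl = _track(np.full(400, 3))
        table = estimate_fdr(chip, ctrl, {"chr1": 400 * 300}, [0.996], seed=5)
        assert table.loc[0, "observed"] == 3
        assert table.loc[0, "simulated"] == 0
        assert table.loc[0, "fdr"] == 0.0

    def test_uniform_chip_fdr_near_one(self):
        sizes = {"chr1": 600_000}
        fdrs = []
        for seed in range(8):
            chip = bin_reads(simulate_uniform_reads(sizes, 6000, seed), 300)
            ctrl = bin_reads(simulate_uniform_reads(sizes, 6000, 100 + seed), 300)
            table = estimate_fdr(chip, ctrl, sizes, [0.99], seed=200 + seed)
            fdrs.append(table.loc[0, "fdr"])
        assert np.mean(fdrs) > 0.5  # noise calls are as frequent as simulated

    def test_fdr_nonincreasing_as_level_tightens_on_planted_data(self):
        genome, peaks, density = recovery_design()
        chip = generate_reads(genome, peaks[:20] + peaks[70:90], density, seed=3)
        ctrl = generate_reads(genome, [], density, seed=4, sample="input")
        table = estimate_fdr(
            bin_reads(chip, 300), bin_reads(ctrl, 300), genome.chrom_sizes,
            [0.99, 0.996, 0.999], seed=9,
        )
        fdr = table.sort_values("level")["fdr"].to_numpy()
        assert np.all(np.diff(fdr) <= 1e-12)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    positions=st.lists(st.integers(0, 9_999), max_size=200),
    bin_width=st.integers(1, 1_000),
)
def test_bin_reads_conserves_every_read(positions, bin_width):
    """Property: each read lands in exactly one bin (floor division)."""
    reads = _readset(sorted(positions), size=10_000)
    track = bin_reads(reads, bin_width)
    assert track.total == len(positions)
    assert track.counts["chr1"].tolist() == histogram_bins(
        positions, bin_width, track.counts["chr1"].size)


def test_generate_reads_deterministic(small_genome):
    a = generate_reads(small_genome, [], 0.01, seed=42)
    b = generate_reads(small_genome, [], 0.01, seed=42)
    for chrom in small_genome.chrom_sizes:
        assert np.array_equal(a.positions[chrom], b.positions[chrom])
        assert np.array_equal(a.strands[chrom], b.strands[chrom])
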