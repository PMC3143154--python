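"""PWM scanning, hub discovery, shuffling, and network wiring tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smadpipe.network import (
    PWM,
    build_network,
    count_hits,
    dinucleotide_shuffle,
    find_hub_tfs,
    permutation_edge_test,
    scan_pwm,
)
from smadpipe.synthetic import generate_pwm_library

from oracles import scan_windows_bruteforce

IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def sharp_pwm(consensus, motif_id="M"):
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, IDX[b]] = 1e7
    return PWM(motif_id, counts)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestPWM:
    def test_columns_normalized(self):
        pwm = generate_pwm_library(1, seed=0)[0]
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            PWM("X", np.ones((3, 4)))

    def test_consensus_scores_maximum(self):
        pwm = generate_pwm_library(1, seed=3)[0]
        (hit,) = [h for h in scan_pwm(pwm.consensus, pwm, 1.0) if h.strand == "+"]
        assert hit.score == pytest.approx(pwm.max_score)
        assert hit.score_fraction == pytest.approx(1.0)


class TestScanPwm:
    def test_exact_consensus_single_hit(self):
        pwm = sharp_pwm("ACGT")
        hits = scan_pwm("ACGT", pwm, 1.0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].offset == 0

    def test_tandem_repeat_and_strand_symmetry(self):
        pwm = sharp_pwm("ACCT")
        fwd = [h for h in scan_pwm("ACCTACCT", pwm, 1.0) if h.strand == "+"]
        assert len(fwd) == 2
        rc = "AGGTAGGT"  # reverse complement of the tandem
        rev = [h for h in scan_pwm(rc, pwm, 1.0) if h.strand == "-"]
        assert len(rev) == 2

    def test_sequence_shorter_than_motif_empty(self):
        assert scan_pwm("ACG", sharp_pwm("ACGT"), 0.5) == []

    def test_n_windows_skipped(self):
        pwm = sharp_pwm("ACGT")
        assert scan_pwm("ACNT", pwm, 0.1) == []
        hits = scan_pwm("NACGTN", pwm, 1.0)
        assert {h.offset for h in hits} == {1}

    def test_matches_bruteforce_window_oracle(self, rng):
        pwm = generate_pwm_library(1, length=8, seed=5, information=0.6)[0]
        for trial in range(5):
            seq = random_seq(rng, 200)
            hits = scan_pwm(seq, pwm, 0.8)
            oracle = scan_windows_bruteforce(
                seq, pwm.probs, pwm.background, True, 0.8
            )
            assert sorted((h.offset, h.strand) for h in hits) == oracle


class TestFindHubTfs:
    def test_identical_sets_no_hubs(self, rng):
        seqs = {f"s{i}": random_seq(rng, 200) for i in range(30)}
        lib = generate_pwm_library(5, seed=1)
        table = find_hub_tfs(seqs, dict(seqs), lib)
        assert not table["hub"].any()

    def test_planted_motif_ranked_first_with_fisher_oracle(self, rng):
        lib = generate_pwm_library(8, seed=2)
        planted = lib[0]
        targets = {}
        for i in range(100):
            seq = random_seq(rng, 300)
            if i < 80:
                site = planted.consensus
                seq = seq[:50] + site + seq[50 + len(site):]
            targets[f"t{i}"] = seq
        background = {f"b{i}": random_seq(rng, 300) for i in range(100)}
        table = find_hub_tfs(targets, background, lib)
        top = table.iloc[0]
        assert top["motif_id"] == planted.motif_id and bool(top["hub"])
        # Fisher oracle on the realized 2x2 table
        t_with = int(top["targets_with_hit"])
        b_with = int(top["background_with_hit"])
        _, p = stats.fisher_exact(
            [[t_with, 100 - t_with], [b_with, 100 - b_with]], "greater"
        )
        assert top["p"] == pytest.approx(p)

    def test_half_planted_recovered_across_seeds(self):
        recovered = 0
        for seed in range(6):
            rng = np.random.default_rng(400 + seed)
            lib = generate_pwm_library(6, seed=seed)
            planted = lib[0]
            targets = {}
            for i in range(100):
                seq = random_seq(rng, 300)
                if i < 50:
                    seq = seq[:10] + planted.consensus + seq[10 + len(planted):]
                targets[f"t{i}"] = seq
            background = {f"b{i}": random_seq(rng, 300) for i in range(100)}
            table = find_hub_tfs(targets, background, lib)
            hubs = set(table.loc[table.hub, "motif_id"])
            if planted.motif_id in hubs:
                recovered += 1
        assert recovered == 6

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            find_hub_tfs({"a": "ACGT"}, {"b": "ACGT"}, [])


class TestDinucleotideShuffle:
    @staticmethod
    def dinucs(s):
        from collections import Counter

        return Counter(zip(s, s[1:]))

    def test_preserves_dinucleotide_counts_and_endpoints(self, rng):
        for n in (10, 50, 300):
            seq = random_seq(rng, n)
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == n
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
            assert self.dinucs(shuf) == self.dinucs(seq)

    def test_preserves_counts_on_arbitrary_sequences(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=40, deadline=None, derandomize=True)
        @given(seq=st.text(alphabet="ACGT", min_size=3, max_size=120),
               seed=st.integers(0, 2**16))
        def check(seq, seed):
            shuf = dinucleotide_shuffle(seq, np.random.default_rng(seed))
            assert self.dinucs(shuf) == self.dinucs(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

        check()

    def test_actually_shuffles(self, rng):
        seq = random_seq(rng, 500)
        outcomes = {dinucleotide_shuffle(seq, rng) for _ in range(5)}
        assert len(outcomes) > 1


class TestPermutationEdgeTest:
    def test_zero_observed_hits_p_one(self, rng):
        pwm = sharp_pwm("ACGTACGTAC")
        obs, p = permutation_edge_test([random_seq(rng, 50)], pwm,
                                       n_permutations=100, seed=1)
        assert obs == 0 and p == 1.0

    def test_addone_lower_bound(self, rng):
        pwm = sharp_pwm("ACGTTGCA")
        seq = random_seq(rng, 200)
        seq = seq[:20] + "ACGTTGCA" + seq[28:]
        _, p = permutation_edge_test([seq], pwm, n_permutations=100, seed=2)
        assert p >= 1 / 101

    def test_planted_consensus_significant(self):
        # 10-mer: chance re-formation in a 300-mer shuffle is ~6e-4 per
        # permutation, so the planted site should stand out at p <= 0.01
        site = "ACGTTGCAGT"
        pwm = sharp_pwm(site)
        significant = 0
        for seed in range(5):
            rng = np.random.default_rng(900 + seed)
            seq = random_seq(rng, 300)
            seq = seq[:100] + site + seq[110:]
            _, p = permutation_edge_test([seq], pwm, n_permutations=999,
                                         seed=seed)
            if p <= 0.01:
                significant += 1
        assert significant >= 4


class TestBuildNetwork:
    def _expr(self, genes, fcs):
        return pd.DataFrame({"log2fc": fcs}, index=genes)

    def test_no_hits_no_edges(self, rng):
        hubs = [sharp_pwm("ACGTACGTACGT", "H1")]
        loci = {"g1": [random_seq(rng, 50)], "g2": [random_seq(rng, 50)]}
        net = build_network(hubs, loci, self._expr(["g1", "g2"], [1.0, -1.0]))
        assert net.number_of_edges() == 0
        assert set(net.nodes) == {"H1"}

    def test_single_planted_edge_with_direction(self, rng):
        hubs = [sharp_pwm("ACGTTGCA", "H1")]
        seq = random_seq(rng, 100)
        loci = {"g1": [seq[:40] + "ACGTTGCA" + seq[48:]],
                "g2": [random_seq(rng, 100)]}
        net = build_network(hubs, loci, self._expr(["g1", "g2"], [-2.0, 1.0]))
        assert list(net.edges) == [("H1", "g1")]
        assert net.nodes["g1"]["direction"] == "down"

    def test_matches_scan_then_join_oracle(self, rng):
        lib = generate_pwm_library(5, seed=8)
        genes = [f"g{i}" for i in range(20)]
        loci = {}
        for i, g in enumerate(genes):
            seqs = [random_seq(rng, 120)]
            if i % 3 == 0:
                pwm = lib[i % 5]
                s = seqs[0]
                seqs[0] = s[:30] + pwm.consensus + s[30 + len(pwm):]
            loci[g] = seqs
        expr = self._expr(genes, [1.0] * 20)
        net = build_network(lib, loci, expr)
        expected = {
            (pwm.motif_id, g)
            for pwm in lib
            for g, seqs in loci.items()
            if count_hits(seqs, pwm) > 0
        }
        assert set(net.edges) == expected


def test_sif_round_trip(tmp_path, rng):
    from smadpipe.io import read_sif, write_sif

    hubs = [sharp_pwm("ACGTTGCA", "H1")]
    seq = random_seq(rng, 80)
    loci = {"g1": [seq[:10] + "ACGTTGCA" + seq[18:]]}
    net = build_network(hubs, loci, pd.DataFrame({"log2fc": [1.0]}, index=["g1"]))
    write_sif(net, tmp_path / "n.sif", tmp_path / "n.tsv")
    back = read_sif(tmp_path / "n.sif")
    assert set(back.edges) == set(net.edges)
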