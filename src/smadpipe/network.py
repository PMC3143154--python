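"""PWM motif scanning, hub-TF discovery, and permutation-tested networks.

Hub transcription factors are PWMs whose motif occurs in significantly
more target binding-locus sequences than in size- and length-matched
random background sequences (one-sided Fisher exact test, Benjamini–
Hochberg corrected), which removes motifs that are enriched in random
sets. The TF→gene network is wired by rescanning each gene's locus
sequences with the hub PWMs; every edge gets a permutation p-value from a
dinucleotide-preserving shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PWM",
    "MotifHit",
    "scan_pwm",
    "find_hub_tfs",
    "build_network",
    "permutation_edge_test",
    "annotate_edge_pvalues",
    "dinucleotide_shuffle",
]

_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


class PWM:
    """Position weight matrix with log-odds scoring.

    ``counts`` is an L×4 array (columns A, C, G, T). A pseudocount is added
    per cell before normalizing each position to probabilities, and scores
    are log2 odds against the background nucleotide frequencies.
    """

    def __init__(
        self,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.01,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("PWM counts must be an L x 4 array")
        if counts.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if np.any(counts < 0):
            raise ValueError("PWM counts must be non-negative")
        self.motif_id = motif_id
        self.pseudocount = pseudocount
        if background is None:
            background = np.full(4, 0.25)
        self.background = np.asarray(background, dtype=float)
        padded = counts + pseudocount
        self.probs = padded / padded.sum(axis=1, keepdims=True)
        self.log_odds = np.log2(self.probs / self.background)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one motif instance from the per-position probabilities."""
        return "".join(
            _BASES[rng.choice(4, p=self.probs[i])] for i in range(len(self))
        )


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int
    strand: str
    score: float
    score_fraction: float


def encode(sequence: str) -> np.ndarray:
    """Encode A/C/G/T to 0..3; any other symbol (N) becomes -1."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, code in _ENC.items():
        out[arr == ord(base)] = code
    return out


def _window_scores(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; windows containing N give -inf."""
    L = log_odds.shape[0]
    n = enc.size - L + 1
    if n <= 0:
        return np.array([])
    idx = np.arange(n)[:, None] + np.arange(L)[None, :]
    windows = enc[idx]
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, -np.inf)
    if valid.any():
        w = windows[valid]
        scores[valid] = log_odds[np.arange(L)[None, :], w].sum(axis=1)
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    score_fraction: float = 0.8,
    seq_id: str = "",
) -> list[MotifHit]:
    """Scan both strands, keeping windows scoring ≥ fraction × max score.

    Windows containing N are skipped. A sequence shorter than the motif
    yields an empty hit list. Offsets are 0-based positions on the input
    (forward) sequence for both strands.
    """
    if not 0.0 < score_fraction <= 1.0:
        raise ValueError("score_fraction must be in (0, 1]")
    enc = encode(sequence)
    cutoff = score_fraction * pwm.max_score
    hits: list[MotifHit] = []
    lo_rc = pwm.log_odds[::-1, ::-1]  # scores the reverse strand in place
    for strand, lo in (("+", pwm.log_odds), ("-", lo_rc)):
        scores = _window_scores(enc, lo)
        for off in np.flatnonzero(scores >= cutoff):
            s = float(scores[off])
            hits.append(
                MotifHit(seq_id, int(off), strand, s, s / pwm.max_score)
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def count_hits(sequences: list[str], pwm: PWM, score_fraction: float = 0.8) -> int:
    """Total motif hits over a list of sequences (both strands)."""
    return sum(len(scan_pwm(s, pwm, score_fraction)) for s in sequences)


def find_hub_tfs(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwm_library: list[PWM],
    score_fraction: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank PWMs by target-vs-background sequence-level enrichment.

    Per PWM, a one-sided Fisher exact test compares the number of target
    sequences with at least one hit against the background set; hubs are
    the PWMs significant after Benjamini–Hochberg at ``alpha`` whose
    target hit fraction exceeds the background hit fraction. Returns the
    full table ranked by adjusted then raw p, with a boolean ``hub``
    column.
    """
    if not pwm_library:
        raise ValueError("empty PWM library")
    rows = []
    n_t, n_b = len(target_seqs), len(background_seqs)
    for pwm in pwm_library:
        t_with = sum(
            1 for s in target_seqs.values() if scan_pwm(s, pwm, score_fraction)
        )
        b_with = sum(
            1 for s in background_seqs.values() if scan_pwm(s, pwm, score_fraction)
        )
        table = [[t_with, n_t - t_with], [b_with, n_b - b_with]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "targets_with_hit": t_with,
                "background_with_hit": b_with,
                "target_fraction": t_with / n_t if n_t else 0.0,
                "background_fraction": b_with / n_b if n_b else 0.0,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["hub"] = (out["q"] < alpha) & (
        out["target_fraction"] > out["background_fraction"]
    )
    out = out.sort_values(["q", "p", "motif_id"], kind="mergesort").reset_index(
        drop=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def build_network(
    hubs: list[PWM],
    gene_loci: dict[str, list[str]],
    expression: pd.DataFrame,
    score_fraction: float = 0.8,
) -> nx.DiGraph:
    """Wire TF→gene edges by scanning hub PWMs over each gene's loci.

    An edge exists when the hub's PWM hits at least one of the gene's
    locus sequences; the edge carries the total hit count. Gene nodes are
    annotated up/down from the expression log2 fold change. Genes missing
    from ``gene_loci`` are skipped.
    """
    net = nx.DiGraph()
    for pwm in hubs:
        net.add_node(pwm.motif_id, kind="tf")
    for gene, seqs in gene_loci.items():
        if gene not in expression.index:
            continue
        direction = "up" if expression.loc[gene, "log2fc"] >= 0 else "down"
        for pwm in hubs:
            n_hits = count_hits(seqs, pwm, score_fraction)
            if n_hits > 0:
                if gene not in net:
                    net.add_node(gene, kind="gene", direction=direction)
                net.add_edge(pwm.motif_id, gene, hits=n_hits)
    return net


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erickson: treat letters as vertices and adjacent pairs as
    directed edges, sample a uniform arborescence of terminal edges toward
    the last letter, shuffle the remaining out-edges per vertex, and read
    off the Eulerian walk from the first letter.
    """
    if len(sequence) < 3:
        return sequence
    seq = sequence.upper()
    vertices = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    non_terminal = [v for v in vertices if v != last and edges[v]]
    while True:
        finals = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
        # accept iff every non-terminal vertex reaches `last` via final edges
        ok = True
        for v in non_terminal:
            cur, hops = v, 0
            while cur != last and hops <= len(vertices):
                cur = finals.get(cur, last)
                hops += 1
            if cur != last:
                ok = False
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in finals:
            rest.remove(finals[v])
        rng.shuffle(rest)
        if v in finals:
            rest.append(finals[v])
        shuffled[v] = rest

    out = [seq[0]]
    cur = seq[0]
    cursor = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][cursor[cur]]
        cursor[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def permutation_edge_test(
    locus_seqs: list[str],
    pwm: PWM,
    n_permutations: int = 1000,
    seed: int = 0,
    score_fraction: float = 0.8,
) -> tuple[int, float]:
    """Permutation p-value for a TF→gene edge.

    The null rescans dinucleotide-preserving shuffles of each locus
    sequence; p = (1 + #{permutations with hit count ≥ observed}) /
    (1 + n_permutations). Returns (observed hit count, p).
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    observed = count_hits(locus_seqs, pwm, score_fraction)
    if observed == 0:
        return 0, 1.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = [dinucleotide_shuffle(s, rng) for s in locus_seqs]
        if count_hits(perm, pwm, score_fraction) >= observed:
            exceed += 1
    return observed, (1 + exceed) / (1 + n_permutations)


def annotate_edge_pvalues(
    net: nx.DiGraph,
    gene_loci: dict[str, list[str]],
    pwms: dict[str, PWM],
    n_permutations: int = 1000,
    seed: int = 0,
    score_fraction: float = 0.8,
) -> nx.DiGraph:
    """Attach a permutation p-value to every edge of the network."""
    for i, (tf, gene) in enumerate(sorted(net.edges)):
        _, p = permutation_edge_test(
            gene_loci[gene],
            pwms[tf],
            n_permutations=n_permutations,
            seed=(seed + i) % 2**31,
            score_fraction=score_fraction,
        )
        net.edges[tf, gene]["perm_p"] = p
    return net
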