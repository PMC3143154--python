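"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a pipeline operation by direct enumeration
or textbook arithmetic, sharing no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np


def histogram_bins(positions, bin_width, n_bins):
    """Direct per-read binning by integer division."""
    counts = [0] * n_bins
    for p in positions:
        counts[int(p) // bin_width] += 1
    return counts


def percentile_threshold_bruteforce(nonzero_counts, level):
    """Smallest observed count whose >=-tail fraction is within 1-level."""
    nz = sorted(int(c) for c in nonzero_counts if c > 0)
    n = len(nz)
    for c in sorted(set(nz)):
        tail = sum(1 for x in nz if x >= c) / n
        if tail <= 1 - level:
            return c
    return max(nz)


def call_loci_bruteforce(chip_counts, input_counts, chip_total, input_total,
                         threshold, min_gap, bin_width):
    """Scan bins left to right, merging significant runs by hand.

    Returns (start, end, summit, score) tuples for one chromosome.
    """
    scale = chip_total / input_total
    sig = [i for i, c in enumerate(chip_counts)
           if c >= threshold and c > input_counts[i] * scale]
    loci = []
    run: list[int] = []
    for i in sig + [None]:
        if i is not None and (not run or i - run[-1] <= min_gap):
            run.append(i)
            continue
        if run:
            best = max(run[0] + np.argmax([chip_counts[j] for j in
                                           range(run[0], run[-1] + 1)]), run[0])
            score = sum(chip_counts[j] - input_counts[j] * scale
                        for j in range(run[0], run[-1] + 1))
            loci.append((run[0] * bin_width, (run[-1] + 1) * bin_width,
                         int(best) * bin_width + bin_width // 2, score))
        run = [i] if i is not None else []
    return loci


def nearest_tss_bruteforce(summit, chrom, genes, window):
    """All-pairs nearest TSS; ties toward smaller TSS then gene id."""
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(summit - g.tss)
        key = (d, g.tss, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g)
    if best is None or best[0][0] > window:
        return None
    return best[1]


def optimal_pairing_categories(stim_summits, unstim_summits, threshold):
    """Minimum-total-distance maximum matching, category multiset.

    Exhaustive over permutations; fine for <= 6 loci per side.
    """
    s, u = list(stim_summits), list(unstim_summits)
    k = min(len(s), len(u))
    best = None
    for s_sub in itertools.permutations(range(len(s)), k):
        for u_sub in itertools.combinations(range(len(u)), k):
            total = sum(abs(s[a] - u[b]) for a, b in zip(s_sub, u_sub))
            if best is None or total < best[0]:
                best = (total, s_sub, u_sub)
    cats = []
    _, s_sub, u_sub = best if best else (0, (), ())
    for a, b in zip(s_sub, u_sub):
        cats.append("Basal" if abs(s[a] - u[b]) <= threshold else "Shift")
    cats += ["StimulatedOnly"] * (len(s) - k)
    cats += ["UnstimulatedOnly"] * (len(u) - k)
    return sorted(cats)


def greedy_pairing_categories(stim_summits, unstim_summits, threshold):
    """Independent greedy nearest-first pairing (re-implementation)."""
    pairs = sorted(
        (abs(a - b), a, b, i, j)
        for i, a in enumerate(stim_summits)
        for j, b in enumerate(unstim_summits)
    )
    used_s, used_u, cats = set(), set(), []
    for d, _, _, i, j in pairs:
        if i in used_s or j in used_u:
            continue
        used_s.add(i)
        used_u.add(j)
        cats.append("Basal" if d <= threshold else "Shift")
    cats += ["StimulatedOnly"] * (len(stim_summits) - len(used_s))
    cats += ["UnstimulatedOnly"] * (len(unstim_summits) - len(used_u))
    return sorted(cats)


def scan_windows_bruteforce(sequence, probs, background, pseudo_already, fraction):
    """Per-window log-odds enumeration on both strands.

    ``probs`` are the already-pseudocounted position probabilities.
    Returns sorted (offset, strand) hit tuples.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = probs.shape[0]
    lod = np.log2(probs / background)
    max_score = lod.max(axis=1).sum()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for off in range(len(sequence) - L + 1):
        window = sequence[off:off + L]
        if any(b not in idx for b in window):
            continue
        fwd = sum(lod[i, idx[b]] for i, b in enumerate(window))
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(lod[i, idx[b]] for i, b in enumerate(rc))
        if fwd >= fraction * max_score:
            hits.append((off, "+"))
        if rev >= fraction * max_score:
            hits.append((off, "-"))
    return sorted(hits)


def average_linkage_bruteforce(data, k):
    """Naive O(n^3) agglomeration with 1 - Pearson distance.

    Average linkage over ORIGINAL pairwise distances; returns a list of
    frozensets of row indices (the k clusters).
    """
    n = data.shape[0]
    corr = np.corrcoef(data)
    dist = 1.0 - corr
    clusters = [frozenset([i]) for i in range(n)]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return clusters


def km_bruteforce(times, events):
    """Hand product-limit estimator: [(time, survival)] at event times.

    Deaths are processed before censorings at tied times.
    """
    order = sorted(zip(times, events))
    distinct = sorted({t for t, e in order if e == 1})
    s = 1.0
    curve = []
    for t in distinct:
        at_risk = sum(1 for ti, _ in order if ti >= t)
        deaths = sum(1 for ti, ei in order if ti == t and ei == 1)
        s *= 1 - deaths / at_risk
        curve.append((t, s))
    return curve


def logrank_bruteforce(times, events, groups):
    """Textbook two-group log-rank: observed-minus-expected chi-square."""
    from scipy import stats

    data = sorted(zip(times, events, groups))
    labels = sorted(set(groups))
    event_times = sorted({t for t, e, _ in data if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n = sum(1 for ti, _, _ in data if ti >= t)
        n1 = sum(1 for ti, _, g in data if ti >= t and g == labels[0])
        d = sum(1 for ti, e, _ in data if ti == t and e == 1)
        d1 = sum(1 for ti, e, g in data if ti == t and e == 1 and g == labels[0])
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var if var > 0 else 0.0
    return stat, float(stats.chi2.sf(stat, df=1))
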