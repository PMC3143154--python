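# Methods

`smadpipe` re-implements, as one tested pipeline, an integrative analysis of
TGFβ-induced SMAD4 occupancy: ChIP-seq peak calling, classification of
binding-pattern changes between stimulated and unstimulated conditions,
integration with differential expression, motif-based regulatory-network
inference, and survival-signature selection in a patient cohort. Every
stage runs on synthetic data with planted ground truth, so the pipeline's
operating characteristics are measurable without any external download.

## Peak calling

Reads are single-end start positions; strand is ignored (no fragment-shift
model). Starts are counted into fixed 300 nt bins (a read at position *s*
falls in bin ⌊s/300⌋). The enrichment threshold at an acceptance level
*q* (default 0.996) is the smallest observed nonzero bin count *c* such
that the fraction of nonzero bins with count ≥ *c* is at most 1 − *q*.
Zero bins are excluded because the genome is mostly empty; including them
would let any nonzero count pass. For a constant track no observed count
satisfies the definition and the maximum observed count is returned. A bin
is called significant when it reaches the threshold **and** exceeds the
input-control count scaled by the library-size ratio (chip total / input
total). Significant bins whose indices differ by at most `min_gap`
(default 1, i.e. adjacent) merge into one locus; the summit is the center
of the maximum-count bin (leftmost on ties) and the score is the summed
chip count minus the summed scaled-input count. Coordinates are 0-based
half-open throughout, including BED export.

The FDR at each level is estimated by placing an equal number of reads
uniformly over the genome, binning them identically, and calling them with
the chip-derived thresholds against the same input; FDR = simulated locus
count / observed locus count, clipped to 1.

**A structural property worth knowing.** The percentile rule calls a fixed
share (≈ 1 − *q*) of nonzero bins whenever the count distribution is
dominated by background. Low true-positive rates therefore cannot coexist
with a low false discovery proportion at a loose level: the planted signal
must occupy most of the call budget for the empirical FDR to be small.
The bundled recovery design is built accordingly: a 2 × 6 Mb genome at
0.01 reads/bp (λ = 3 reads/bin) carries 140 planted peaks of width 300 at
15× enrichment with summits placed on bin centers, so each planted peak
occupies a single analysis bin (≈ 45 reads) and exact ground-truth
bookkeeping is possible. At the 0.996 level the caller admits ≈ 0.4% of
≈ 38,000 nonzero bins (≈ 152); 140 of those are planted, capping false
calls near 12, which gives recall 1 and a true FDR ≤ ~0.08 by
construction. A Poisson tail calculation (λ = 3: P(X ≥ 11) ≈ 2.9 × 10⁻⁴,
P(X ≥ 12) ≈ 7.1 × 10⁻⁵) puts the realized threshold at 11–12 and the
expected false count near 3–12, consistent with what the pipeline
measures.

## Locus annotation and binding patterns

Each locus is assigned to the gene whose TSS is nearest its summit, if
that distance is within ±100 kb; the distance is signed in gene
orientation (negative = upstream), and the promoter flag marks |distance|
≤ 8 kb. The summit is the single anchor for both gene assignment and
inter-locus distances — a deterministic point that avoids ambiguity about
peak boundaries. A locus belongs to at most one gene; ties in distance
break toward the smaller TSS coordinate, then the smaller gene id.
Assigned-fraction and promoter-fraction percentages are reported over the
total locus count.

Between conditions, the gene-assigned loci of each gene are paired
greedily nearest-first by summit distance (ties toward the leftmost
stimulated summit). Pairs within 1 kb are **Basal**, beyond 1 kb
**Shift**; unpaired loci are **Stimulated Only** / **Unstimulated Only**.
Every gene-assigned locus lands in exactly one call, so category counts
partition each condition's loci, and the Basal/Shift pair counts are
identical from either condition's perspective. Greedy pairing is not
guaranteed to minimize total pair distance on adversarial layouts where
distances straddle the 1 kb cut; on realistic layouts (summits spread over
±100 kb) it coincides with the exhaustive minimum-distance matching, which
the tests verify. Reported percentages round half-up to one decimal.

## Differential expression and integration

Per gene, a two-sided equal-variance Student t-test compares the
triplicate groups of a log2-scale matrix; log2 FC = mean(stimulated) −
mean(unstimulated). The DE flag is deliberately liberal — |log2 FC| > 0.5
and p < 0.10 — with a stricter p < 0.05 variant; no multiple-testing
correction enters the call (a Benjamini–Hochberg column is emitted for
information). Degenerate zero-variance genes get p = 1 when the group
means agree and p = 0 otherwise. DE calls are intersected with the set of
genes carrying stimulated-condition binding loci to produce the
DE-only / locus-only / DE-and-locus partition.

## Network inference

PWMs carry per-position probabilities (pseudocount 0.01 per cell before
normalization) and are scored as log2 odds against the background
composition. A scan reports windows on either strand scoring at least
`score_fraction` (default 0.80) of the maximum attainable log-odds;
windows containing N are skipped. Hub-TF discovery is a screen over the
PWM library: per motif, a one-sided Fisher exact test on the 2 × 2 table
of sequences with/without a hit in targets versus length- and size-matched
random background, Benjamini–Hochberg corrected; hubs must be significant
at α = 0.05 **and** more frequent in targets. This formulation keeps the
screen's defining property — motifs equally enriched in random sequence
sets are eliminated. Edges connect a hub to every
DE-and-locus gene with ≥ 1 hit in ≥ 1 of its locus sequences; gene nodes
carry the up/down direction of their expression change. Each edge's
permutation p-value rescans dinucleotide-preserving shuffles
(Altschul–Erickson, uniform over the shuffle class) of the gene's locus
sequences: p = (1 + #{permutations ≥ observed}) / (1 + N), so p ≥
1/(N + 1). The permutation unit is the sequence; the default N is 199 in
the bundled pipeline (1,000 via the CLI flag where tighter p-values are
wanted).

## Survival signatures

Cohort expression rows are mean-centered; genes and patients are
clustered agglomeratively with distance 1 − Pearson correlation and
average linkage, cutting the tree to exactly k groups (k = 4 for both
axes by default; both are exposed as parameters since the grouping counts
are an empirical choice, not a derivable one). For each gene group the
patients are re-clustered on that group's sub-matrix and every pair of
patient groups is compared by the standard two-group log-rank chi-square
(1 df) on Kaplan–Meier survival; patients without complete survival
information are dropped first. The gene group with the smallest pairwise
p is reported as the signature. That minimum is a selection statistic
over 4 gene groups × 6 patient-group pairs and is **not** corrected for
selection; the result object carries this caveat. A Cox
partial-likelihood-ratio variant of the two-group test is available as an
option. A size-matched random gene set disjoint from the signature is
rerun through the same patient clustering + best-pair log-rank as a
control. KM ties process deaths before censorings; the median is the
smallest time with survival ≤ 0.5 (undefined when never reached).

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their seeds and reproduce the
study-like structure end to end:

- **Reads**: uniform background at a configurable density (default 0.01
  reads/bp) multiplied inside planted peak windows by the enrichment
  factor; single-end, 36 nt, start+strand only. No mappability structure,
  duplicate artifacts, fragment-length distribution, or sequencing error.
- **Binding layout**: the pattern design plants 18 genes per category on
  a 2 × 3 Mb, 80-gene genome — Basal pairs offset by 300 nt, Shift pairs
  by 2,400 nt, plus condition-specific peaks — all summits on bin centers
  within ±25 kb of their gene's TSS.
- **Expression**: Gaussian log2 intensities, triplicates per condition,
  planted signed effects of |log2 FC| = 2 at noise SD 0.3 on 24
  peak-bearing and 80 unbound genes of a 400-gene universe.
- **Sequences**: i.i.d. nucleotides (default uniform composition,
  configurable) with one PWM-sampled motif instance planted in a chosen
  fraction of loci at a random offset/strand. Library PWMs hold their
  consensus base at probability 0.95 per position so that PWM-sampled
  instances score above the 0.8 scan threshold; flatter motifs emit
  planted instances the scanner cannot distinguish from background, which
  defeats the purpose of planting.
- **Cohort**: 60 patients, 60 genes, a 12-gene prognostic group shifted
  by 3 noise-SDs in a random half of patients; exponential survival with
  baseline hazard ln 2 / 63 months and hazard ratio 4 for the poor group;
  20% of patients censored independently, uniformly before their event.
  Real cohorts have correlated gene blocks, non-exponential hazards, and
  informative censoring; none of that is modelled.

Passing tests on these fixtures demonstrate that the algorithms do what
they claim under their own assumptions — not that the pipeline's
biological conclusions transfer to any real dataset.

## Problem sizes and numerical choices

The bundled studies are sized to run the full suite in well under a
minute each: 12 Mb / ~126 k reads for peak-recovery, 6 Mb / ~62 k reads
per condition for the pattern study, 400 genes × 6 arrays, ~28 locus
sequences of 300–600 nt, and a 60-patient cohort. Null calibrations use
400–500 replicates (log-rank uniformity, DE type-I rate) and 200 seeds ×
199 permutations (permutation-p uniformity, on a deliberately weak 5-mer
PWM at scan fraction 0.55 so observed hit counts vary enough for the
discrete add-one estimator to approximate a continuous uniform).

All randomness flows from a single seed: per-stage seeds derive from
CRC-32 hashes of the stage name, so stages are reproducible in isolation
and the end-to-end report is byte-identical across runs. Percentages
round half-up to one decimal. The FDR table clips estimates at 1.
Thresholds are non-decreasing in the acceptance level by construction.

## Known limitations

- The percentile threshold interpretation (over nonzero bins, chip-only
  counts) is one concrete reading of a one-line description of the
  original caller; the exact internals of that tool (its percentile grid,
  and whether thresholds derive from chip or chip-minus-input counts) are
  not published alongside it.
- Hub-TF discovery here is an enrichment screen with the same observable
  contract as the original machine-learning pipeline (discriminative
  motifs, background-enriched motifs eliminated), not a re-implementation
  of its classifier internals.
- The signature-selection p-value is uncorrected by design, mirroring the
  analysis it reproduces; treat it as a ranking score.
- Probe-to-gene mapping, array normalization, GO enrichment, and
  visualization are out of scope; inputs are assumed normalized and
  identifier-consistent.
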