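# smadpipe

An integrative regulatory-genomics pipeline for TGFβ/SMAD4 ChIP-seq
studies: percentile-scoring peak calling with simulated-read FDR,
four-way classification of binding-pattern changes between stimulated and
unstimulated conditions, integration with microarray differential
expression, PWM-based hub-TF network inference with permutation-tested
edges, and clustering-based survival-signature selection in patient
cohorts. A synthetic-data module generates every input with planted
ground truth, so the whole analysis is reproducible and testable offline.

It is written for computational biologists who want the individual
operations (binning, thresholding, locus↔gene assignment, motif scanning,
log-rank testing, …) as a library, and for analysts who want the staged
analysis as runnable scripts.

## The analysis in brief

1. **Peak calling.** Read starts are binned at 300 nt. The enrichment
   threshold at acceptance level *q* (default 0.996) is the smallest
   nonzero bin count whose ≥-tail holds at most 1 − *q* of nonzero bins.
   Significant bins must also beat the depth-scaled input control;
   adjacent significant bins merge into loci (summit = max bin center,
   score = chip − scaled input). FDR(*q*) = loci called on uniformly
   simulated reads / loci called on the data.
2. **Binding patterns.** Loci are assigned to the nearest TSS within
   ±100 kb (±8 kb flags the promoter). Per gene, loci of the two
   conditions pair greedily nearest-first: pairs ≤ 1 kb apart are
   *Basal*, > 1 kb *Shift*; unpaired loci are *Stimulated Only* /
   *Unstimulated Only*.
3. **Expression integration.** Per-gene equal-variance t-tests over
   triplicates; DE ⇔ |log2 FC| > 0.5 and p < 0.10 (strict variant
   p < 0.05); DE calls intersect the locus-bearing genes.
4. **Networks.** PWMs score log2-odds on both strands at ≥ 0.8 of the
   maximum; hub TFs are motifs enriched in target locus sequences over
   matched random background (one-sided Fisher, BH at 0.05) — motifs that
   random sets also contain are eliminated. Hub→gene edges get
   permutation p-values from dinucleotide-preserving shuffles.
5. **Survival.** Mean-centered cohort expression is double-clustered
   (1 − Pearson, average linkage; 4 gene groups × 4 patient groups);
   gene groups are ranked by their best pairwise Kaplan–Meier log-rank
   contrast, with a size-matched random gene set as control.

See `docs/methods.md` for assumptions, parameter defaults, and
limitations.

## Worked example

Run the staged analysis (each script reads its predecessor's output under
`results/`):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_call_peaks.py
python analysis/03_classify_binding_patterns.py
python analysis/04_integrate_expression.py
python analysis/05_infer_network.py
python analysis/06_survival_signature.py
```

`02_call_peaks.py` prints the caller's operating characteristics on the
recovery design (140 planted 15× peaks on 12 Mb):

```
recovery design: 146 loci called at level 0.996; recall 1.000,
empirical FDR 0.041, simulated-read FDR estimate 0.021
```

— all planted peaks were recovered, 4.1% of called loci were background
fluctuations, and the simulated-read estimator put the FDR at 2.1%.
`03_classify_binding_patterns.py` then classifies the two-condition
study:

```
      category  count  total  percent
StimulatedOnly     27     72     37.5
         Shift     27     72     37.5
         Basal     18     72     25.0
planted category recovered for 65/72 genes (90.3%)
```

(The planted design has 18 genes per category; false-positive loci
inflate Shift/Only counts, which is why recovery is reported against the
planted truth.) `06_survival_signature.py` ends with:

```
selected gene group 1 with 23 genes (best pairwise log-rank p = 4.02e-06)
planted prognostic genes inside the selected group: 12/12
patient group 1: n=26, median survival 17.3 months
patient group 3: n=29, median survival 114.6 months
random 23-gene control: best pairwise log-rank p = 0.3946
```

— the scan found the planted 12-gene prognostic group (plus 11
correlated passengers), separated a poor-survival from a good-survival
patient group, and a random same-size gene set showed no comparable
separation.

The same stages are callable as a CLI (`smadpipe simulate|callpeaks|
classify|de|network|survival|all`) or as one orchestrated run:

```sh
smadpipe all --seed 1 --outdir results/pipeline
```

which writes per-stage tables and a deterministic `report.json`.

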