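"""Assign called loci to genes and classify the four binding patterns.

Consumes the BED files from 02_call_peaks.py, writes TSS-distance
histograms, the per-gene pattern table, and per-condition category
percentages to results/03_patterns/, and reports how often the planted
category was recovered.
"""

from pathlib import Path

import pandas as pd

from smadpipe import io as pio
from smadpipe.annotation import (
    annotation_summary,
    assign_to_genes,
    classify_patterns,
    pattern_summary,
    tss_distance_histogram,
)
from smadpipe.config import PipelineConfig
from smadpipe.study import pattern_design

IN = Path("results/02_peaks")
OUT = Path("results/03_patterns")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    design = pattern_design()
    genes = list(design.genome.genes)

    assignments = {}
    for condition in ("stimulated", "unstimulated"):
        loci = pio.read_loci_bed(IN / f"loci_{condition}.bed",
                                 condition=condition)
        asn = assign_to_genes(loci, genes, cfg.gene_window,
                              cfg.promoter_window)
        assignments[condition] = asn
        tss_distance_histogram(asn).to_csv(
            OUT / f"tss_hist_{condition}.tsv", sep="\t", index=False)
        s = annotation_summary(asn)
        print(f"{condition}: {s['assigned']}/{s['total_loci']} loci within "
              f"±{cfg.gene_window//1000} kb of a TSS ({s['assigned_pct']}%), "
              f"{s['promoter_pct']}% in the ±{cfg.promoter_window//1000} kb promoter window")

    calls = classify_patterns(assignments["stimulated"],
                              assignments["unstimulated"],
                              cfg.shift_threshold)
    rows = [(c.gene_id, c.category,
             c.stim_locus.summit if c.stim_locus else "",
             c.unstim_locus.summit if c.unstim_locus else "",
             c.distance if c.distance is not None else "")
            for c in calls]
    pd.DataFrame(rows, columns=["gene_id", "category", "stim_summit",
                                "unstim_summit", "distance"]).to_csv(
        OUT / "pattern_calls.tsv", sep="\t", index=False)

    for condition in ("stimulated", "unstimulated"):
        summary = pattern_summary(calls, condition)
        summary.to_csv(OUT / f"summary_{condition}.tsv", sep="\t", index=False)
        print(f"-- {condition} --")
        print(summary.to_string(index=False))

    truth = {g: c for g, c in design.truth_category.items() if c != "None"}
    called = {}
    for c in calls:
        if c.gene_id not in called or c.category in ("Basal", "Shift"):
            called[c.gene_id] = c.category
    hits = sum(1 for g, cat in truth.items() if called.get(g) == cat)
    print(f"planted category recovered for {hits}/{len(truth)} genes "
          f"({100 * hits / len(truth):.1f}%)")


if __name__ == "__main__":
    main()
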