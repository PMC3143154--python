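"""Differential expression and overlap with binding-target genes.

Reads the expression matrix from 01 and the stimulated-condition pattern
calls from 03, calls DE at the liberal (p < 0.10) and strict (p < 0.05)
thresholds with |log2 FC| > 0.5, and partitions genes into DE-only,
locus-only and DE-and-locus sets. Tables land in results/04_expression/.
"""

import json
from pathlib import Path

import pandas as pd

from smadpipe import io as pio
from smadpipe.config import PipelineConfig
from smadpipe.expression import differential_expression, integrate, strict_variant
from smadpipe.study import pattern_design

OUT = Path("results/04_expression")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    design = pattern_design()

    matrix = pio.read_matrix_tsv("results/01_inputs/expression.tsv")
    labels = ["unstimulated"] * 3 + ["stimulated"] * 3
    results = differential_expression(matrix, labels, cfg.fc_threshold,
                                      cfg.p_threshold)
    results.to_csv(OUT / "de_results.tsv", sep="\t")

    patterns = pd.read_csv("results/03_patterns/pattern_calls.tsv", sep="\t")
    stim_bound = set(
        patterns.loc[patterns.category.isin(
            ["Basal", "Shift", "StimulatedOnly"]), "gene_id"])
    liberal = integrate(results, stim_bound)
    strict = strict_variant(results, stim_bound, cfg.p_threshold_strict)
    summary = {"liberal": liberal.summary(), "strict": strict.summary()}
    (OUT / "integration.json").write_text(json.dumps(summary, indent=2) + "\n")

    n_de = int(results.de.sum())
    print(f"{n_de} DE genes of {len(results)} at |log2FC| > "
          f"{cfg.fc_threshold}, p < {cfg.p_threshold}")
    print(f"liberal partition: {summary['liberal']}")
    print(f"strict partition:  {summary['strict']}")

    planted = set(design.de_effects)
    called = set(results.index[results.de])
    print(f"planted DE recovered: {len(planted & called)}/{len(planted)}")
    pd.Series(sorted(liberal.de_and_locus)).to_csv(
        OUT / "de_and_locus_genes.txt", index=False, header=False)


if __name__ == "__main__":
    main()
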