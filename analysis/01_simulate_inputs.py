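"""Generate the synthetic study inputs and write them as standard files.

Writes the gene annotation, mapped-read BED files for the stimulated,
unstimulated and input samples, the triplicate expression matrix, the PWM
library, and the patient cohort under results/01_inputs/.
"""

from pathlib import Path

from smadpipe import io as pio
from smadpipe.config import PipelineConfig
from smadpipe.study import cohort_spec, expression_genome, pattern_design
from smadpipe.synthetic import (
    condition_peaks,
    generate_cohort,
    generate_expression,
    generate_pwm_library,
    generate_reads,
)

OUT = Path("results/01_inputs")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    design = pattern_design()

    pio.write_genes_tsv(design.genome.genes, OUT / "genes.tsv")
    for condition in ("stimulated", "unstimulated"):
        reads = generate_reads(
            design.genome, condition_peaks(design.peaks, condition),
            design.background_density,
            seed=cfg.stage_seed(f"reads:{condition}"), sample=condition,
        )
        pio.write_reads_bed(reads, OUT / f"reads_{condition}.bed")
        print(f"{condition}: {reads.total:,} reads")
    ctrl = generate_reads(design.genome, [], design.background_density,
                          seed=cfg.stage_seed("input"), sample="input")
    pio.write_reads_bed(ctrl, OUT / "reads_input.bed")
    print(f"input: {ctrl.total:,} reads")

    expr = generate_expression(expression_genome(design), design.de_effects,
                               noise_sd=0.3, n_replicates=3,
                               seed=cfg.stage_seed("expression"))
    pio.write_matrix_tsv(expr, OUT / "expression.tsv")
    print(f"expression: {expr.shape[0]} genes x {expr.shape[1]} samples, "
          f"{len(design.de_effects)} planted DE")

    pwms = generate_pwm_library(10, seed=cfg.stage_seed("pwm_library"))
    pio.write_jaspar(pwms, OUT / "pwms.jaspar")

    cohort = generate_cohort(cohort_spec(seed=cfg.stage_seed("cohort")))
    pio.write_matrix_tsv(cohort.matrix, OUT / "cohort_matrix.tsv")
    pio.write_survival_tsv(cohort.time, cohort.event, OUT / "cohort_survival.tsv")
    print(f"cohort: {cohort.matrix.shape[1]} patients, "
          f"{len(cohort.truth['prognostic_genes'])} planted prognostic genes")


if __name__ == "__main__":
    main()
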