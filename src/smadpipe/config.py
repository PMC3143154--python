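"""Pipeline configuration: one flat key=value file holds every threshold.

Defaults are the analysis constants used throughout: 300 nt bins, 0.996
acceptance level, ±100 kb gene window, ±8 kb promoter window, 1 kb shift
threshold, 0.5 log2 fold-change and 0.1 / 0.05 p-value cuts, 0.8 PWM score
fraction, and four gene / patient cluster groups.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % 2**31


@dataclass
class PipelineConfig:
    bin_width: int = 300
    acceptance_level: float = 0.996
    min_gap: int = 1
    gene_window: int = 100_000
    promoter_window: int = 8_000
    shift_threshold: int = 1_000
    fc_threshold: float = 0.5
    p_threshold: float = 0.1
    p_threshold_strict: float = 0.05
    score_fraction: float = 0.8
    hub_alpha: float = 0.05
    n_permutations: int = 199
    k_gene: int = 4
    k_patient: int = 4
    seed: int = 1
    outdir: str = "results/pipeline"

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not 0 < self.acceptance_level < 1:
            raise ValueError("acceptance_level must be in (0, 1)")
        for name in ("p_threshold", "p_threshold_strict", "hub_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.score_fraction <= 1:
            raise ValueError("score_fraction must be in (0, 1]")
        for name in ("gene_window", "promoter_window", "shift_threshold",
                     "n_permutations", "k_gene", "k_patient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kind = types[key]
            if kind == "int":
                kwargs[key] = int(value)
            elif kind == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
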