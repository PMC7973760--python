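"""Pipeline configuration with lossless JSON round-tripping."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, Optional


@dataclass
class PipelineConfig:
    # input paths (stages run only when their inputs are present)
    genome_fasta: Optional[str] = None
    alignments: Optional[str] = None      # interval TSV, or directory of SAM files
    vcf: Optional[str] = None
    pool_map: Optional[str] = None
    out_dir: str = "ddrad_out"

    # digestion / design
    enzymes: str = "PstI,MboI"
    enzyme_table: Optional[str] = None    # TSV override: name, motif, cut_offset, meth
    window_min: int = 300
    window_max: int = 400
    yield_bp_per_sample: float = 250e6

    # coverage
    min_mapq_exclusive: int = 3
    depth_min: int = 1
    bin_size: int = 1000
    correlation_method: str = "spearman"
    k_per_pool: int = 3

    # variants
    max_missing: float = 0.05
    min_maf: float = 0.01
    density_window: int = 1000
    flank: int = 50

    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing <= 1 or not 0 <= self.min_maf <= 1:
            raise ValueError("variant thresholds must be in [0, 1]")
        if self.window_min > self.window_max or self.window_min < 0:
            raise ValueError("invalid size window")
        if self.bin_size <= 0 or self.density_window <= 0:
            raise ValueError("window/bin sizes must be positive")
        if self.depth_min < 1:
            raise ValueError("depth_min must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())
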