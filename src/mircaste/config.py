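"""Declarative pipeline configuration.

Every analysis parameter has the standard default of the method (adapter
and HD trimming, 16 nt length floor, k=1 genome / k=2 mature-miRNA
mismatch bounds, 4,000,000 normalization total, OFC offset 20 and
threshold 1, abundance floor 200).  Configs round-trip through YAML
unchanged, and unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from mircaste.preprocess import DEFAULT_ADAPTER


@dataclass
class PipelineConfig:
    # inputs
    genome_fasta: str = ""
    mirna_fasta: str = ""
    sample_sheet: str = ""
    output_dir: str = "runs"
    run_name: str = ""  # empty -> timestamped directory name
    # preprocessing
    adapter: str = DEFAULT_ADAPTER
    hd_length: int = 4
    min_overlap: int = 7
    l_min: int = 16
    # alignment
    k_genome: int = 1
    k_mirbase: int = 2
    # normalization; "auto" selects the rounded-up median of accepted totals
    normalization_total: int | str = 4_000_000
    # library screen
    score_threshold: float = 0.8
    exclude_libraries: list[str] = field(default_factory=list)
    # differential expression
    offset: float = 20.0
    ofc_threshold: float = 1.0
    abundance_floor: float = 200.0
    ofc_variant: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalization_total != "auto":
            if int(self.normalization_total) <= 0:
                raise ValueError("normalization_total must be positive or 'auto'")
            self.normalization_total = int(self.normalization_total)
        if self.ofc_variant not in ("mean", "edge"):
            raise ValueError(f"unknown ofc_variant {self.ofc_variant!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
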