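"""Mapping configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class MappingConfig:
    """Tunable parameters of the haplotype-block scan.

    window_size
        Number of consecutive SNPs per sliding window (stride 1).
    min_group_size
        A candidate block is kept only if its largest haplotype group has
        at least this many strains.
    flank_bp
        Flank added on both sides of a gene interval when collecting
        overlapping blocks.
    p_floor
        Lower clamp for p-values so -log10(p) stays finite in degenerate
        perfect-separation blocks.
    """

    window_size: int = 3
    min_group_size: int = 2
    flank_bp: int = 10_000
    p_floor: float = 1e-300

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not (0 < self.p_floor < 1):
            raise ValueError("p_floor must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MappingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
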