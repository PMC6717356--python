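"""Run configuration: every tunable in one serializable object.

Defaults follow the published workflow where it states them: e-value cutoff
1e-5, 300-nt minimum hit, 270-codon intact rule, 10,000 coalescent /
permutation replicates, FDR alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # mining
    evalue_cutoff: float = 1e-5
    min_hit_nt: int = 300
    merge_dist: int = 50
    extension_window_nt: int = 3000
    min_codons: int = 270  # coding codons, stop excluded
    gap_min_n: int = 10
    tm_window: int = 19
    tm_threshold: float = 1.6
    require_tm: bool = True
    # population genetics
    coalescent_reps: int = 10000
    permutation_reps: int = 10000
    fdr_alpha: float = 0.05
    fdr_family: str = "pooled"  # pooled | per_locus
    # randomness
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
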