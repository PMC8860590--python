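"""Pipeline configuration: every stage threshold in one round-trippable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Defaults mirror the thresholds used throughout the package: BlastP-style
    filtering at E < 1e-4 and coverage > 60% under BLOSUM-45, tandem-repeat
    scoring 2/7/7 with reporting threshold 50, sigma-70 boxes with a 15-19 nt
    spacer, and titrations at 15 C (288.15 K)."""

    evalue_max: float = 1e-4
    coverage_min: float = 0.6
    matrix: str = "BLOSUM45"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    n_shuffles: int = 50
    cluster_threshold: float = 0.90
    repeat_match: int = 2
    repeat_mismatch: int = 7
    repeat_indel: int = 7
    repeat_min_score: int = 50
    promoter_max_mismatches: int = 2
    spacer_min: int = 15
    spacer_max: int = 19
    terminator_min_stem: int = 4
    terminator_loop_min: int = 3
    terminator_loop_max: int = 8
    orf_min_codons: int = 30
    pseudoknot_min_bp: int = 3
    score_gc: int = 3
    score_au: int = 2
    score_gu: int = 1
    motif_pattern: str = "GAAAU"
    motif_cut: int = 3
    flank_up: int = 1000
    flank_down: int = 1000
    temperature_K: float = 288.15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def as_dict(self) -> dict:
        return asdict(self)
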