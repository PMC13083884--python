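"""Pipeline configuration: every tunable threshold in one place, with the
published defaults, YAML serialization and validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # gene categorization
    category_fold: float = 4.0
    category_flat: float = 2.0
    abundance_eps: float = 0.01
    control_max_fc: float = 2.0
    ercc_total_molecules: int = 623_291_645
    # peak calling / consensus
    peak_fdr: float = 0.01  # Results preset; Methods preset 0.1 also valid
    peak_min_length: int = 150
    peak_window: int = 200
    peak_merge_gap: int = 100
    consensus_half_width: int = 2000
    consensus_min_reps: int = 2
    # pausing
    promoter_fraction: float = 0.05
    body_fraction: float = 0.30
    ser5p_pause_start: int = 31
    ser5p_pause_end: int = 60
    # occupancy
    promoter_half_widths: tuple = (200, 500, 2000)
    signal_eps: float = 0.01
    cuttag_scale_constant: int = 10_000
    # motif
    motif_flank: int = 75
    motif_fdr: float = 0.05
    # single cell
    qc_min_genes: int = 500
    qc_max_mito_frac: float = 0.05
    qc_min_fragments: int = 1000
    qc_min_tss_score: float = 4.0
    tn5_shift_plus: int = 4
    tn5_shift_minus: int = 5
    diff_fc_up: float = 2.0
    diff_fc_down: float = 0.5
    diff_fdr: float = 0.05
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.peak_fdr < 1:
            raise ValueError("peak_fdr must be in (0, 1)")
        if not 0 < self.promoter_fraction <= 1:
            raise ValueError("promoter_fraction must be in (0, 1]")
        if not 0 <= self.body_fraction < 1:
            raise ValueError("body_fraction must be in [0, 1)")
        if self.category_fold <= self.category_flat:
            raise ValueError("category_fold must exceed category_flat")
        if self.consensus_min_reps < 1:
            raise ValueError("consensus_min_reps must be >= 1")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["promoter_half_widths"] = list(self.promoter_half_widths)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "promoter_half_widths" in data:
            data["promoter_half_widths"] = tuple(data["promoter_half_widths"])
        return cls(**data)
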