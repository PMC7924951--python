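"""Central configuration: every analysis threshold appears exactly once here."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .intervals import ValidationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their standard defaults.

    ChIP peaks: caller q-value < ``q_max`` and fold enrichment > ``fe_min``
    in every replicate; the strong subset additionally needs
    FE > ``fe_strong``.  Peak-center matching and merging use
    ``overlap_bp``.  ATAC reproducibility needs FE > ``atac_fe_min`` in
    all ``atac_n_replicates``; DAR counting windows span
    ±``dar_window`` bp.  DE genes need TPM > ``tpm_min``, fold change >
    ``fc_min`` and NB p < ``p_max``; DARs need BH-adjusted p <
    ``dar_padj_max``.  Loop matching uses ``loop_tol``; the connectivity
    chain uses ``peak_anchor_tol`` and ``tss_anchor_tol``.
    """

    q_max: float = 1e-4
    fe_min: float = 10.0
    fe_strong: float = 20.0
    overlap_bp: float = 150.0
    atac_fe_min: float = 3.0
    atac_n_replicates: int = 3
    dar_window: int = 500
    dar_padj_max: float = 0.05
    tpm_min: float = 5.0
    fc_min: float = 3.0
    p_max: float = 0.05
    loop_tol: float = 10_000.0
    peak_anchor_tol: float = 5_000.0
    tss_anchor_tol: float = 15_000.0
    strong_only: bool = True  # classify on the FE>fe_strong subset
    seed: int = 0
    output_dir: str = "chirswitch_out"
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "q_max", "fe_min", "fe_strong", "overlap_bp", "atac_fe_min",
            "dar_window", "dar_padj_max", "tpm_min", "fc_min", "p_max",
            "loop_tol", "peak_anchor_tol", "tss_anchor_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)
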