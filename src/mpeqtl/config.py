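"""Pipeline configuration: every stage threshold with its standard default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and tuning parameters of every analysis stage.

    Defaults are the study's operating points: expression filter -5
    (mean log2 fpkm), Tukey p < 0.001, transgression envelope of 2
    pooled SDs with a 50-line count threshold, 100 heritability
    permutations at the 0.95 quantile, eQTL FP/TP ratio < 0.01 on a
    0.05 grid, trans-bands of > 100 eQTLs in a 1-Mbp window, GO
    enrichment at p < 1e-5 with term size > 3, and a cross-study call
    threshold of 3.5.
    """

    expression_filter: float = -5.0
    pseudocount: float = 2.0**-10
    tukey_alpha: float = 0.001
    deg_fpr_permutations: int = 10
    transgression_k_sd: float = 2.0
    transgression_count: int = 50
    transgression_fpr_permutations: int = 10
    h2_permutations: int = 100
    h2_quantile: float = 0.95
    eqtl_fpr_ratio: float = 0.01
    eqtl_grid_step: float = 0.05
    eqtl_min_class: int = 5
    eqtl_threshold_override: Optional[float] = None
    trans_band_min_count: int = 100
    window: int = 1_000_000
    go_p: float = 1e-5
    go_min_set: int = 3
    cross_study_threshold: float = 3.5


@dataclass
class PipelineConfig:
    """Inputs, outputs, seed, stage toggles, and analysis thresholds."""

    outdir: str = "results"
    seed: int = 0
    genotypes: Optional[str] = None
    expression: Optional[str] = None
    samples: Optional[str] = None
    annotation: Optional[str] = None
    go_associations: Optional[str] = None
    simulate: Optional[dict[str, Any]] = None  # SimConfig overrides; None -> read inputs
    run_parental: bool = True
    run_heritability: bool = True
    run_eqtl: bool = True
    run_trans_bands: bool = True
    write_profiles: bool = False
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        analysis = AnalysisConfig(**raw.pop("analysis", {}))
        return cls(analysis=analysis, **raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
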