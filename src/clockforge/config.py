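"""Schema-validated pipeline configuration.

A config file (YAML or JSON) is validated strictly before any stage runs:
unknown keys are rejected by name, all violations are reported together, and
omitted keys fall back to documented defaults.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PanelSection(_Strict):
    min_markers_per_sample: int = Field(4, ge=0)
    min_presence_fraction: float = Field(0.30, ge=0.0, le=1.0)


class PreprocessSection(_Strict):
    outlier_fraction: float = Field(0.005, ge=0.0, lt=0.5)
    impute_floor: float = 0.0
    scaler: str = "minmax"
    fit_scope: str = "train_only"
    two_sided: bool = False

    @field_validator("fit_scope")
    @classmethod
    def _scope(cls, v):
        if v not in ("train_only", "full_table"):
            raise ValueError("fit_scope must be 'train_only' or 'full_table'")
        return v


class ClockSection(_Strict):
    hidden_sizes: tuple[int, ...] = (1000, 100)
    learning_rate: float = Field(5e-3, ge=0)
    weight_decay: float = Field(1e-4, ge=0)
    batch_size: int = Field(2048, ge=1)
    max_steps: int = Field(2000, ge=1)
    eval_interval: int = Field(10, ge=1)
    checkpoint: str = "best_val"
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)

    @model_validator(mode="after")
    def _fractions_sum(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        return self


class CorrectionSection(_Strict):
    mode: str = "median_kernel"  # median_kernel | logistic | quantile | subsample
    alpha: float = Field(0.001, gt=0)
    kernel: str = "additive_chi2"
    min_count: int = Field(10, ge=1)

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        allowed = ("median_kernel", "logistic", "quantile", "subsample")
        if v not in allowed:
            raise ValueError(f"mode must be one of {allowed}")
        return v


class ExplainSection(_Strict):
    window: float = Field(2.0, gt=0)
    min_background: int = Field(50, ge=2)
    n_permutations: int = Field(16, ge=1)
    n_samples: int = Field(20, ge=1)


class ReductionSection(_Strict):
    enabled: bool = False
    correlation_threshold: float = Field(0.5, ge=0.0, le=1.0)
    elimination_schedule: tuple[int, ...] = (5, 5)
    cost_exclusions: tuple[str, ...] = ()
    target_size: int = Field(7, ge=1)
    n_explain: int = Field(60, ge=1)


class SimulateSection(_Strict):
    n_subjects: int = Field(4000, ge=10)
    sigma_b: float = Field(5.0, ge=0)
    missing_rate: float = Field(0.22, ge=0.0, le=1.0)
    age_min: float = 20.0
    age_max: float = 80.0


class PipelineConfig(_Strict):
    cohort_path: str | None = None  # None -> simulate
    output_dir: str = "clockforge_run"
    seed: int = 0
    log_level: str = "INFO"
    panel: PanelSection = PanelSection()
    preprocess: PreprocessSection = PreprocessSection()
    clock: ClockSection = ClockSection()
    correction: CorrectionSection = CorrectionSection()
    explain: ExplainSection = ExplainSection()
    reduction: ReductionSection = ReductionSection()
    simulate: SimulateSection = SimulateSection()

    def stage_seed(self, stage: str) -> int:
        """Fan the global seed out to a stable per-stage seed."""
        return zlib.crc32(f"{self.seed}:{stage}".encode()) % (2**31)


def validate_config(path) -> PipelineConfig:
    """Load and strictly validate a YAML/JSON config file.

    All violations are reported together (pydantic collects them); unknown
    keys are named explicitly.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)


def config_digest(config: PipelineConfig) -> str:
    import hashlib

    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
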