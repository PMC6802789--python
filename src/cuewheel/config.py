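"""Validated pipeline configuration (JSON or YAML), with strict schemas.

Unknown keys are rejected everywhere, so typos in a config file fail before
any stage runs. The config hash (sha256 of the canonical JSON, first 12 hex
digits) is stamped into every output file's header comment for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationConfig(_Strict):
    n_subjects: int = 20
    n_blocks: Optional[int] = None          # default: 7 (E1) / 8 (E2)
    practice: bool = True
    seed: int = 0
    counterbalance_arm: Optional[Literal["2->right", "2->left"]] = None  # default: alternate
    params: dict = Field(default_factory=dict)  # GenerativeParams field overrides


class PreprocessConfig(_Strict):
    madm_multiplier: float = 5.0
    cells: Optional[Literal["cue", "soa-cue"]] = None  # default: by experiment


class SamplerConfig(_Strict):
    n_walkers: Optional[int] = None
    n_steps: int = 4000
    n_burn: int = 2000
    thin: int = 8
    seed: Optional[int] = None              # default: simulation seed + 1
    progress: bool = False


class ModelConfig(_Strict):
    method: Literal["bayes", "mle"] = "bayes"
    hierarchical: bool = True
    random_slopes: bool = False
    reference: Optional[str] = None
    priors: dict = Field(default_factory=dict)
    sampler: SamplerConfig = Field(default_factory=SamplerConfig)


class ReportConfig(_Strict):
    hdi_masses: list[float] = Field(default_factory=lambda: [0.95, 0.5])
    out_dir: str = "cuewheel_out"


class PipelineConfig(_Strict):
    experiment: Literal["E1", "E2"] = "E1"
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    preprocessing: PreprocessConfig = Field(default_factory=PreprocessConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    report: ReportConfig = Field(default_factory=ReportConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.model_validate(data or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
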