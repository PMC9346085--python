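"""Pipeline configuration: one YAML file drives every analysis stage.

Each run records the config hash and master seed so outputs are
reproducible and attributable to an exact parameterization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .qc import FilterConfig
from .selection import IhsConfig
from .sfs import FitConfig
from .simulate import ArtifactConfig


@dataclass
class PipelineConfig:
    """All thresholds, window sizes and simulation budgets in one place."""

    seed: int = 1
    filters: FilterConfig = field(default_factory=FilterConfig)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    ihs: IhsConfig = field(default_factory=IhsConfig)
    fitting: FitConfig = field(default_factory=FitConfig)
    fd_window_snvs: int = 25
    fd_step_snvs: int = 10
    fd_top_fraction: float = 0.05
    jackknife_block_bp: int = 1_000_000
    sweep_window_bp: int = 25_000
    sweep_step_bp: int = 12_500
    ihs_threshold: float = 1.5
    roh_min_length_bp: int = 500_000
    fis_bootstraps: int = 1000
    rarefaction_missing_rule: float = 0.2

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("filters", FilterConfig),
            ("artifacts", ArtifactConfig),
            ("ihs", IhsConfig),
            ("fitting", FitConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
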