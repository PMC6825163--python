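"""Run configuration shared by the CLI commands (YAML file + overrides)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .applicability import LAMBDA_A, LAMBDA_B
from .errors import ValidationError
from .fitting import FitOptions
from .io_tensile import ColumnMap

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    raw_dir: str = "raw"
    metadata: str = "metadata.csv"
    out_dir: str = "out"
    columns: ColumnMap = field(default_factory=ColumnMap)
    slope_fraction: float = 0.1
    plateau_window: int = 5
    enforce_stability: bool = True
    enforce_linear_part: bool = True
    nrmse_threshold: float = 0.05
    lambda_a: float = LAMBDA_A
    lambda_b: float = LAMBDA_B
    preconditioning_cycles: int = 2
    seed: int = 0

    def __post_init__(self):
        bad = []
        if not self.nrmse_threshold > 0:
            bad.append("nrmse_threshold")
        if not self.lambda_a < self.lambda_b:
            bad.append("lambda_a")
        if bad:
            raise ValidationError("invalid run configuration", fields=bad)

    def fit_options(self) -> FitOptions:
        return FitOptions(
            enforce_stability=self.enforce_stability,
            enforce_linear_part=self.enforce_linear_part,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the analysis parameters (paths excluded),
        recorded in outputs."""
        params = {
            k: v
            for k, v in self.to_dict().items()
            if k not in ("raw_dir", "metadata", "out_dir")
        }
        text = json.dumps(params, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "columns" in data:
            data["columns"] = ColumnMap(**data["columns"])
        config = cls(**data)
        return replace(config, **overrides) if overrides else config
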