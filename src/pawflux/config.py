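"""Pipeline configuration: defaults, YAML round-trip, reproducibility hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline in one serializable object."""

    fps: float = 30.0
    likelihood_threshold: float = 0.6
    median_window: int = 5
    detrend_order: int = 2
    n_scales: int = 20
    s_min: int | None = None  # frames; default max(8, order + 3)
    s_max_fraction: float = 0.25  # s_max = N * fraction
    rho: float = 1.25  # rotation exponent for crossover localization
    window_seconds: float = 30.0
    window_step_fraction: float = 0.5
    fence_k: float = 1.5
    correction: str = "bonferroni"
    graph_scales_seconds: tuple[float, ...] = (5.0, 30.0)
    px_per_cm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.likelihood_threshold <= 1:
            raise ParameterError("likelihood_threshold must be in [0, 1]")
        if self.median_window % 2 == 0 or self.median_window < 1:
            raise ParameterError("median_window must be odd and positive")
        if not 1 <= self.detrend_order <= 3:
            raise ParameterError("detrend_order must be 1, 2 or 3")
        if self.correction not in ("bonferroni", "fdr_bh"):
            raise ParameterError(f"unknown correction {self.correction!r}")
        if not 0 < self.s_max_fraction <= 0.5:
            raise ParameterError("s_max_fraction must lie in (0, 0.5]")
        if isinstance(self.graph_scales_seconds, list):
            self.graph_scales_seconds = tuple(self.graph_scales_seconds)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["graph_scales_seconds"] = list(self.graph_scales_seconds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
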