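"""Pipeline configuration: every numeric constant plus input/output paths."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value or path is invalid."""


@dataclass
class PipelineConfig:
    min_contig_bp: int = 5000
    ani_threshold_pct: float = 95.0
    breadth_min: float = 0.75
    # documentation of the upstream mapper's read-identity filter; counts are
    # consumed post-filter, this value is only echoed into reports
    read_identity_min: float = 0.90
    rpkm_total_min: float = 100.0
    rpkm_value_min: float = 20.0
    prevalence_min: float = 0.10
    mag_quality_min: float = 50.0
    spacer_len: tuple[int, int] = (20, 30)
    spacer_max_mismatch: int = 2
    tir_range: tuple[float, float] = (3.9, 10.0)
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    INPUT_KEYS = (
        "annotations",
        "ani",
        "coverage",
        "library_sizes",
        "mag_membership",
        "mag_quality",
        "mag_taxonomy",
        "spacer_hits",
        "metadata",
        "da_vp_list",
        "mag_counts",
    )
    OPTIONAL_INPUT_KEYS = ("cgm", "ogtt", "truth")

    def __post_init__(self) -> None:
        self.spacer_len = tuple(self.spacer_len)  # type: ignore[assignment]
        self.tir_range = tuple(self.tir_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if self.min_contig_bp <= 0:
            raise ConfigError("min_contig_bp must be positive")
        if not 0 < self.ani_threshold_pct <= 100:
            raise ConfigError("ani_threshold_pct must be in (0, 100]")
        if not 0 <= self.breadth_min <= 1:
            raise ConfigError("breadth_min must be in [0, 1]")
        if not 0 <= self.prevalence_min <= 1:
            raise ConfigError("prevalence_min must be in [0, 1]")
        if self.rpkm_total_min < 0 or self.rpkm_value_min < 0:
            raise ConfigError("rpkm thresholds must be non-negative")
        if len(self.spacer_len) != 2 or self.spacer_len[0] > self.spacer_len[1] or self.spacer_len[0] < 1:
            raise ConfigError("spacer_len must be an increasing positive pair")
        if self.spacer_max_mismatch < 0:
            raise ConfigError("spacer_max_mismatch must be >= 0")
        if len(self.tir_range) != 2 or self.tir_range[0] >= self.tir_range[1]:
            raise ConfigError("tir_range must be an increasing pair")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    def path(self, key: str) -> Path:
        if key not in self.paths:
            raise ConfigError(f"missing path for {key!r} in config")
        return Path(self.paths[key])

    def check_inputs(self, keys: tuple[str, ...] | None = None) -> None:
        """Fail before any stage runs when a required input path is absent."""
        for key in keys if keys is not None else self.INPUT_KEYS:
            p = self.path(key)
            if not p.exists():
                raise ConfigError(f"input {key!r} not found at {p}")

    def out_dir(self) -> Path:
        out = Path(self.paths.get("out_dir", "results"))
        out.mkdir(parents=True, exist_ok=True)
        return out

    def echo(self) -> dict:
        d = asdict(self)
        d["spacer_len"] = list(self.spacer_len)
        d["tir_range"] = list(self.tir_range)
        return d


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load YAML or JSON config; keyword overrides win over file values."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
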