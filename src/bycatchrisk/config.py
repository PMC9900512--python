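"""Pipeline configuration: one YAML file, one root seed.

The configuration names the synthetic-world scale (or, for real-data runs,
paths to pre-built input tables), the output directory, and toggles such as
whether to ingest a supplied abundance grid instead of running advection.
It round-trips through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "out"
    year_start: int = 2000
    year_end: int = 2009
    species: list[str] = field(default_factory=lambda: ["kemps_ridley", "green"])
    gears: list[str] = field(
        default_factory=lambda: ["shrimp_trawl", "gillnet", "recreational"]
    )
    # synthetic-world scale
    particles_per_day: int = 8
    window_days: int = 10
    age_classes: list[float] = field(default_factory=lambda: [0.5, 1.5])
    step_hours: float = 0.5
    # estimate-stage toggles
    use_abundance_file: bool = True  # ingest abundance.csv instead of drifting
    # optional explicit input paths (default: files inside outdir)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ConfigError("year_end must be >= year_start")
        if not self.species:
            raise ConfigError("species list must be non-empty")
        if self.particles_per_day < 1 or self.window_days < 1:
            raise ConfigError("particle release scale must be >= 1")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.year_start, self.year_end + 1))

    def path(self, name: str) -> Path:
        """Resolve an input/output file, honouring explicit overrides."""
        if name in self.inputs:
            return Path(self.inputs[name])
        return Path(self.outdir) / name

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
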