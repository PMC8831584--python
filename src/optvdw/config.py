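"""Run configuration: a flat, file-round-trippable record of CLI settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of a command-line run; round-trips losslessly through YAML."""

    inputs: list[str] = field(default_factory=list)
    system: str | None = None  # builder name for synthetic systems
    system_params: dict = field(default_factory=dict)
    damping: str = "gaussian"
    broadening_ev: float = 0.3
    shift_ev: float = 0.0
    r_grid_angstrom: list[float] = field(default_factory=list)
    modes: list[int] = field(default_factory=list)  # 1-based
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.broadening_ev <= 0:
            raise ValueError("broadening must be positive")
        if self.damping not in ("bare", "gaussian"):
            raise ValueError(f"unknown damping {self.damping!r}")
        if any(r <= 0 for r in self.r_grid_angstrom):
            raise ValueError("scan distances must be positive")
        if any(k < 1 for k in self.modes):
            raise ValueError("mode indices are 1-based")

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
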