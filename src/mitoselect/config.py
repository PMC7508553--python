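"""Run configuration: a single plain-text YAML file, strictly validated.

Unknown keys are rejected outright (fail-fast) so typos cannot silently
change a run. The configuration plus the root seed fully determine every
output table.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import ParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    outdir: str = "mitoselect_run"
    presets: list[str] = field(
        default_factory=lambda: [
            "wt_control", "wt_restricted", "daf16_control", "daf16_restricted",
        ]
    )
    n_lineages: int = 30
    n_lines: int = 6
    generations: int = 8
    carry_n: int = 200
    genotype_sample: int = 48
    n_boot: int = 2000
    normalization_mode: str = "ratio"
    weighted_pooling: bool = False
    measurement: bool = False
    preset_file: str | None = None

    def __post_init__(self) -> None:
        if self.normalization_mode not in ("ratio", "difference"):
            raise ParameterError("normalization_mode must be 'ratio' or 'difference'")
        if self.seed < 0:
            raise ParameterError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must hold a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    def digest(self) -> str:
        """Stable hash of the canonical YAML form of this configuration."""
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
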