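"""Analysis configuration: presets, overrides and deterministic metadata.

Configurations round-trip through YAML bit-exactly and reject unknown keys;
the seed only scatters randomised initial guesses (the model itself is
deterministic) and is recorded in every output header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .params import ModelParameters, preset


@dataclass
class AnalysisConfig:
    preset: str = "ca3_default"
    overrides: dict[str, Any] = field(default_factory=dict)
    analysis: str = "simulate"
    bif_param: str = "ISapp"
    p_range: tuple[float, float] = (-500.0, 500.0)
    t_max: float = 5000.0
    rtol: float = 1e-8
    atol: float = 1e-8
    seed: int = 0
    out: str | None = None

    def __post_init__(self):
        self.p_range = tuple(float(v) for v in self.p_range)
        if len(self.p_range) != 2 or self.p_range[0] >= self.p_range[1]:
            raise ValueError("p_range must be an increasing pair")

    def params(self) -> ModelParameters:
        return preset(self.preset, **self.overrides)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["p_range"] = list(self.p_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"# pyrcell {__version__}",
            f"# config_hash={self.hash()} seed={self.seed}",
            f"# rtol={self.rtol} atol={self.atol}",
        ]


def write_csv(path: str | Path, header_lines: list[str], columns: list[str],
              rows) -> None:
    """CSV with commented provenance header, 6 significant digits."""
    lines = list(header_lines)
    lines.append(",".join(columns))
    for row in rows:
        vals = []
        for c in columns:
            v = row[c] if isinstance(row, dict) else getattr(row, c)
            vals.append(f"{v:.6g}" if isinstance(v, float) else str(v))
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")
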