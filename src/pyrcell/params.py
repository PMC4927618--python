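"""Model parameter sets and presets.

The two-compartment CA3/CA1 pyramidal cell model is fully determined by the
maximal conductances, reversal potentials, the somatic area fraction ``p``,
the membrane capacitance ``Cm`` and the applied currents.  Conductances and
currents form a consistent per-area unit set (the values are numerically
identical whether the conductance unit is read as the historical mS/cm^2 or
as uS/cm^2); voltages are in mV and time in ms.

``Cm`` is not part of the published parameter table; the value 3 of the
original Pinsky-Rinzel formulation is adopted and exposed as an ordinary
parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

VARIANTS = ("smooth", "original")

#: Ordering of the numeric parameters as passed to the generated callables.
THETA_FIELDS = (
    "gNa", "gKDR", "gKCa", "gKAHP", "gCa", "gL", "gC",
    "VNa", "VK", "VCa", "VL", "p", "Cm", "ISapp", "IDapp",
)


@dataclass
class ModelParameters:
    """Conductances (per-area units), reversal potentials (mV) and drive.

    Defaults are the published CA3 set: gNa=30, gKDR=15, gKCa=15, gKAHP=0.8,
    gCa=10, gL=0.1, gC=2.1 and VNa=60, VK=-75, VCa=80, VL=-60 with p=0.5.
    """

    gNa: float = 30.0
    gKDR: float = 15.0
    gKCa: float = 15.0
    gKAHP: float = 0.8
    gCa: float = 10.0
    gL: float = 0.1
    gC: float = 2.1
    VNa: float = 60.0
    VK: float = -75.0
    VCa: float = 80.0
    VL: float = -60.0
    p: float = 0.5
    Cm: float = 3.0
    ISapp: float = 0.0
    IDapp: float = 0.0
    variant: str = "smooth"

    def __post_init__(self) -> None:
        for g in ("gNa", "gKDR", "gKCa", "gKAHP", "gCa", "gL", "gC"):
            if getattr(self, g) < 0:
                raise ValueError(f"conductance {g} must be non-negative")
        if not 0.0 < self.p < 1.0:
            raise ValueError("somatic area fraction p must lie in (0, 1)")
        if self.Cm <= 0:
            raise ValueError("membrane capacitance Cm must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    def theta(self) -> tuple[float, ...]:
        """Numeric parameter vector in :data:`THETA_FIELDS` order."""
        return tuple(float(getattr(self, name)) for name in THETA_FIELDS)

    def replace(self, **changes: Any) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


#: Published parameter presets.  ``ca3_default`` is the printed CA3 table;
#: ``ca1_gca7`` is the CA1 variant obtained by lowering gCa from 10 to 7.
PRESETS: dict[str, dict[str, Any]] = {
    "ca3_default": {},
    "ca1_gca7": {"gCa": 7.0},
}


def preset(name: str, **overrides: Any) -> ModelParameters:
    """Build a :class:`ModelParameters` from a named preset plus overrides."""
    try:
        base = dict(PRESETS[name])
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    base.update(overrides)
    return ModelParameters.from_dict(base)


def save_params(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def load_params(path: str | Path) -> ModelParameters:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError("parameter file must contain a mapping")
    return ModelParameters.from_dict(d)
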