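"""Combined cell parameter set, multiplicative scaling, and config I/O.

``CellParams`` is the flat union of the myofilament and calcium parameter
namespaces plus pacing and solver settings.  Every field name is a stable
config key; parameter sets round-trip through YAML/JSON as flat key->value
mappings.  Remodelling (genetic variants, drugs, interventions, population
variability) is expressed as multiplicative factors on these keys via
:meth:`CellParams.scaled`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .calcium import CalciumParams
from .myofilament import MyofilamentParams

__all__ = ["CellParams", "default_params"]

_MYO_FIELDS = {f.name for f in dataclasses.fields(MyofilamentParams)}
_CA_FIELDS = {f.name for f in dataclasses.fields(CalciumParams)}


@dataclass(frozen=True)
class CellParams(MyofilamentParams, CalciumParams):
    """All model constants plus pacing/solver settings.

    Pacing defaults to a 1000 ms cycle length (1 Hz), the protocol under
    which all biomarkers are computed at steady state.
    """

    cycle_ms: float = 1000.0   # pacing cycle length
    rtol: float = 1e-6         # solver relative tolerance
    atol: float = 1e-9         # solver absolute tolerance (state-scaled)
    max_step_ms: float = 50.0  # solver maximum step

    def __post_init__(self) -> None:
        MyofilamentParams.__post_init__(self)
        CalciumParams.__post_init__(self)
        if self.cycle_ms <= 0:
            raise ValueError("cycle_ms must be positive")
        if self.rtol <= 0 or self.atol <= 0 or self.max_step_ms <= 0:
            raise ValueError("solver tolerances and max step must be positive")

    # -- views ------------------------------------------------------------
    def myofilament(self) -> MyofilamentParams:
        kw = {n: getattr(self, n) for n in _MYO_FIELDS}
        return MyofilamentParams(**kw)

    def calcium(self) -> CalciumParams:
        kw = {n: getattr(self, n) for n in _CA_FIELDS}
        return CalciumParams(**kw)

    # -- remodelling -------------------------------------------------------
    def replace(self, **overrides: Any) -> "CellParams":
        return dataclasses.replace(self, **overrides)

    def scaled(self, factors: Mapping[str, float]) -> "CellParams":
        """Return a copy with each named parameter multiplied by its factor.

        Factors compose: ``p.scaled(a).scaled(b)`` equals scaling by the
        elementwise product of ``a`` and ``b``.
        """
        overrides: dict[str, float] = {}
        for name, factor in factors.items():
            if not hasattr(self, name):
                raise KeyError(f"unknown parameter {name!r}")
            if factor <= 0:
                raise ValueError(f"scaling factor for {name!r} must be > 0")
            overrides[name] = getattr(self, name) * factor
        return self.replace(**overrides)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["fb_bounds"] = list(d["fb_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CellParams":
        kw = dict(d)
        if "fb_bounds" in kw:
            kw["fb_bounds"] = tuple(kw["fb_bounds"])
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CellParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def default_params(**overrides: Any) -> CellParams:
    """The control (wild-type) parameter set, optionally with overrides."""
    return CellParams(**overrides)
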