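"""Analysis configuration: a TOML-serialisable bundle of pipeline options."""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Union

from .errors import ValidationError


@dataclass
class AnalysisConfig:
    """Everything the batch-analysis pipeline needs besides the data.

    ``series_paths`` lists tidy CSV inputs; ``carrier`` selects the electron
    carrier for the energy partition; ``thresholds`` are the ΔG levels (kJ)
    for the H2 windows; ``default_co2_pa``/``default_ch4_pa`` supply gas
    partial pressures when an input series lacks those channels (a CO2/CH4
    headspace assumption is unavoidable for ΔG on acid-only series).
    """

    series_paths: List[str] = field(default_factory=list)
    thermo_table: Optional[str] = None
    carrier: str = "hydrogen"
    thresholds: List[float] = field(default_factory=lambda: [0.0, -10.0])
    min_points: int = 4
    window_days: float = 5.0
    default_co2_pa: float = 30397.5   # 0.3 atm
    default_ch4_pa: float = 50662.5   # 0.5 atm
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.carrier not in ("hydrogen", "formate"):
            raise ValidationError(f"carrier must be hydrogen or formate, got {self.carrier!r}")
        if self.min_points < 2:
            raise ValidationError("min_points must be at least 2")
        if self.window_days <= 0:
            raise ValidationError("window_days must be positive")

    # -- TOML round trip -----------------------------------------------------

    @classmethod
    def from_toml(cls, source: Union[str, Path]) -> "AnalysisConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        raw = tomllib.loads(text)
        known = {f: raw[f] for f in cls.__dataclass_fields__ if f in raw}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_toml(self) -> str:
        return _emit_toml(asdict(self))

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_toml())


def _emit_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        escaped = value.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_emit_value(v) for v in value) + "]"
    raise ValidationError(f"cannot serialise {type(value).__name__} to TOML")


def _emit_toml(mapping: dict) -> str:
    lines = []
    for key, value in mapping.items():
        if value is None:
            continue  # optional field left unset
        lines.append(f"{key} = {_emit_value(value)}")
    return "\n".join(lines) + "\n"
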