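"""Run configuration: one flat key = value file, CLI-overridable.

Defaults are the training-procedure constants: 1,500-residue length
cap, 90% identity reduction, 30% holdout, groups of at least 35, 150 /
500 minimum positives / negatives, MCC discard threshold 0.05,
H-reliability floors (0.3, 0.3, 0.7, 0.3), display threshold 0.5 and
the COGIC strata (0.75, 0.50, 0.25, 0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .assessment import COGIC_STRATA, COGIC_WEIGHTS
from .training import GridSpec


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # paths
    ontology: str = ""
    annotations: str = ""
    sequences: str = ""
    features: str = ""
    distances: str = ""
    vocab: str = ""
    models: str = ""
    output: str = ""
    ic_table: str = ""
    # dataset parameters
    max_length: int = 1500
    identity: float = 0.90
    min_pos: int = 150
    min_neg: int = 500
    # partition / training parameters
    holdout: float = 0.30
    min_group: int = 35
    discard_mcc: float = 0.05
    reliability: tuple[float, float, float, float] = (0.3, 0.3, 0.7, 0.3)
    grid_c: tuple[float, ...] = tuple(float(2.0 ** e) for e in range(-5, 8, 2))
    grid_gamma: tuple[float, ...] = tuple(float(2.0 ** e)
                                          for e in range(-9, 2, 2))
    grid_kinds: tuple[str, ...] = ("linear", "rbf")
    # prediction / assessment parameters
    display_threshold: float = 0.5
    cogic_strata: tuple[float, ...] = COGIC_STRATA
    cogic_weights: tuple[float, ...] = COGIC_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout < 1.0:
            raise ConfigError("holdout must be in (0, 1)")
        if not 0.0 < self.identity <= 1.0:
            raise ConfigError("identity must be in (0, 1]")
        if self.discard_mcc < -1 or self.discard_mcc > 1:
            raise ConfigError("discard_mcc must be in [-1, 1]")
        if len(self.reliability) != 4:
            raise ConfigError("reliability needs 4 thresholds")

    def grid(self) -> GridSpec:
        return GridSpec(c_values=self.grid_c, gamma_values=self.grid_gamma,
                        kinds=self.grid_kinds)

    # -- flat-file round trip ------------------------------------------------

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                rendered = ",".join(str(v) for v in value)
            else:
                rendered = str(value)
            lines.append(f"{f.name} = {rendered}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"malformed config line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value
        return cls._from_raw(raw, overrides)

    @classmethod
    def _from_raw(cls, raw: dict[str, str], overrides: dict) -> "RunConfig":
        kwargs: dict = {}
        by_name = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in by_name:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(value, by_name[key].type,
                                  getattr(cls(), key))
        for key, value in overrides.items():
            if value is not None:
                kwargs[key] = value
        return cls(**kwargs)


def _coerce(text: str, annotation: str, default):
    if isinstance(default, tuple):
        parts = [p for p in text.split(",") if p != ""]
        if default and isinstance(default[0], str):
            return tuple(parts)
        return tuple(float(p) for p in parts)
    if isinstance(default, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(text)
    if isinstance(default, float):
        return float(text)
    return text
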