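"""Tool configuration: classifier thresholds, efficiencies, analysis knobs.

All values are model parameters exposed to the user; defaults are chosen
to reproduce the observed on-target / family / escape / partial blocking
behaviour (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Minimum contiguous complementary run from the junction for full blocking.
FULL_BLOCK_MIN = 8
#: Minimum run for partial blocking (register 0 short match or +1 gap register).
PARTIAL_MIN = 6

#: Fraction of a species' molecules covalently capped per blocking class.
#: BLOCKED must exceed 0.9934 for a species at 60% of input reads to fall
#: below 1% of the post-blocking library; 0.995 is the default.
DEFAULT_EFFICIENCY = {"BLOCKED": 0.995, "PARTIAL": 0.5, "ESCAPE": 0.0, "NONE": 0.0}

#: Library evaluation defaults: common down-sampling depth and the
#: detection count threshold most analyses quote.
DEFAULT_DEPTH = 6_000_000
DEFAULT_THRESHOLD = 10


@dataclass(frozen=True)
class ClassifierConfig:
    full_block_min: int = FULL_BLOCK_MIN
    partial_min: int = PARTIAL_MIN
    efficiency_map: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFICIENCY)
    )

    def __post_init__(self) -> None:
        if not 0 < self.partial_min <= self.full_block_min:
            raise ValueError("need 0 < partial_min <= full_block_min")
        for cls, eff in self.efficiency_map.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"efficiency for {cls} outside [0, 1]: {eff}")

    def efficiency(self, blocking_class: str) -> float:
        return float(self.efficiency_map[blocking_class])


@dataclass(frozen=True)
class DesignConfig:
    overhang_length: int = 12
    stem: str = "GCAGCCTG"
    loop: str = "GAAA"
    tm_window: tuple[float, float] = (28.0, 48.0)


@dataclass(frozen=True)
class EvalConfig:
    depth: int = DEFAULT_DEPTH
    thresholds: tuple[int, ...] = tuple(range(1, 101))
    base_mean_min: float = 10.0
    seed: int = 0
    deterministic: bool = False


def load_yaml_config(path: str | Path, cls: type, **overrides: Any):
    """Build a config dataclass from a YAML file plus keyword overrides."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cls(**raw)


def dump_config(cfg: Any) -> str:
    """Serialize any config dataclass to YAML (for output provenance)."""
    return yaml.safe_dump(asdict(cfg), sort_keys=True)


__all__ = [
    "ClassifierConfig",
    "DesignConfig",
    "EvalConfig",
    "DEFAULT_EFFICIENCY",
    "DEFAULT_DEPTH",
    "DEFAULT_THRESHOLD",
    "load_yaml_config",
    "dump_config",
    "replace",
]
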