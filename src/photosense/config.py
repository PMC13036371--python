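"""Run configuration: validation, YAML loading, and the reproducibility manifest."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy
import yaml

from .bounds import FACTOR_NAMES, FactorBounds, bounds_from_mapping, default_bounds

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    """Validated configuration of a full audit run.

    Defaults mirror the standard study configuration: N = 256 base samples
    over the five factors (1792 evaluations per image), deterministic seed
    2021, neutral decision threshold 0.5, 5-step OAT sweeps.
    """

    images: str | None = None
    metadata: str | None = None
    out: str = "photosense_out"
    predictor: str = "probe:hue"
    n: int = 256
    seed: int = 2021
    threshold: float = 0.5
    side: int = 128
    oat_steps: int = 5
    strata: tuple[str, ...] = ()
    bounds: list[FactorBounds] = field(default_factory=default_bounds)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.oat_steps < 2:
            raise ValueError(f"oat_steps must be >= 2, got {self.oat_steps}")
        names = tuple(b.name for b in self.bounds)
        if names != FACTOR_NAMES:
            raise ValueError(f"bounds must name {FACTOR_NAMES} in order, got {names}")
        for col in self.strata:
            if col not in ("dx", "dx_type", "sex", "localization", "age", "label"):
                raise ValueError(f"unknown stratification column {col!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bounds"] = {b.name: [b.lo, b.hi] for b in self.bounds}
        d["strata"] = list(self.strata)
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    File keys match :class:`RunConfig` fields; ``bounds`` is a mapping
    ``{factor: [lo, hi]}``.  Overrides (e.g. CLI flags) win over file values.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    if isinstance(values.get("bounds"), dict):
        values["bounds"] = bounds_from_mapping(values["bounds"])
    if "strata" in values:
        values["strata"] = tuple(values["strata"])
    return RunConfig(**values)


def write_manifest(config: RunConfig, path: str | Path, extra: dict | None = None) -> None:
    """Write the JSON run manifest: full config, seeds and library versions."""
    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "photosense": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
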