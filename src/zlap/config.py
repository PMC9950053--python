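"""Run configuration: the assay's a priori thresholds plus I/O settings.

The thresholds default to the assay's published values and normally stay
untouched: validity 0.5 (minimum body-part likelihood), movement 3 px per
6 s, scoot/burst cut 20 px, edge at 50 % of the well radius, OMR eligibility
at 5 % period movement, whole-recording exclusion at 1 % movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    validity_threshold: float = 0.5
    move_threshold_px: float = 3.0
    burst_threshold_px: float = 20.0
    edge_fraction: float = 0.5
    omr_min_move_fraction: float = 0.05
    exclusion_move_fraction: float = 0.01
    schedule_path: str | None = None
    rows: int = 8
    cols: int = 12
    min_radius: int = 65
    max_radius: int = 85
    min_dist: int = 150
    seed: int = 0
    out_dir: str = "zlap_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("validity_threshold", "move_threshold_px", "burst_threshold_px",
                     "edge_fraction", "omr_min_move_fraction", "exclusion_move_fraction"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.move_threshold_px >= self.burst_threshold_px:
            raise ConfigError("move threshold must be below the burst cut")


def load_config(path: str | Path | None) -> RunConfig:
    """Read a YAML run configuration; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**kwargs, extra=extra)
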