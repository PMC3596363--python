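"""Analysis configuration: every tunable threshold in one place.

Defaults are the published values (H-bond cutoffs, energy classes,
Ramachandran windows, gap tolerance) and are used throughout unless a YAML
config overrides them.  The YAML mirrors the dataclass layout::

    hbond:
      d_max_calpha: 3.0
      d_max_amide: 2.7
      angle_min: 90.0
      weak_energy: -0.5
      strong_energy: -1.0
    rama:
      helical_phi: [-85, -55]
      helical_psi: [-69, -45]
      ppii_phi: [-85, -55]
      ppii_psi: [130, 170]
      broad_phi: [-110, -40]
      broad_psi: [-80, -5]
    trajectory:
      gap_tolerance: 10
      time_step: 1.0
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .conformation import RamaWindows
from .interactions import HBondCriteria

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class TrajectorySettings:
    gap_tolerance: int = 10
    time_step: float = 1.0  # ps per frame


@dataclass
class AnalysisConfig:
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    rama: RamaWindows = field(default_factory=RamaWindows)
    trajectory: TrajectorySettings = field(default_factory=TrajectorySettings)

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logging."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: Optional[Union[str, Path]] = None) -> AnalysisConfig:
    """Published-default config, optionally overridden from a YAML file."""
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "hbond" in raw:
        cfg.hbond = HBondCriteria(**{**asdict(cfg.hbond), **raw["hbond"]})
    if "rama" in raw:
        base = asdict(cfg.rama)
        base.update({k: tuple(v) for k, v in raw["rama"].items()})
        cfg.rama = RamaWindows(**base)
    if "trajectory" in raw:
        cfg.trajectory = TrajectorySettings(
            **{**asdict(cfg.trajectory), **raw["trajectory"]}
        )
    return cfg
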