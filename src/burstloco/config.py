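"""Run configuration and the unit/coordinate conventions the pipeline assumes.

Conventions (used by every module):

* SI units internally: seconds, metres, kilograms, newtons, watts. Muscle
  architecture tables keep the field's g/cm units on disk and in
  :class:`~burstloco.muscle.MuscleRecord`; conversion to SI happens only
  inside the power computation.
* Fore-aft axis positive in the direction of travel; vertical axis positive
  up; force plates zeroed so the unloaded vertical reading is ~0 N.
* Time origin t = 0 at the common trigger shared by force plates and cameras.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

GRAVITY = 9.81  # m/s^2


@dataclass
class RunConfig:
    """Tunable pipeline parameters with their defaults.

    Parameters mirror the processing choices of the study design: 500 Hz
    force sampling, 250 Hz marker sampling, a quintic-spline tolerance of
    0.75 mm^2, a 10-frame kinematic window on each side of contact, and a
    stance-detection threshold of 2% body weight.
    """

    force_rate_hz: float = 500.0
    marker_rate_hz: float = 250.0
    spline_tolerance_mm2: float = 0.75
    #: 'per-frame' bounds the mean squared residual; 'total' bounds the sum.
    spline_tolerance_mode: str = "per-frame"
    frames_before_contact: int = 10
    frames_after_contact: int = 10
    stance_threshold_bw_fraction: float = 0.02
    subtract_force_baseline: bool = False
    #: COM power window: 'hindlimb' (push-off stance) or 'stride'.
    power_window: str = "hindlimb"
    #: include gravitational potential energy in COM energy fluctuations
    include_potential_energy: bool = True
    vertical_v0: float = 0.0
    n_boot: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


DEFAULT_CONFIG = RunConfig()
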