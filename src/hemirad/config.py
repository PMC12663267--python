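"""Model configuration: search radii, angular grids, foliage densities.

The λ defaults are *uncalibrated placeholders*: the effective foliage area
volume density of a forest type must normally be calibrated against
hemispherical photographs or crown-segmented lidar.  The defaults are
field-plausible orders of magnitude for spruce/beech canopies and exist so
the model runs end-to-end; any quantitative application must supply its own
calibrated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "load_config"]


@dataclass
class ModelConfig:
    # horizon search
    local_radius: float = 300.0       # m, local DTM stage
    regional_radius: float = 25000.0  # m, regional DTM stage
    viewer_height: float = 0.0        # m above ground surface

    # angular discretisation
    azimuth_step: float = 1.0   # degrees
    zenith_step: float = 1.0    # degrees
    svf_ring_width: float = 10.0  # degrees, zenith ring width for SVF

    # solar geometry
    solar_disc_diameter: float = 0.53  # degrees, apparent solar diameter
    track_step: int = 2                # minutes, solar-track cadence
    utc_offset: float = 1.0            # hours; CET as a fixed offset
    apply_refraction: bool = False     # atmospheric refraction in solar zenith

    # canopy transmission (Beer–Lambert)
    G: float = 0.5  # projection function; 0.5 = random foliage orientation
    canopy_ray_step: float = 0.5  # m, ray-march step through the canopy
    lambda_evergreen: float = 0.75      # m⁻¹, uncalibrated placeholder
    lambda_deciduous_on: float = 0.6    # m⁻¹, uncalibrated placeholder
    lambda_deciduous_off: float = 0.2   # m⁻¹, uncalibrated placeholder
    lambda_larch_on: float = 0.75       # m⁻¹, = evergreen value for leaf-on larch
    lambda_larch_off: float = 0.15      # m⁻¹, uncalibrated placeholder

    # binarisation of the transmission probability
    binarise_mode: str = "stochastic"  # "stochastic" | "threshold"
    rng_seed: int = 0

    # run control
    year: int = 2020

    def __post_init__(self) -> None:
        if self.local_radius <= 0 or self.regional_radius <= 0:
            raise ValueError("search radii must be positive")
        if self.solar_disc_diameter <= 0:
            raise ValueError("solar disc diameter must be positive")
        for step, full in ((self.zenith_step, 90.0), (self.azimuth_step, 360.0),
                           (self.svf_ring_width, 90.0)):
            if step <= 0 or abs(full / step - round(full / step)) > 1e-9:
                raise ValueError(f"angular step {step} must divide {full}")
        if 60 % self.track_step != 0:
            raise ValueError("track step (minutes) must divide 60")
        if not 0 < self.G <= 1:
            raise ValueError("projection function G must lie in (0, 1]")
        for name in ("lambda_evergreen", "lambda_deciduous_on", "lambda_deciduous_off",
                     "lambda_larch_on", "lambda_larch_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.binarise_mode not in ("stochastic", "threshold"):
            raise ValueError("binarise_mode must be 'stochastic' or 'threshold'")

    @property
    def n_zenith(self) -> int:
        return round(90.0 / self.zenith_step)

    @property
    def n_azimuth(self) -> int:
        return round(360.0 / self.azimuth_step)

    def lambda_value(self, condition: str, forest_class: str) -> float:
        """λ endpoint for the deciduous component of a mixed pixel."""
        if forest_class == "forced_larch":
            return self.lambda_larch_on if condition == "leaf_on" else self.lambda_larch_off
        if condition == "leaf_on":
            return self.lambda_deciduous_on
        if condition == "leaf_off":
            return self.lambda_deciduous_off
        raise ValueError(f"unknown leaf condition {condition!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> ModelConfig:
    """Load a ModelConfig from a YAML mapping; unset keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ModelConfig(**data)
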