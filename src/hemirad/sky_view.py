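"""Sky-view factors from a hemispheric image using 10° zenith rings.

Two receiver geometries are supported.  *SVF-planar* is the perspective of
a flat horizontal surface: each ring's sky fraction is weighted by the
ring's area projected onto the horizontal plane, w ∝ sin²θ₂ − sin²θ₁.
*SVF-hemi* is the perspective of a three-dimensional receiver such as a
plant: rings are weighted by their surface area on the hemisphere,
w ∝ cosθ₁ − cosθ₂.  Within a ring, each 1° cell contributes with its solid
angle (∝ sin of its zenith centre).  Ring weights are analytic, so images
whose obstruction boundaries fall on ring edges reproduce the spherical
closed forms exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .terrain_horizon import HemisphericImage

__all__ = ["SvfPair", "ring_sky_fraction", "svf_planar", "svf_hemi", "sky_view_pair"]


@dataclass(frozen=True)
class SvfPair:
    svf_planar: float
    svf_hemi: float


def ring_sky_fraction(image: HemisphericImage, ring: tuple[float, float]) -> float:
    """Solid-angle-weighted sky fraction of the zenith ring [θ₁, θ₂)."""
    t1, t2 = ring
    if not (0.0 <= t1 < t2 <= 90.0):
        raise ValueError(f"ring {ring} must satisfy 0 <= θ₁ < θ₂ <= 90")
    step = image.zenith_step
    if abs(t1 / step - round(t1 / step)) > 1e-9 or abs(t2 / step - round(t2 / step)) > 1e-9:
        raise ValueError(f"ring {ring} is not aligned to the {step}° zenith bins")
    i1, i2 = round(t1 / step), round(t2 / step)
    centres = image.zenith_centres[i1:i2]
    w = np.sin(np.radians(centres))
    sky = image.sky[i1:i2]
    return float((sky * w[:, None]).sum() / (w.sum() * sky.shape[1]))


def _ring_edges(config: ModelConfig) -> np.ndarray:
    n = round(90.0 / config.svf_ring_width)
    return np.linspace(0.0, 90.0, n + 1)


def _weighted_svf(image: HemisphericImage, config: ModelConfig,
                  ring_weight) -> float:
    edges = _ring_edges(config)
    weights = ring_weight(np.radians(edges[:-1]), np.radians(edges[1:]))
    weights = weights / weights.sum()
    fractions = np.array([ring_sky_fraction(image, (edges[i], edges[i + 1]))
                          for i in range(edges.size - 1)])
    # guard against ulp-level overshoot of the normalised weighted sum
    return float(min(max((weights * fractions).sum(), 0.0), 1.0))


def svf_planar(image: HemisphericImage, config: ModelConfig | None = None) -> float:
    """Sky-view factor for a horizontal planar receiver.

    Ring weights ∝ sin²θ₂ − sin²θ₁, the projected area of the annulus on
    the horizontal plane (cosine-weighted sky view).
    """
    config = config or ModelConfig()
    return _weighted_svf(image, config,
                         lambda t1, t2: np.sin(t2) ** 2 - np.sin(t1) ** 2)


def svf_hemi(image: HemisphericImage, config: ModelConfig | None = None) -> float:
    """Sky-view factor for a 3-D receiver (hemisphere surface-area weights).

    Ring weights ∝ cosθ₁ − cosθ₂, the area of the annulus on the unit
    hemisphere.
    """
    config = config or ModelConfig()
    return _weighted_svf(image, config,
                         lambda t1, t2: np.cos(t1) - np.cos(t2))


def sky_view_pair(image: HemisphericImage, config: ModelConfig | None = None) -> SvfPair:
    """Both SVF variants of one image."""
    config = config or ModelConfig()
    return SvfPair(svf_planar=svf_planar(image, config),
                   svf_hemi=svf_hemi(image, config))
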