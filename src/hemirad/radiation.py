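"""Surface shortwave radiation from DBT, SVF and above-canopy forcing.

The reconstruction is a two-term split of the incoming shortwave flux:
the direct component is scaled per time step by the direct-beam
transmissivity and the diffuse component by the (static) sky-view factor:

    SWR_i = SWR_dir,i · DBT_i + SWR_dif,i · SVF

When no measured or modelled forcing is available, a maximum-potential
flux can be substituted from the solar constant and an assumed
atmospheric transmissivity: I₀ · cos(θ) · τ_atm, clamped to zero at night.
"""

from __future__ import annotations

import numpy as np

__all__ = ["surface_swr", "max_potential_swr", "SOLAR_CONSTANT"]

SOLAR_CONSTANT = 1361.0  # W m⁻²


def surface_swr(swr_dir, swr_dif, dbt, svf: float) -> np.ndarray:
    """Sub-canopy shortwave radiation per time step (W m⁻²).

    ``swr_dir``/``swr_dif`` are the above-canopy direct and diffuse
    components; ``dbt`` the per-step direct-beam transmissivity in [0, 1];
    ``svf`` a single sky-view factor in [0, 1].  Which SVF variant to pass
    (planar vs hemi) depends on the receiver the caller models.
    """
    swr_dir = np.asarray(swr_dir, dtype=float)
    swr_dif = np.asarray(swr_dif, dtype=float)
    dbt = np.asarray(dbt, dtype=float)
    if swr_dir.shape != swr_dif.shape or swr_dir.shape != dbt.shape:
        raise ValueError("forcing and DBT series are misaligned")
    if np.any(swr_dir < 0) or np.any(swr_dif < 0):
        raise ValueError("shortwave forcing components must be >= 0")
    valid = ~np.isnan(dbt)
    if np.any((dbt[valid] < 0) | (dbt[valid] > 1)):
        raise ValueError("DBT values must lie in [0, 1]")
    if not 0.0 <= svf <= 1.0:
        raise ValueError("SVF must lie in [0, 1]")
    return swr_dir * dbt + swr_dif * svf


def max_potential_swr(zenith, tau_atm: float = 1.0) -> np.ndarray | float:
    """Maximum potential shortwave flux I₀·cos(θ)·τ_atm (W m⁻²).

    ``zenith`` in degrees; values at or beyond 90° yield 0 (night).
    """
    if not 0.0 < tau_atm <= 1.0:
        raise ValueError("atmospheric transmissivity must lie in (0, 1]")
    zen = np.asarray(zenith, dtype=float)
    flux = SOLAR_CONSTANT * np.cos(np.radians(zen)) * tau_atm
    flux = np.where(zen >= 90.0, 0.0, np.maximum(flux, 0.0))
    if np.isscalar(zenith):
        return float(flux)
    return flux
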