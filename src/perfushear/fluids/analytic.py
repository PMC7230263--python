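"""Closed-form plane-Poiseuille references for the empty channel.

For fully developed flow between parallel plates separated by h with volume
flow Q through a channel of width w, the velocity profile is

    u(z) = 6 U (z/h) (1 - z/h),   U = Q / (w h),

and the wall shear stress is tau_w = mu * du/dz |_{z=0} = 6 mu Q / (w h^2).
These are the normalization anchors for the nodule shear profiles.
"""

from __future__ import annotations

import numpy as np

from .geometry import ChannelGeometry, FluidProperties, InvalidParameterError

PA_TO_DYN_CM2 = 10.0


def mean_inlet_velocity(fluid: FluidProperties, geom: ChannelGeometry) -> float:
    """Cross-section mean velocity U = Q/(w h) in m/s.

    An explicitly supplied ``inlet_mean_velocity_U`` overrides the derived
    value.
    """
    if fluid.inlet_mean_velocity_U is not None:
        return fluid.inlet_mean_velocity_U
    area = geom.width_w * geom.height_h
    if area <= 0:
        raise InvalidParameterError("channel cross-section must be positive")
    return geom.flow_rate_Q / area


def analytic_wall_shear(fluid: FluidProperties, geom: ChannelGeometry) -> float:
    """Plane-Poiseuille wall shear stress tau_w = 6 mu Q/(w h^2), in Pa."""
    if geom.width_w <= 0 or geom.height_h <= 0:
        raise InvalidParameterError("channel dimensions must be positive")
    U = mean_inlet_velocity(fluid, geom)
    return 6.0 * fluid.viscosity_mu * U / geom.height_h


def wall_shear_dyn_cm2(fluid: FluidProperties, geom: ChannelGeometry) -> float:
    """Wall shear stress in dyn/cm² (1 Pa = 10 dyn/cm²)."""
    return analytic_wall_shear(fluid, geom) * PA_TO_DYN_CM2


def poiseuille_profile(z: np.ndarray, U: float, h: float) -> np.ndarray:
    """Fully developed velocity profile u(z) = 6U (z/h)(1 - z/h)."""
    zz = np.asarray(z, dtype=float) / h
    return 6.0 * U * zz * (1.0 - zz)
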