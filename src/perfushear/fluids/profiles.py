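"""Shear-stress and penetration-flux profiles on the nodule surface.

The exposed surface is the part of the ellipse above the channel floor,
parameterised by the polar angle t (t = pi/2 at the apex).  Shear is the
tangential velocity gradient along the outward normal, sigma = mu du_t/dn,
estimated from one-sided finite differences of the interpolated velocity
field just outside the surface, and reported both raw (Pa) and normalized by
the analytic plane-channel wall shear tau_w.  Flux is the normal velocity
component sampled just inside the porous nodule (where the flow is pure
Darcy seepage), signed positive into the nodule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytic import analytic_wall_shear
from .geometry import NoduleGeometry, PorousProperties, MeshSpec
from .solver import FlowField, solve_channel_flow

N_SURFACE_SAMPLES = 181


class UsageError(RuntimeError):
    """A profile was requested for a case it is not defined for."""


@dataclass
class ShearProfile:
    """Shear stress along the exposed nodule surface.

    arc_positions are polar angles t (radians, apex at pi/2); shear_raw is in
    Pa and shear_normalized = shear_raw / wall_shear_tau_w.
    """

    arc_positions: np.ndarray
    shear_raw: np.ndarray
    shear_normalized: np.ndarray
    wall_shear_tau_w: float

    @property
    def peak_normalized(self) -> float:
        return float(np.max(np.abs(self.shear_normalized)))

    def asymmetry(self) -> float:
        """max |sigma*(t) - sigma*(pi - t)| relative to the peak."""
        mirrored = self.shear_normalized[::-1]
        return float(np.max(np.abs(self.shear_normalized - mirrored))
                     / self.peak_normalized)


@dataclass
class FluxProfile:
    """Signed normal seepage velocity along the exposed surface (m/s).

    normal_flux > 0 means flow entering the nodule; scale_velocity is the
    maximum magnitude, the natural normalization for the profile.
    """

    arc_positions: np.ndarray
    normal_flux: np.ndarray
    scale_velocity: float
    arc_lengths: np.ndarray  # ds weights for surface integrals

    def net_flux(self) -> float:
        """Closed-surface flux integral (per unit depth, m²/s).

        The nodule boundary is the exposed arc plus its base on the no-slip
        floor, which carries no flow, so this is the full surface integral.
        """
        return float(np.trapezoid(self.normal_flux * self.arc_lengths,
                                  self.arc_positions)
                     / np.trapezoid(self.arc_lengths, self.arc_positions)
                     * self.total_arc_length())

    def total_arc_length(self) -> float:
        return float(np.trapezoid(self.arc_lengths, self.arc_positions))

    def net_flux_relative(self) -> float:
        """|net flux| relative to max|q| times the arc length."""
        denom = self.scale_velocity * self.total_arc_length()
        return abs(self.net_flux()) / denom if denom > 0 else 0.0


def _surface_frame(nodule: NoduleGeometry, n: int = N_SURFACE_SAMPLES):
    """Sample points, outward normals, tangents and ds on the exposed arc."""
    a, b, z0 = nodule.semi_major_a_x, nodule.semi_minor_b_z, nodule.center_z0
    # exposed points satisfy z = z0 + b sin(t) >= 0
    t0 = -np.arcsin(np.clip(z0 / b, -1.0, 1.0))
    t = np.linspace(t0, np.pi - t0, n)
    x = a * np.cos(t)
    z = z0 + b * np.sin(t)
    # outward normal ~ grad[(x/a)^2 + ((z-z0)/b)^2]
    nvec = np.column_stack([np.cos(t) / a, np.sin(t) / b])
    nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
    tvec = np.column_stack([-nvec[:, 1], nvec[:, 0]])
    ds = np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)  # |dr/dt|
    return t, np.column_stack([x, z]), nvec, tvec, ds


def shear_profile(field: FlowField, nodule: NoduleGeometry | None = None,
                  n_samples: int = N_SURFACE_SAMPLES) -> ShearProfile:
    """sigma(t) = mu du_t/dn on the exposed surface, normalized by tau_w."""
    nodule = nodule or field.nodule
    if nodule is None:
        raise UsageError("shear profile requested for an empty channel")
    mu = field.fluid.viscosity_mu
    t, pts, nvec, tvec, _ = _surface_frame(nodule, n_samples)
    delta = max(field.dx, field.dz)

    # quadratic fit through three samples just outside the surface,
    # extrapolating du_t/dn to the interface; no-slip is not assumed, so the
    # same estimator serves solid obstacles and permeable nodules (which
    # carry a genuine slip/seepage velocity at the interface)
    ut = [np.sum(field.velocity_at(pts + k * delta * nvec) * tvec, axis=1)
          for k in (1, 2, 3)]
    dudn = (-5.0 * ut[0] + 8.0 * ut[1] - 3.0 * ut[2]) / (2.0 * delta)

    sigma = mu * dudn
    tau_w = analytic_wall_shear(field.fluid, field.geom)
    return ShearProfile(arc_positions=t, shear_raw=sigma,
                        shear_normalized=sigma / tau_w,
                        wall_shear_tau_w=tau_w)


def flux_profile(field: FlowField, nodule: NoduleGeometry | None = None,
                 porous: PorousProperties | None = None,
                 n_samples: int = N_SURFACE_SAMPLES) -> FluxProfile:
    """Signed normal seepage velocity on the exposed surface of a porous nodule."""
    nodule = nodule or field.nodule
    porous = porous or field.porous
    if nodule is None:
        raise UsageError("flux profile requested for an empty channel")
    if porous is None or not porous.is_porous:
        raise UsageError("flux profile is defined only for porous nodules")
    t, pts, nvec, _, ds = _surface_frame(nodule, n_samples)
    # sample inside the nodule, clear of the interface cells, where the
    # velocity is the smooth Darcy seepage field
    delta_in = 2.0 * max(field.dx, field.dz)
    v = field.velocity_at(pts - delta_in * nvec)
    q = -np.sum(v * nvec, axis=1)  # positive into the nodule
    return FluxProfile(arc_positions=t, normal_flux=q,
                       scale_velocity=float(np.max(np.abs(q))),
                       arc_lengths=ds)


def sweep_nodule_geometry(
    a_values_um,
    porous_cases=("solid", "porous"),
    geom=None,
    fluid=None,
    porous_props: PorousProperties | None = None,
    mesh: MeshSpec | None = None,
    semi_minor_b_um: float = 40.0,
    protrusion_um: float = 60.0,
) -> pd.DataFrame:
    """Solve one case per (semi-major axis, porosity flag) and tabulate.

    Returns a DataFrame with one row per case: a_um, porous, peak normalized
    shear, flux scale velocity (porous only), residual and a failure flag.
    Solver failures are recorded per-row rather than aborting the sweep.
    """
    from .geometry import ChannelGeometry, FluidProperties

    geom = geom or ChannelGeometry.simulated_default()
    fluid = fluid or FluidProperties()
    porous_props = porous_props or PorousProperties()
    rows = []
    for a_um in a_values_um:
        nod = NoduleGeometry(semi_major_a_x=a_um * 1e-6,
                             semi_minor_b_z=semi_minor_b_um * 1e-6,
                             protrusion=protrusion_um * 1e-6)
        for case in porous_cases:
            props = porous_props if case == "porous" else PorousProperties.solid()
            row = {"a_um": float(a_um), "porous": case == "porous",
                   "peak_shear_normalized": np.nan, "scale_velocity": np.nan,
                   "residual": np.nan, "failed": False}
            try:
                fld = solve_channel_flow(geom, fluid, nod, props, mesh)
                row["residual"] = fld.residual
                row["peak_shear_normalized"] = shear_profile(fld).peak_normalized
                if case == "porous":
                    row["scale_velocity"] = flux_profile(fld).scale_velocity
            except Exception:
                row["failed"] = True
            rows.append(row)
    return pd.DataFrame(rows)
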