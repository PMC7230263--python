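"""Geometry and material parameter records for the microchannel flow model.

All quantities are SI internally (metres, seconds, Pa).  Constructors accept
SI values; convenience classmethods take the lab units the chip is specified
in (mm, µm, µL/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

UL_PER_MIN = 1e-9 / 60.0  # m^3/s per µL/min
UM = 1e-6


class InvalidParameterError(ValueError):
    """A geometry or fluid parameter violates its physical constraints."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Cross-section and flow-rate parameters of the perfusion channel.

    The channel is w wide (spanwise, out of the simulated XZ plane) and h
    tall; the 2D model solves a central section of length ``domain_length_x``
    far from the inlet/outlet ports so entrance effects are excluded.
    """

    width_w: float = 4e-3
    height_h: float = 254e-6
    domain_length_x: float = 2.2e-3
    flow_rate_Q: float = 2 * UL_PER_MIN

    def __post_init__(self) -> None:
        if self.width_w <= 0 or self.height_h <= 0 or self.domain_length_x <= 0:
            raise InvalidParameterError("channel dimensions must be positive")
        if self.flow_rate_Q < 0:
            raise InvalidParameterError("flow rate must be non-negative")

    @classmethod
    def chip_default(cls) -> "ChannelGeometry":
        """The physical chip: 4 mm x 254 µm, 2 µL/min."""
        return cls()

    @classmethod
    def simulated_default(cls) -> "ChannelGeometry":
        """The simulated central section: 250 µm channel height."""
        return cls(height_h=250e-6)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid parameters (water-like culture medium by default)."""

    viscosity_mu: float = 1.0e-3
    density_rho: float = 1000.0
    inlet_mean_velocity_U: float | None = None  # derived from Q if None
    outlet_pressure: float = 0.0  # gauge

    def __post_init__(self) -> None:
        if self.viscosity_mu <= 0 or self.density_rho <= 0:
            raise InvalidParameterError("viscosity and density must be positive")
        if self.inlet_mean_velocity_U is not None and self.inlet_mean_velocity_U < 0:
            raise InvalidParameterError("inlet velocity must be non-negative")


@dataclass(frozen=True)
class NoduleGeometry:
    """Elliptical tumor micronodule in the XZ plane.

    The nodule is an ellipse with semi-major axis a along the flow (X) and
    semi-minor axis b vertical (Z), centred at (0, z0) so that it protrudes
    ``protrusion = z0 + b`` above the channel floor.  The default matches a
    40 µm semi-minor axis with a 60 µm protrusion, i.e. centre (0, 20 µm).
    """

    semi_major_a_x: float = 40e-6
    semi_minor_b_z: float = 40e-6
    protrusion: float = 60e-6

    def __post_init__(self) -> None:
        a, b, p = self.semi_major_a_x, self.semi_minor_b_z, self.protrusion
        if b <= 0 or a < b * (1.0 - 1e-9):
            raise InvalidParameterError("require semi-major a >= semi-minor b > 0")
        if not (0 < p <= 2 * b):
            raise InvalidParameterError("protrusion must be in (0, 2b]")

    @property
    def center_z0(self) -> float:
        """Height of the ellipse centre above the floor (may be negative)."""
        return self.protrusion - self.semi_minor_b_z

    @classmethod
    def from_center(cls, a: float, b: float, z0: float) -> "NoduleGeometry":
        return cls(semi_major_a_x=a, semi_minor_b_z=b, protrusion=z0 + b)


@dataclass(frozen=True)
class PorousProperties:
    """Brinkman material parameters of a permeable nodule.

    permeability κ (m²) sets the Darcy drag µ/κ; porosity ε is carried for
    reporting.  ``solid()`` represents an impermeable nodule (realised in the
    solver by penalization with a vanishing permeability).
    """

    permeability_kappa: float = 1e-11
    porosity_eps: float = 0.3
    is_porous: bool = True

    SOLID_KAPPA = 1e-18

    def __post_init__(self) -> None:
        if self.is_porous:
            if self.permeability_kappa <= 0:
                raise InvalidParameterError("permeability must be positive")
            if not (0 < self.porosity_eps < 1):
                raise InvalidParameterError("porosity must be in (0, 1)")

    @classmethod
    def solid(cls) -> "PorousProperties":
        return cls(permeability_kappa=cls.SOLID_KAPPA, porosity_eps=0.3,
                   is_porous=False)

    @property
    def effective_kappa(self) -> float:
        """Permeability used by the solver (solid -> penalization value)."""
        return self.permeability_kappa if self.is_porous else self.SOLID_KAPPA


@dataclass(frozen=True)
class MeshSpec:
    """Uniform staggered-grid resolution and linear-solver tolerance."""

    target_cell_size: float = 2.5e-6
    refinement_levels: int = 0
    solver_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.target_cell_size <= 0 or self.solver_tolerance <= 0:
            raise InvalidParameterError("cell size and tolerance must be positive")
        if self.refinement_levels < 0:
            raise InvalidParameterError("refinement_levels must be >= 0")

    @property
    def cell_size(self) -> float:
        return self.target_cell_size / 2 ** self.refinement_levels
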