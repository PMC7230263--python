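"""Steady Stokes flow in the channel section with an optional Brinkman nodule.

The model is the 2D XZ-plane Stokes problem

    mu lap(u) - (mu/kappa(x)) u - grad p = 0,    div u = 0,

on a rectangle of length Lx and height h, discretised on a uniform staggered
(MAC) grid: u on vertical cell faces, w on horizontal faces, p at cell
centres.  MAC staggering is inf-sup stable, so no pressure stabilisation is
needed, and the discrete divergence is enforced exactly per cell.

Boundary conditions: no-slip floor/ceiling, fully developed parabolic inlet
with mean velocity U, zero gauge pressure at the outlet (one-sided pressure
closure, exact for developed flow).  The nodule — an ellipse centred on the
channel floor region — enters through the Darcy drag mu/kappa evaluated at
face centres: a porous nodule uses its physical permeability, a solid nodule
a vanishing penalization permeability, which drives the interior velocity to
zero and recovers the no-slip obstacle.

The linear system is solved with a sparse direct factorisation, so the result
is deterministic for a given MeshSpec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .analytic import mean_inlet_velocity, poiseuille_profile
from .geometry import (
    ChannelGeometry,
    FluidProperties,
    InvalidParameterError,
    MeshSpec,
    NoduleGeometry,
    PorousProperties,
)


class SolverFailureError(RuntimeError):
    """The linear solve did not reach the requested residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


@dataclass
class FlowField:
    """Discrete velocity/pressure solution on the staggered grid.

    u has shape (nx+1, nz) on x-faces, w has shape (nx, nz+1) on z-faces and
    p has shape (nx, nz) at cell centres.  ``nodule_center_x`` is the x
    coordinate of the nodule centre in grid coordinates (the nodule frame
    puts its centre at x = 0; profiles subtract this offset).
    """

    u: np.ndarray
    w: np.ndarray
    p: np.ndarray
    dx: float
    dz: float
    geom: ChannelGeometry
    fluid: FluidProperties
    nodule: NoduleGeometry | None
    porous: PorousProperties | None
    nodule_center_x: float
    converged: bool
    residual: float

    @property
    def nx(self) -> int:
        return self.p.shape[0]

    @property
    def nz(self) -> int:
        return self.p.shape[1]

    def interpolators(self):
        """(u_interp, w_interp) bilinear interpolators taking (x, z) pairs."""
        from scipy.interpolate import RegularGridInterpolator

        xu = np.arange(self.nx + 1) * self.dx
        zu = (np.arange(self.nz) + 0.5) * self.dz
        xw = (np.arange(self.nx) + 0.5) * self.dx
        zw = np.arange(self.nz + 1) * self.dz
        ui = RegularGridInterpolator((xu, zu), self.u, bounds_error=False,
                                     fill_value=None)
        wi = RegularGridInterpolator((xw, zw), self.w, bounds_error=False,
                                     fill_value=None)
        return ui, wi

    def velocity_at(self, points: np.ndarray) -> np.ndarray:
        """Velocity vectors (u, w) at (N, 2) points given in nodule-centred x."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        pts[:, 0] += self.nodule_center_x
        ui, wi = self.interpolators()
        return np.column_stack([ui(pts), wi(pts)])

    def cross_section_flux(self, i: int) -> float:
        """Volume flux per unit depth through x-face column i (m²/s)."""
        return float(np.sum(self.u[i, :]) * self.dz)

    def floor_shear(self, x: float | None = None) -> float:
        """Wall shear at the channel floor, mu*du/dz|_{z=0}, at position x.

        Uses a quadratic fit through the wall (u=0) and the first two u
        samples, exact for a parabolic profile.
        """
        i = self.nx // 2 if x is None else int(round(x / self.dx))
        i = min(max(i, 0), self.nx)
        u0, u1 = self.u[i, 0], self.u[i, 1]
        return float(self.fluid.viscosity_mu * (9.0 * u0 - u1) / (3.0 * self.dz))


def _drag_mask(x: np.ndarray, z: np.ndarray, nodule: NoduleGeometry | None,
               kappa: float, mu: float, x0: float) -> np.ndarray:
    """Darcy drag coefficient mu/kappa at the given face centres."""
    d = np.zeros(np.broadcast(x, z).shape)
    if nodule is None:
        return d
    a, b, z0 = nodule.semi_major_a_x, nodule.semi_minor_b_z, nodule.center_z0
    inside = ((x - x0) / a) ** 2 + ((z - z0) / b) ** 2 <= 1.0
    d[inside] = mu / kappa
    return d


def solve_channel_flow(
    geom: ChannelGeometry,
    fluid: FluidProperties,
    nodule: NoduleGeometry | None = None,
    porous: PorousProperties | None = None,
    mesh: MeshSpec | None = None,
) -> FlowField:
    """Solve the channel Stokes(-Brinkman) problem on a staggered grid."""
    mesh = mesh or MeshSpec()
    h = geom.height_h
    Lx = geom.domain_length_x
    mu = fluid.viscosity_mu
    U = mean_inlet_velocity(fluid, geom)

    if nodule is not None:
        if nodule.protrusion > h:
            raise InvalidParameterError("nodule protrudes above the channel")
        if geom.domain_length_x < 10 * nodule.semi_major_a_x:
            raise InvalidParameterError(
                "domain must be at least 10 semi-major axes long")
        if mesh.cell_size > nodule.semi_minor_b_z / 10:
            raise InvalidParameterError(
                "mesh cell size must resolve the nodule (<= b/10)")

    nz = max(int(round(h / mesh.cell_size)), 4)
    nx = int(round(Lx / mesh.cell_size))
    nx += nx % 2  # even cell count keeps the grid mirror-symmetric about Lx/2
    dx, dz = Lx / nx, h / nz
    x0 = Lx / 2.0  # nodule centre in grid coordinates

    kappa = (porous or PorousProperties.solid()).effective_kappa
    if nodule is None:
        kappa = np.inf

    n_u = (nx + 1) * nz
    n_w = nx * (nz + 1)
    n_p = nx * nz
    off_w = n_u
    off_p = n_u + n_w
    n_tot = n_u + n_w + n_p

    def iu(i, j):
        return i * nz + j

    def iw(i, j):
        return off_w + i * (nz + 1) + j

    def ip(i, j):
        return off_p + i * nz + j

    rows, cols, vals = [], [], []
    b = np.zeros(n_tot)

    def add(r, c, v):
        rows.append(np.ravel(r))
        cols.append(np.ravel(c))
        vals.append(np.ravel(np.broadcast_to(v, np.shape(r))))

    cdx2, cdz2 = mu / dx ** 2, mu / dz ** 2

    # ---- u momentum -----------------------------------------------------
    jj = np.arange(nz)
    zj = (jj + 0.5) * dz

    # inlet Dirichlet: parabolic profile
    r = iu(0, jj)
    add(r, r, 1.0)
    b[r] = poiseuille_profile(zj, U, h)

    # interior and outlet faces
    for part in ("interior", "outlet"):
        if part == "interior":
            ii = np.arange(1, nx)
        else:
            ii = np.array([nx])
        I, J = np.meshgrid(ii, jj, indexing="ij")
        xf = I * dx
        zf = (J + 0.5) * dz
        d = _drag_mask(xf, zf, nodule, kappa, mu, x0) if np.isfinite(kappa) \
            else np.zeros(I.shape)
        r = iu(I, J)
        center = -2.0 * cdz2 - d
        center = center + np.where(J == 0, -cdz2, 0.0)       # floor ghost
        center = center + np.where(J == nz - 1, -cdz2, 0.0)  # ceiling ghost
        if part == "interior":
            center = center - 2.0 * cdx2
            add(r, iu(I + 1, J), cdx2)
            add(r, iu(I - 1, J), cdx2)
            add(r, ip(I, J), -1.0 / dx)
            add(r, ip(I - 1, J), 1.0 / dx)
        else:
            # one-sided: du/dx = 0 ghost east, p = 0 at the outlet boundary
            center = center - cdx2
            add(r, iu(I - 1, J), cdx2)
            add(r, ip(I - 1, J), 2.0 / dx)
        # z neighbours (skip beyond walls)
        m = J < nz - 1
        add(r[m], iu(I, J + 1)[m], cdz2)
        m = J > 0
        add(r[m], iu(I, J - 1)[m], cdz2)
        add(r, r, center)

    # ---- w momentum -----------------------------------------------------
    ii = np.arange(nx)
    # wall rows: w = 0 at floor and ceiling
    for jwall in (0, nz):
        r = iw(ii, jwall)
        add(r, r, 1.0)

    I, J = np.meshgrid(ii, np.arange(1, nz), indexing="ij")
    xf = (I + 0.5) * dx
    zf = J * dz
    d = _drag_mask(xf, zf, nodule, kappa, mu, x0) if np.isfinite(kappa) \
        else np.zeros(I.shape)
    r = iw(I, J)
    center = -2.0 * cdz2 - d - 2.0 * cdx2
    center = center + np.where(I == 0, -cdx2, 0.0)       # inlet ghost (w=0)
    center = center + np.where(I == nx - 1, cdx2, 0.0)   # outlet ghost (dw/dx=0)
    m = I < nx - 1
    add(r[m], iw(I + 1, J)[m], cdx2)
    m = I > 0
    add(r[m], iw(I - 1, J)[m], cdx2)
    add(r, iw(I, J + 1), cdz2)
    add(r, iw(I, J - 1), cdz2)
    add(r, ip(I, J), -1.0 / dz)
    add(r, ip(I, J - 1), 1.0 / dz)
    add(r, r, center)

    # ---- continuity ------------------------------------------------------
    I, J = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
    r = ip(I, J)
    add(r, iu(I + 1, J), 1.0 / dx)
    add(r, iu(I, J), -1.0 / dx)
    add(r, iw(I, J + 1), 1.0 / dz)
    add(r, iw(I, J), -1.0 / dz)

    A = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_tot, n_tot),
    )
    x = spla.spsolve(A, b)

    # backward-error style scaling: ||Ax-b|| / (||A|| ||x|| + ||b||)
    scale = spla.norm(A, np.inf) * np.linalg.norm(x, np.inf) + \
        np.linalg.norm(b, np.inf)
    residual = float(np.linalg.norm(A @ x - b, np.inf) / (scale or 1.0))
    converged = residual <= max(mesh.solver_tolerance, 1e-30)
    if not converged and residual > 1e-4:
        raise SolverFailureError("sparse direct solve failed", residual)

    u = x[:n_u].reshape(nx + 1, nz)
    w = x[off_w:off_p].reshape(nx, nz + 1)
    p = x[off_p:].reshape(nx, nz)
    return FlowField(u=u, w=w, p=p, dx=dx, dz=dz, geom=geom, fluid=fluid,
                     nodule=nodule, porous=porous, nodule_center_x=x0,
                     converged=converged, residual=residual)
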