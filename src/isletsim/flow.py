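"""Steady incompressible flow in the perifusion channel.

Momentum balance and continuity (incompressible Newtonian medium) are
discretized on a staggered (MAC) grid matching the transport mesh:
x-velocities on vertical faces, y-velocities on horizontal faces, pressure
at cell centers. Islet and capsule interiors are rendered impermeable by a
large Brinkman drag (velocities there are pinned to zero after the solve);
an optional mode instead lets medium seep through the capsule with a finite
Brinkman permeability.

At perifusion conditions the Reynolds number is ≪ 10, so the transient term
is dropped and the flow solved once (Stokes by default); a Picard-iterated
Navier–Stokes variant is available for cross-checks.

Boundary conditions: fully developed parabolic inlet profile at the
prescribed mean speed, no-slip walls, zero-normal-stress outlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CAPSULE, ISLET, LabeledMesh
from .params import FluidProps

class FlowSolveError(RuntimeError):
    """Flow solver failed to converge."""


def mean_speed_from_flow_rate(flow_rate: float, column_diameter: float) -> float:
    """Mean axial speed [m/s] for a volumetric flow through a circular bore.

    E.g. 100 μL/min through a 1.0 mm column gives 2.12 × 10⁻³ m/s.
    """
    if column_diameter <= 0:
        raise ValueError("column diameter must be > 0")
    if flow_rate < 0:
        raise ValueError("flow rate must be >= 0")
    area = math.pi * (column_diameter / 2.0) ** 2
    return flow_rate / area


@dataclass
class VelocityField:
    """Discrete steady flow solution on the MAC grid.

    ``u`` has shape (ny, nx+1) on vertical faces, ``v`` (ny+1, nx) on
    horizontal faces, ``p`` (ny, nx) at cell centers.
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    mean_inlet_speed: float
    h: float

    def divergence(self) -> np.ndarray:
        """Cell-wise discrete divergence [1/s]."""
        return (self.u[:, 1:] - self.u[:, :-1] + self.v[1:, :] - self.v[:-1, :]) / self.h

    def max_speed(self) -> float:
        return max(float(np.abs(self.u).max()), float(np.abs(self.v).max()))

    def inlet_flux(self) -> float:
        """Volumetric flux per unit depth through the inlet [m²/s]."""
        return float(self.u[:, 0].sum() * self.h)

    def outlet_flux(self) -> float:
        return float(self.u[:, -1].sum() * self.h)

    def cell_center_velocity(self):
        """(u, v) averaged to cell centers, for export/inspection."""
        uc = 0.5 * (self.u[:, 1:] + self.u[:, :-1])
        vc = 0.5 * (self.v[1:, :] + self.v[:-1, :])
        return uc, vc


def _drag_and_solid(mesh: LabeledMesh, fluid: FluidProps, capsule_flow: bool,
                    capsule_permeability: float):
    """Per-cell Brinkman drag σ [Pa·s·m⁻²] and impermeable-cell mask.

    Islets are always impermeable (velocity unknowns eliminated by
    Dirichlet rows); capsules are impermeable by default but become a
    Brinkman porous medium in the exploratory seepage mode.
    """
    sigma = np.zeros((mesh.ny, mesh.nx))
    solid = mesh.labels == ISLET
    if capsule_flow:
        sigma[mesh.labels == CAPSULE] = fluid.eta / capsule_permeability
    else:
        solid = solid | (mesh.labels == CAPSULE)
    return sigma, solid


def solve_flow(
    mesh: LabeledMesh,
    fluid: FluidProps,
    mean_inlet_speed: float,
    model: str = "stokes",
    capsule_flow: bool = False,
    capsule_permeability: float = 1e-14,
    picard_tol: float = 1e-10,
    picard_maxiter: int = 30,
) -> VelocityField:
    """Solve the steady flow problem on the labeled mesh.

    ``model``: "stokes" (linear, one solve) or "navier-stokes" (Picard
    iteration on the upwinded convective term).
    """
    nx, ny, h = mesh.nx, mesh.ny, mesh.h
    eta = fluid.eta
    sigma, solid = _drag_and_solid(mesh, fluid, capsule_flow, capsule_permeability)
    # faces touching an impermeable cell carry Dirichlet zero velocity
    u_solid = np.zeros((ny, nx + 1), dtype=bool)
    u_solid[:, 1:] |= solid
    u_solid[:, :-1] |= solid
    v_solid = np.zeros((ny + 1, nx), dtype=bool)
    v_solid[1:, :] |= solid
    v_solid[:-1, :] |= solid

    nu = ny * (nx + 1)
    nv = (ny + 1) * nx
    npp = ny * nx

    def iu(j, i):
        return j * (nx + 1) + i

    def iv(j, i):
        return nu + j * nx + i

    def ip(j, i):
        return nu + nv + j * nx + i

    # parabolic inlet profile, mean = mean_inlet_speed
    yy = (np.arange(ny) + 0.5) / ny
    u_in = 6.0 * mean_inlet_speed * yy * (1.0 - yy)

    def assemble(u_prev=None, v_prev=None):
        rows, cols, vals = [], [], []
        rhs = np.zeros(nu + nv + npp)

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        visc = eta / h**2

        # --- u-momentum -------------------------------------------------
        for j in range(ny):
            for i in range(nx + 1):
                r = iu(j, i)
                if i == 0:  # inlet Dirichlet
                    add(r, r, 1.0)
                    rhs[r] = u_in[j]
                    continue
                if u_solid[j, i]:  # impermeable subdomain: u = 0
                    add(r, r, 1.0)
                    continue
                sig = sigma[j, i - 1] if i == nx else max(sigma[j, i - 1], sigma[j, i])
                diag = 4.0 * visc + sig
                # east neighbor (outlet ghost: copy -> reduces diagonal)
                if i + 1 <= nx:
                    add(r, iu(j, i + 1), -visc)
                else:
                    diag -= visc
                add(r, iu(j, i - 1), -visc)
                # north/south (wall ghost: reflection -> adds to diagonal)
                if j + 1 <= ny - 1:
                    add(r, iu(j + 1, i), -visc)
                else:
                    diag += visc
                if j - 1 >= 0:
                    add(r, iu(j - 1, i), -visc)
                else:
                    diag += visc
                # pressure gradient
                if i <= nx - 1:
                    add(r, ip(j, i), 1.0 / h)
                    add(r, ip(j, i - 1), -1.0 / h)
                else:  # outlet: zero normal stress (mean face pressure 0)
                    add(r, ip(j, i - 1), -2.0 / h)
                # convection (Picard-linearized, first-order upwind)
                if u_prev is not None:
                    a = u_prev[j, i]
                    ie = min(i, nx - 1)
                    b = 0.25 * (
                        v_prev[j, i - 1]
                        + v_prev[j + 1, i - 1]
                        + v_prev[j, ie]
                        + v_prev[j + 1, ie]
                    )
                    rho = fluid.rho
                    ap, am = max(a, 0.0), min(a, 0.0)
                    bp, bm = max(b, 0.0), min(b, 0.0)
                    diag += rho * (ap - am + bp - bm) / h
                    add(r, iu(j, i - 1), -rho * ap / h)
                    if i + 1 <= nx:
                        add(r, iu(j, i + 1), rho * am / h)
                    else:
                        diag += rho * am / h
                    if j - 1 >= 0:
                        add(r, iu(j - 1, i), -rho * bp / h)
                    else:
                        diag += rho * bp / h  # ghost = -self
                    if j + 1 <= ny - 1:
                        add(r, iu(j + 1, i), rho * bm / h)
                    else:
                        diag -= rho * bm / h
                add(r, r, diag)

        # --- v-momentum -------------------------------------------------
        for j in range(ny + 1):
            for i in range(nx):
                r = iv(j, i)
                if j == 0 or j == ny:  # walls
                    add(r, r, 1.0)
                    continue
                if v_solid[j, i]:  # impermeable subdomain: v = 0
                    add(r, r, 1.0)
                    continue
                sig = max(sigma[j - 1, i], sigma[j, i])
                diag = 4.0 * visc + sig
                if i + 1 <= nx - 1:
                    add(r, iv(j, i + 1), -visc)
                else:  # outlet ghost copy
                    diag -= visc
                if i - 1 >= 0:
                    add(r, iv(j, i - 1), -visc)
                else:  # inlet: v = 0 plane, reflection ghost
                    diag += visc
                add(r, iv(j + 1, i), -visc)
                add(r, iv(j - 1, i), -visc)
                add(r, ip(j, i), 1.0 / h)
                add(r, ip(j - 1, i), -1.0 / h)
                if u_prev is not None:
                    a = 0.25 * (
                        u_prev[j - 1, i]
                        + u_prev[j - 1, i + 1]
                        + u_prev[j, i]
                        + u_prev[j, i + 1]
                    )
                    b = v_prev[j, i]
                    rho = fluid.rho
                    ap, am = max(a, 0.0), min(a, 0.0)
                    bp, bm = max(b, 0.0), min(b, 0.0)
                    diag += rho * (ap - am + bp - bm) / h
                    if i - 1 >= 0:
                        add(r, iv(j, i - 1), -rho * ap / h)
                    else:
                        diag += rho * ap / h
                    if i + 1 <= nx - 1:
                        add(r, iv(j, i + 1), rho * am / h)
                    else:
                        diag += rho * am / h
                    add(r, iv(j - 1, i), -rho * bp / h)
                    add(r, iv(j + 1, i), rho * bm / h)
                add(r, r, diag)

        # --- continuity ---------------------------------------------------
        for j in range(ny):
            for i in range(nx):
                r = ip(j, i)
                if solid[j, i]:
                    # all faces pinned; pressure unused -> pin to zero
                    add(r, r, 1.0)
                    continue
                add(r, iu(j, i + 1), 1.0)
                add(r, iu(j, i), -1.0)
                add(r, iv(j + 1, i), 1.0)
                add(r, iv(j, i), -1.0)

        A = sp.csc_matrix(
            (vals, (rows, cols)), shape=(nu + nv + npp, nu + nv + npp)
        )
        return A, rhs

    def split(x):
        u = x[:nu].reshape(ny, nx + 1)
        v = x[nu : nu + nv].reshape(ny + 1, nx)
        p = x[nu + nv :].reshape(ny, nx)
        return u, v, p

    def refined_solve(A, rhs):
        """Direct solve plus residual-monitored iterative refinement."""
        lu = spla.splu(A)
        x = lu.solve(rhs)
        scale = max(float(np.linalg.norm(rhs)), 1e-300)
        best = x
        best_res = float(np.linalg.norm(rhs - A @ x)) / scale
        for _ in range(2):
            r = rhs - A @ x
            x = x + lu.solve(r)
            res = float(np.linalg.norm(rhs - A @ x)) / scale
            if res < best_res:
                best, best_res = x, res
            else:
                break
        if not np.all(np.isfinite(best)):
            raise FlowSolveError("flow solve produced non-finite values")
        return best

    A, rhs = assemble()
    x = refined_solve(A, rhs)
    u, v, p = split(x)

    if model == "navier-stokes":
        for it in range(picard_maxiter):
            A, rhs = assemble(u_prev=u, v_prev=v)
            x_new = refined_solve(A, rhs)
            du = np.linalg.norm(x_new - x) / max(np.linalg.norm(x_new), 1e-300)
            x = x_new
            u, v, p = split(x)
            if du < picard_tol:
                break
        else:
            res = du  # noqa: F821 - loop ran at least once
            raise FlowSolveError(
                f"Navier-Stokes Picard iteration did not converge "
                f"(relative update {res:.2e} after {picard_maxiter} iterations)"
            )
    elif model != "stokes":
        raise ValueError(f"unknown flow model {model!r}")

    # pin velocities in/around impermeable subdomains to exactly zero
    solid = mesh.labels == ISLET
    if not capsule_flow:
        solid = solid | (mesh.labels == CAPSULE)
    u_solid = np.zeros((ny, nx + 1), dtype=bool)
    u_solid[:, 1:] |= solid
    u_solid[:, :-1] |= solid
    v_solid = np.zeros((ny + 1, nx), dtype=bool)
    v_solid[1:, :] |= solid
    v_solid[:-1, :] |= solid
    u = np.where(u_solid, 0.0, u)
    v = np.where(v_solid, 0.0, v)

    return VelocityField(u=u, v=v, p=p, mean_inlet_speed=mean_inlet_speed, h=h)
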