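"""Plane-stress finite-element check of the graded-beam analytical model.

A small structured solver for the four-point-bent beam: 4-node bilinear
quadrilaterals, isotropic plane stress with the through-thickness graded
modulus sampled at element centroids, simply supported at the outer
contacts with the machine load split over the two inner contacts.  The
neutral axis is never imposed — it emerges from the displacement solution
as the zero line of the longitudinal strain, and is compared against the
analytical prediction at mid-span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve

from .core import (
    GradientModulusModel,
    NeutralAxisState,
    SpecimenGeometry,
    load_from_stress,
    modulus_profile,
)

__all__ = [
    "BeamMesh",
    "FemResult",
    "build_mesh",
    "assemble_and_solve",
    "extract_neutral_axis",
    "compare_fem_analytical",
]

# 2x2 Gauss rule
_GP = 1.0 / np.sqrt(3.0)
_GAUSS = [(-_GP, -_GP), (_GP, -_GP), (_GP, _GP), (-_GP, _GP)]


@dataclass(frozen=True)
class BeamMesh:
    """Structured quad mesh over the beam's side face (length x height, mm)."""

    geom: SpecimenGeometry
    nx: int
    ny: int
    length: float
    nodes: np.ndarray  # (n_nodes, 2)
    elements: np.ndarray  # (n_elem, 4) counter-clockwise connectivity
    contact_x: tuple[float, float, float, float]  # outer-L, inner-L, inner-R, outer-R

    @property
    def dx(self) -> float:
        return self.length / self.nx

    @property
    def dy(self) -> float:
        return self.geom.height_h / self.ny

    def node_id(self, ix: int, iy: int) -> int:
        return iy * (self.nx + 1) + ix

    def element_of(self, x: float, y: float) -> tuple[int, int]:
        ix = min(max(int(x / self.dx), 0), self.nx - 1)
        iy = min(max(int(y / self.dy), 0), self.ny - 1)
        return ix, iy

    def element_centroid_y(self, iy: int) -> float:
        return (iy + 0.5) * self.dy


def build_mesh(geom: SpecimenGeometry, nx: int, ny: int) -> BeamMesh:
    """Uniform structured grid over (outer span) x (height).

    The four contact x-positions (0, a, a+b, 2a+b) must fall on node
    columns, which requires nx * a / L to be an integer; ny must be even so
    a node row lies at mid-depth.
    """
    if nx < 2 or ny < 2:
        raise ValueError("nx and ny must be >= 2")
    if ny % 2:
        raise ValueError("ny must be even so a node row lies at mid-depth")
    L = geom.outer_span
    a = geom.lever_arm_a
    dx = L / nx
    for xc in (a, L - a):
        steps = xc / dx
        if abs(steps - round(steps)) > 1e-9:
            from fractions import Fraction

            q = Fraction(a / L).limit_denominator(10**6).denominator
            raise ValueError(
                f"contact at x={xc} mm is not a mesh node with nx={nx}; "
                f"choose nx as a multiple of {q}"
            )
    xs = np.linspace(0.0, L, nx + 1)
    ys = np.linspace(0.0, geom.height_h, ny + 1)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    elems = np.empty((nx * ny, 4), dtype=int)
    e = 0
    for iy in range(ny):
        for ix in range(nx):
            n0 = iy * (nx + 1) + ix
            elems[e] = (n0, n0 + 1, n0 + nx + 2, n0 + nx + 1)
            e += 1
    return BeamMesh(
        geom=geom,
        nx=nx,
        ny=ny,
        length=L,
        nodes=nodes,
        elements=elems,
        contact_x=(0.0, a, L - a, L),
    )


def _q4_stiffness(dx: float, dy: float, D: np.ndarray, thickness: float) -> np.ndarray:
    """Stiffness of one rectangular bilinear quad (8x8)."""
    K = np.zeros((8, 8))
    for xi, eta in _GAUSS:
        B = _b_matrix(xi, eta, dx, dy)
        K += B.T @ D @ B * (dx * dy / 4.0) * thickness
    return K


def _b_matrix(xi: float, eta: float, dx: float, dy: float) -> np.ndarray:
    # shape-function derivatives on a dx-by-dy rectangle
    dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    dN_dx = dN_dxi * 2.0 / dx
    dN_dy = dN_deta * 2.0 / dy
    B = np.zeros((3, 8))
    B[0, 0::2] = dN_dx
    B[1, 1::2] = dN_dy
    B[2, 0::2] = dN_dy
    B[2, 1::2] = dN_dx
    return B


def _plane_stress_D(E: float, nu: float) -> np.ndarray:
    c = E / (1.0 - nu * nu)
    return c * np.array([[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]])


@dataclass(frozen=True)
class FemResult:
    """Displacement solution with strain-evaluation helpers and extracts."""

    mesh: BeamMesh
    displacements: np.ndarray  # (n_nodes, 2)
    element_E: np.ndarray
    nu: float
    load_F: float
    reaction_sum_y: float
    neutral_axis_height: float  # mm from the bottom face, at mid-span
    surface_strain_top: float  # eps_xx at the top (compression) surface, mid-span
    surface_strain_bottom: float

    def eval_strain_xx(self, x: float, y: float) -> float:
        """Longitudinal strain from the bilinear field at a physical point."""
        m = self.mesh
        ix, iy = m.element_of(x, y)
        xc, yc = (ix + 0.5) * m.dx, (iy + 0.5) * m.dy
        xi = 2.0 * (x - xc) / m.dx
        eta = 2.0 * (y - yc) / m.dy
        conn = m.elements[iy * m.nx + ix]
        ue = self.displacements[conn].ravel()
        B = _b_matrix(np.clip(xi, -1, 1), np.clip(eta, -1, 1), m.dx, m.dy)
        return float(B[0] @ ue)


def _strain_column(mesh: BeamMesh, u: np.ndarray, x_station: float) -> tuple[np.ndarray, np.ndarray]:
    """eps_xx sampled at element-centroid heights in the element column
    whose center is nearest x_station (centroid-x sampling avoids the
    inter-element strain jump of bilinear quads)."""
    ix = min(max(int(round(x_station / mesh.dx - 0.5)), 0), mesh.nx - 1)
    xc = (ix + 0.5) * mesh.dx
    ys = np.array([mesh.element_centroid_y(iy) for iy in range(mesh.ny)])
    eps = np.empty(mesh.ny)
    for iy in range(mesh.ny):
        conn = mesh.elements[iy * mesh.nx + ix]
        ue = u[conn].ravel()
        B = _b_matrix(0.0, 0.0, mesh.dx, mesh.dy)
        eps[iy] = B[0] @ ue
    return ys, eps


def _surface_strain(mesh: BeamMesh, u: np.ndarray, x_station: float, top: bool) -> float:
    ix = min(max(int(round(x_station / mesh.dx - 0.5)), 0), mesh.nx - 1)
    iy = mesh.ny - 1 if top else 0
    conn = mesh.elements[iy * mesh.nx + ix]
    ue = u[conn].ravel()
    B = _b_matrix(0.0, 1.0 if top else -1.0, mesh.dx, mesh.dy)
    return float(B[0] @ ue)


def assemble_and_solve(
    mesh: BeamMesh,
    model: GradientModulusModel,
    axis: NeutralAxisState,
    load_F: float,
    nu: float = 0.3,
) -> FemResult:
    """Assemble and solve the four-point-bending plane-stress problem.

    Element moduli come from the graded profile evaluated at the element
    centroid's height relative to the analytically located neutral axis
    (``axis.h_T`` above the bottom face); the FEM itself never imposes that
    axis.  Outer contacts are simply supported (vertical at both, horizontal
    at the left), and ``load_F/2`` presses down on each inner contact.
    """
    if load_F <= 0:
        raise ValueError("load_F must be > 0")
    geom = mesh.geom
    n_nodes = mesh.nodes.shape[0]
    ndof = 2 * n_nodes
    y_axis = axis.h_T  # neutral-axis height above the bottom face

    # per-row element modulus (E varies only through the thickness)
    row_E = np.array(
        [
            modulus_profile(model, mesh.element_centroid_y(iy) - y_axis)
            for iy in range(mesh.ny)
        ]
    )
    element_E = np.repeat(row_E, mesh.nx)

    # one template stiffness per distinct modulus row
    rows_i, cols_i, data = [], [], []
    K_rows = [
        _q4_stiffness(mesh.dx, mesh.dy, _plane_stress_D(E, nu), geom.width_w)
        for E in row_E
    ]
    for e, conn in enumerate(mesh.elements):
        Ke = K_rows[e // mesh.nx]
        dofs = np.column_stack([2 * conn, 2 * conn + 1]).ravel()
        ii, jj = np.meshgrid(dofs, dofs, indexing="ij")
        rows_i.append(ii.ravel())
        cols_i.append(jj.ravel())
        data.append(Ke.ravel())
    K = coo_matrix(
        (np.concatenate(data), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(ndof, ndof),
    ).tocsr()

    f = np.zeros(ndof)
    x_left_in, x_right_in = mesh.contact_x[1], mesh.contact_x[2]
    top_iy = mesh.ny
    for xc in (x_left_in, x_right_in):
        ix = int(round(xc / mesh.dx))
        f[2 * mesh.node_id(ix, top_iy) + 1] = -load_F / 2.0

    # supports: bottom nodes at the outer contacts
    n_left = mesh.node_id(0, 0)
    n_right = mesh.node_id(mesh.nx, 0)
    fixed = [2 * n_left, 2 * n_left + 1, 2 * n_right + 1]
    free = np.setdiff1d(np.arange(ndof), fixed)

    u = np.zeros(ndof)
    K_ff: csr_matrix = K[free][:, free]
    u[free] = spsolve(K_ff, f[free])
    if not np.all(np.isfinite(u)):
        raise RuntimeError("singular system: check boundary conditions")

    reactions = K @ u - f
    reaction_sum_y = float(reactions[[2 * n_left + 1, 2 * n_right + 1]].sum())

    u2 = u.reshape(-1, 2)
    x_mid = mesh.length / 2.0
    ys, eps = _strain_column(mesh, u2, x_mid)
    na_height = _zero_crossing_height(ys, eps)
    return FemResult(
        mesh=mesh,
        displacements=u2,
        element_E=element_E,
        nu=nu,
        load_F=load_F,
        reaction_sum_y=reaction_sum_y,
        neutral_axis_height=na_height,
        surface_strain_top=_surface_strain(mesh, u2, x_mid, top=True),
        surface_strain_bottom=_surface_strain(mesh, u2, x_mid, top=False),
    )


def _zero_crossing_height(ys: np.ndarray, eps: np.ndarray) -> float:
    sign_change = np.nonzero(np.diff(np.sign(eps)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("no strain sign change through the thickness (no neutral axis)")
    i = int(sign_change[0])
    y0, y1, e0, e1 = ys[i], ys[i + 1], eps[i], eps[i + 1]
    return float(y0 + (0.0 - e0) * (y1 - y0) / (e1 - e0))


def extract_neutral_axis(result: FemResult, x_station: float) -> float:
    """Height (mm from the bottom face) of the eps_xx = 0 line at x_station."""
    m = result.mesh
    inner_lo, inner_hi = m.contact_x[1], m.contact_x[2]
    if not inner_lo <= x_station <= inner_hi:
        raise ValueError(
            f"x_station={x_station} outside the pure-bending inner span "
            f"[{inner_lo}, {inner_hi}]"
        )
    ys, eps = _strain_column(m, result.displacements, x_station)
    return _zero_crossing_height(ys, eps)


def compare_fem_analytical(
    traj_result,
    nx: int = 126,
    ny: int = 24,
    nu: float = 0.3,
) -> pd.DataFrame:
    """FEM vs analytical neutral-axis height per life fraction.

    For every solved state of a trajectory the graded model feeds an
    independent FEM solve; deviation_pct is the height difference in percent
    of the section height.
    """
    cfg = traj_result.config
    geom = cfg.geometry
    mesh = build_mesh(geom, nx, ny)
    F = load_from_stress(cfg.measurement_stress, geom)
    rows = []
    for s in traj_result.states:
        fem = assemble_and_solve(mesh, s.model, s.axis, F, nu=nu)
        h_T_fem = fem.neutral_axis_height
        rows.append(
            (
                s.strain.life_fraction_t,
                s.axis.h_T,
                h_T_fem,
                100.0 * (h_T_fem - s.axis.h_T) / geom.height_h,
            )
        )
    return pd.DataFrame(
        rows, columns=["t", "h_T_analytical_mm", "h_T_fem_mm", "deviation_pct"]
    )
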