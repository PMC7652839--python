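"""Plane-stress finite elements on structured quad meshes.

Bilinear quadrilateral elements with per-element out-of-plane thickness.
Every element is a congruent axis-aligned square of side ``pixel_size``, so
one reference stiffness matrix (unit thickness) serves the whole mesh and
assembly reduces to a thickness-weighted scatter.  Stresses are evaluated
at element centroids, where the bilinear strain field is its own average
(the optimal sampling point for this element).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve

from .plate_model import MaterialParams, PlateMesh


class SolverError(RuntimeError):
    """The linear system is singular (insufficient constraints) or failed."""


@dataclass(frozen=True)
class StressField:
    """Per-element centroid plane-stress state and its principal values."""

    sxx: np.ndarray
    syy: np.ndarray
    txy: np.ndarray

    @property
    def sigma1(self) -> np.ndarray:
        """Maximum principal stress per element."""
        return principal_stress(self.sxx, self.syy, self.txy)[0]

    @property
    def principal_angle(self) -> np.ndarray:
        """Angle of the sigma1 eigenvector from the x axis, per element."""
        return principal_stress(self.sxx, self.syy, self.txy)[1]


def principal_stress(
    sxx: np.ndarray | float, syy: np.ndarray | float, txy: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form 2-D principal stress and direction.

    Returns (sigma1, theta) where sigma1 is the larger eigenvalue of the
    stress tensor and theta the angle of its eigenvector from the x axis,
    theta = 0.5 atan2(2 txy, sxx - syy).  For an isotropic state the
    direction is undefined; atan2 then returns 0 and the caller applies its
    own tie-break (continue along the previous crack direction).
    """
    sxx = np.asarray(sxx, float)
    syy = np.asarray(syy, float)
    txy = np.asarray(txy, float)
    mean = 0.5 * (sxx + syy)
    radius = np.sqrt((0.5 * (sxx - syy)) ** 2 + txy**2)
    theta = 0.5 * np.arctan2(2.0 * txy, sxx - syy)
    return mean + radius, theta


def elasticity_matrix(material: MaterialParams) -> np.ndarray:
    """Plane-stress constitutive matrix D (3x3, Voigt order xx, yy, xy)."""
    E, nu = material.youngs_modulus, material.poisson_ratio
    return E / (1.0 - nu**2) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )


def _shape_gradients(xi: float, eta: float, a: float) -> np.ndarray:
    """dN/dx, dN/dy (2x4) for a square element of side a at natural (xi, eta)."""
    # N_i = 1/4 (1 +/- xi)(1 +/- eta) on [-1, 1]^2; J = a/2 * I
    dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    return (2.0 / a) * np.vstack([dxi, deta])


def _b_matrix(xi: float, eta: float, a: float) -> np.ndarray:
    """Strain-displacement matrix B (3x8) at natural coordinates (xi, eta)."""
    g = _shape_gradients(xi, eta, a)
    B = np.zeros((3, 8))
    B[0, 0::2] = g[0]
    B[1, 1::2] = g[1]
    B[2, 0::2] = g[1]
    B[2, 1::2] = g[0]
    return B


def reference_stiffness(material: MaterialParams, a: float = 1.0) -> np.ndarray:
    """8x8 stiffness of a unit-thickness square bilinear quad of side a.

    2x2 Gauss quadrature, exact for this element geometry.
    """
    D = elasticity_matrix(material)
    gp = 1.0 / np.sqrt(3.0)
    K = np.zeros((8, 8))
    detJ = (a / 2.0) ** 2
    for xi in (-gp, gp):
        for eta in (-gp, gp):
            B = _b_matrix(xi, eta, a)
            K += B.T @ D @ B * detJ
    return K


def assemble_stiffness(mesh: PlateMesh) -> csr_matrix:
    """Global stiffness, K = sum_e thickness_e * K_ref scattered by DOF."""
    K0 = reference_stiffness(mesh.material, mesh.pixel_size)
    en = mesh.elem_nodes
    dofs = np.empty((mesh.n_elems, 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * en
    dofs[:, 1::2] = 2 * en + 1
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    vals = (mesh.thickness[:, None] * K0.ravel()[None, :]).ravel()
    n = 2 * mesh.n_nodes
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def solve_elasticity(
    mesh: PlateMesh,
    forces: np.ndarray,
    fixed_nodes: np.ndarray | None = None,
    fixed_values: np.ndarray | None = None,
    fixed_dofs: np.ndarray | None = None,
    fixed_dof_values: np.ndarray | None = None,
) -> tuple[np.ndarray, StressField]:
    """Static equilibrium of the plate under nodal forces.

    Parameters
    ----------
    mesh
        Plate mesh (possibly with split crack nodes).
    forces
        (n_nodes, 2) nodal force array.
    fixed_nodes
        Node ids with prescribed displacement (both components).  Defaults
        to the window border when ``fixed_dofs`` is not given either.
    fixed_values
        (len(fixed_nodes), 2) prescribed displacements; zero by default.
    fixed_dofs, fixed_dof_values
        Alternative per-DOF constraints (DOF index = 2*node + component);
        may be combined with ``fixed_nodes``.

    Returns
    -------
    (u, stress)
        u is (n_nodes, 2); stress holds centroid components per element.
        The solution is exactly linear in the applied forces.
    """
    if fixed_nodes is None and fixed_dofs is None:
        fixed_nodes = mesh.border_nodes()

    K = assemble_stiffness(mesh)
    n_dof = 2 * mesh.n_nodes
    f = np.asarray(forces, float).reshape(mesh.n_nodes, 2).ravel()
    u = np.zeros(n_dof)

    all_fixed: list[np.ndarray] = []
    if fixed_nodes is not None:
        fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64)
        nd = np.concatenate([2 * fixed_nodes, 2 * fixed_nodes + 1])
        all_fixed.append(nd)
        if fixed_values is not None:
            fv = np.asarray(fixed_values, float).reshape(len(fixed_nodes), 2)
            u[2 * fixed_nodes] = fv[:, 0]
            u[2 * fixed_nodes + 1] = fv[:, 1]
    if fixed_dofs is not None:
        fixed_dofs = np.asarray(fixed_dofs, dtype=np.int64)
        all_fixed.append(fixed_dofs)
        if fixed_dof_values is not None:
            u[fixed_dofs] = np.asarray(fixed_dof_values, float)
    fixed_dofs = np.unique(np.concatenate(all_fixed)) if all_fixed else np.array([], np.int64)
    if fixed_dofs.size == 0:
        raise SolverError("no constrained DOFs: rigid-body modes present")

    free = np.setdiff1d(np.arange(n_dof), fixed_dofs, assume_unique=False)
    rhs = f[free] - K[free][:, fixed_dofs] @ u[fixed_dofs]
    Kff = K[free][:, free]
    try:
        uf = spsolve(Kff.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - scipy raising is rare here
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise SolverError("singular system: non-finite displacements")
    u[free] = uf

    stress = element_stresses(mesh, u.reshape(-1, 2))
    return u.reshape(-1, 2), stress


def element_stresses(mesh: PlateMesh, u: np.ndarray) -> StressField:
    """Centroid stresses sigma = D B u_e for every element (vectorized)."""
    D = elasticity_matrix(mesh.material)
    B = _b_matrix(0.0, 0.0, mesh.pixel_size)
    ue = np.empty((mesh.n_elems, 8))
    ue[:, 0::2] = u[mesh.elem_nodes, 0]
    ue[:, 1::2] = u[mesh.elem_nodes, 1]
    s = ue @ (D @ B).T  # (n_elems, 3)
    return StressField(sxx=s[:, 0], syy=s[:, 1], txy=s[:, 2])


def uniform_edge_tension(
    mesh: PlateMesh, total_force: float, axis: str = "x"
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary conditions for a uniaxial tension test on the full window.

    axis='x': constrain u_x along the left node column (u_y free so Poisson
    contraction is unimpeded, plus one u_y pin to remove the rigid mode) and
    distribute ``total_force`` in +x over the right column with consistent
    nodal weights for a uniform traction (half weight at the corners).
    axis='y' is the transposed setup.  Returns (forces, fixed_dofs).
    """
    gi, gj = mesh.grid_node[:, 0], mesh.grid_node[:, 1]
    forces = np.zeros((mesh.n_nodes, 2))
    if axis == "x":
        fixed_nodes = np.flatnonzero(gj == 0)
        loaded = np.flatnonzero(gj == mesh.cols)
        ends = (gi[loaded] == 0) | (gi[loaded] == mesh.rows)
        comp = 0
    else:
        fixed_nodes = np.flatnonzero(gi == 0)
        loaded = np.flatnonzero(gi == mesh.rows)
        ends = (gj[loaded] == 0) | (gj[loaded] == mesh.cols)
        comp = 1
    w = np.where(ends, 0.5, 1.0)
    forces[loaded, comp] = total_force * w / w.sum()
    fixed_dofs = np.concatenate([2 * fixed_nodes + comp, [2 * fixed_nodes[0] + 1 - comp]])
    return forces, fixed_dofs
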