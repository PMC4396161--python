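"""P1 Lagrange finite-element assembly on triangle meshes.

Operators for the Galerkin weak form of the coupled electrodiffusion model:
consistent mass matrix, diffusion stiffness, the electromigration drift
operator A(phi)_ij = coeff * int_Omega psi_j (grad phi_h . grad psi_i), a
Gaussian point-source load (surrogate for a Dirac at the cell center), and
symmetric Dirichlet elimination.

P1 x P1 products are integrated exactly (closed-form element matrices); the
sharp Gaussian source uses a 7-point degree-5 Gauss rule per element with
optional uniform subdivision for accuracy studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh import TriangleMesh

__all__ = [
    "FemField",
    "tri_geometry",
    "assemble_mass",
    "assemble_lumped_mass",
    "assemble_stiffness",
    "assemble_drift",
    "assemble_point_source",
    "apply_dirichlet",
    "GAUSS7_POINTS",
    "GAUSS7_WEIGHTS",
]


@dataclass
class FemField:
    """Nodal scalar field on a mesh (one value per vertex)."""

    mesh: TriangleMesh
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.mesh.n_nodes:
            raise ValueError("field length does not match mesh node count")
        if not np.isfinite(self.values).all():
            raise ValueError("field contains non-finite values")


def _values_of(field, mesh: TriangleMesh) -> np.ndarray:
    if isinstance(field, FemField):
        if field.mesh is not mesh and field.mesh.n_nodes != mesh.n_nodes:
            raise ValueError("field defined on a different mesh")
        return field.values
    v = np.asarray(field, dtype=float).ravel()
    if v.size != mesh.n_nodes:
        raise ValueError("field length does not match mesh node count")
    return v


def tri_geometry(mesh: TriangleMesh):
    """Per-element areas (m,) and P1 basis gradients (m, 3, 2).

    For a triangle with vertices p0, p1, p2 the barycentric basis gradients
    are constant; grad psi_k is perpendicular to the opposite edge with
    magnitude (opposite edge length)/(2 area).
    """
    p = mesh.nodes[mesh.triangles]
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    area = 0.5 * det
    grads = np.empty((len(p), 3, 2))
    # rotate edge vectors by 90 degrees: grad psi_k = rot(edge_opp_k)/det
    e0 = p[:, 2] - p[:, 1]   # opposite vertex 0
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    for k, e in enumerate((e0, e1, e2)):
        grads[:, k, 0] = -e[:, 1] / det
        grads[:, k, 1] = e[:, 0] / det
    return area, grads


def _accumulate(mesh: TriangleMesh, elem: np.ndarray) -> sp.csr_matrix:
    """Scatter (m, 3, 3) element matrices into a global CSR operator."""
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    A = sp.coo_matrix((elem.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return A.tocsr()


_MASS_REF = (np.ones((3, 3)) + np.eye(3)) / 12.0


def assemble_mass(mesh: TriangleMesh) -> sp.csr_matrix:
    """Consistent mass matrix M_ij = int psi_i psi_j (SPD; row sums tile the
    domain area)."""
    area, _ = tri_geometry(mesh)
    elem = area[:, None, None] * _MASS_REF[None, :, :]
    return _accumulate(mesh, elem)


def assemble_lumped_mass(mesh: TriangleMesh) -> sp.csr_matrix:
    """Row-sum lumped diagonal mass matrix (stability-experiment option)."""
    M = assemble_mass(mesh)
    return sp.diags(np.asarray(M.sum(axis=1)).ravel()).tocsr()


def assemble_stiffness(mesh: TriangleMesh, coeff: float = 1.0) -> sp.csr_matrix:
    """Stiffness K_ij = coeff * int grad psi_i . grad psi_j (symmetric PSD;
    constants lie in the kernel)."""
    if coeff < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    area, grads = tri_geometry(mesh)
    elem = coeff * area[:, None, None] * np.einsum("tik,tjk->tij", grads, grads)
    return _accumulate(mesh, elem)


def assemble_drift(mesh: TriangleMesh, phi, drift_coeff: float) -> sp.csr_matrix:
    """Electromigration operator A(phi)_ij = drift_coeff * int psi_j
    (grad phi_h . grad psi_i).

    This is the Galerkin form of -div(drift_coeff * C grad phi) after
    integration by parts with the no-flux species boundary condition, so it
    contributes no boundary term and conserves discrete mass (its columns sum
    to zero).  grad phi_h is elementwise constant for P1, and psi_j integrates
    to area/3, making the element integral exact.
    """
    v = _values_of(phi, mesh)
    area, grads = tri_geometry(mesh)
    g = np.einsum("tk,tkd->td", v[mesh.triangles], grads)   # grad phi per elem
    gdot = np.einsum("td,tid->ti", g, grads)                # grad phi . grad psi_i
    elem = drift_coeff * (area / 3.0)[:, None, None] * gdot[:, :, None] \
        * np.ones((1, 1, 3))
    return _accumulate(mesh, elem)


# 7-point degree-5 Gauss rule on the reference triangle (barycentric coords)
_a1 = 0.0597158717897698
_b1 = 0.4701420641051151
_a2 = 0.7974269853530873
_b2 = 0.1012865073234563
GAUSS7_POINTS = np.array([
    [1 / 3, 1 / 3, 1 / 3],
    [_a1, _b1, _b1], [_b1, _a1, _b1], [_b1, _b1, _a1],
    [_a2, _b2, _b2], [_b2, _a2, _b2], [_b2, _b2, _a2],
])
GAUSS7_WEIGHTS = np.array([0.225,
                           0.1323941527885062, 0.1323941527885062,
                           0.1323941527885062,
                           0.1259391805448271, 0.1259391805448271,
                           0.1259391805448271])


def _point_in_mesh(mesh: TriangleMesh, point: np.ndarray) -> bool:
    p = mesh.nodes[mesh.triangles]
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    w = point[None, :] - p[:, 0]
    l1 = (w[:, 0] * v1[:, 1] - w[:, 1] * v1[:, 0]) / det
    l2 = (v0[:, 0] * w[:, 1] - v0[:, 1] * w[:, 0]) / det
    eps = 1e-12
    return bool(np.any((l1 >= -eps) & (l2 >= -eps) & (l1 + l2 <= 1 + eps)))


def assemble_point_source(mesh: TriangleMesh, center=(0.0, 0.0),
                          sharpness: float = 1000.0,
                          subdivisions: int = 0) -> np.ndarray:
    """Load vector b_i = int f psi_i with f = exp(-sharpness * |x - center|^2),
    the Gaussian surrogate of a Dirac at the cell center.

    Integrated per element with the 7-point Gauss rule; ``subdivisions``
    uniformly splits each element 4^s times first, for studies where the
    source is sharp relative to h.  Over the whole plane int f = pi/sharpness,
    so on a domain much wider than 1/sqrt(sharpness) the entries sum to
    approximately pi/sharpness.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    c = np.asarray(center, dtype=float)
    if not _point_in_mesh(mesh, c):
        warnings.warn("point-source center lies outside the mesh; the load "
                      "will be nearly zero", stacklevel=2)
    p = mesh.nodes[mesh.triangles]          # (m, 3, 2)
    b = np.zeros(mesh.n_nodes)
    # subdivide in barycentric coordinates: list of (3,3) corner-weight sets
    corners = [np.eye(3)]
    for _ in range(subdivisions):
        new = []
        for cw in corners:
            m01, m12, m20 = (0.5 * (cw[0] + cw[1]), 0.5 * (cw[1] + cw[2]),
                             0.5 * (cw[2] + cw[0]))
            new += [np.array([cw[0], m01, m20]), np.array([cw[1], m12, m01]),
                    np.array([cw[2], m20, m12]), np.array([m01, m12, m20])]
        corners = new
    frac = 1.0 / len(corners)
    area, _ = tri_geometry(mesh)
    for cw in corners:
        # quadrature nodes of the sub-triangle in physical coords (m, 7, 2)
        lam = GAUSS7_POINTS @ cw                      # (7, 3) barycentric in parent
        xq = np.einsum("qk,tkd->tqd", lam, p)
        r2 = ((xq - c[None, None, :]) ** 2).sum(axis=2)
        fq = np.exp(-sharpness * r2)                  # (m, 7)
        w = GAUSS7_WEIGHTS[None, :] * fq * (area * frac)[:, None]
        contrib = np.einsum("tq,qk->tk", w, lam)      # psi_k = parent barycentric
        np.add.at(b, mesh.triangles, contrib)
    return b


def apply_dirichlet(op: sp.spmatrix, rhs: np.ndarray,
                    boundary_nodes: np.ndarray, value=0.0):
    """Impose u = value on ``boundary_nodes`` by symmetric elimination.

    Returns a modified (operator, rhs) pair: constrained rows and columns are
    zeroed with a unit diagonal, the prescribed values are moved to the
    right-hand side of the interior rows, and rhs at the constrained nodes is
    set to the values themselves.  Solving the returned system yields exactly
    ``value`` at the constrained nodes.
    """
    n = op.shape[0]
    bnd = np.asarray(boundary_nodes, dtype=np.int64).ravel()
    vals = np.broadcast_to(np.asarray(value, dtype=float), bnd.shape)
    A = op.tocsr()
    u_b = np.zeros(n)
    u_b[bnd] = vals
    new_rhs = np.asarray(rhs, dtype=float).copy() - A @ u_b
    keep = np.ones(n)
    keep[bnd] = 0.0
    D = sp.diags(keep)
    A2 = (D @ A @ D + sp.diags(1.0 - keep)).tocsr()
    new_rhs[bnd] = vals
    return A2, new_rhs
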