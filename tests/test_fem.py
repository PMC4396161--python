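import math

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from npcable import (apply_dirichlet, assemble_drift, assemble_mass,
                     assemble_point_source, assemble_stiffness,
                     generate_ellipse_mesh)
from npcable.fem import FemField

# Independent quadrature oracle: 6-point degree-4 Gauss rule on a triangle
# (distinct from the package's closed-form element matrices and from its
# 7-point rule).
_Q_W = np.array([0.223381589678011] * 3 + [0.109951743655322] * 3)
_Q_A = [0.108103018168070, 0.445948490915965, 0.816847572980459,
        0.091576213509771]
_Q_PTS = np.array([
    [_Q_A[0], _Q_A[1], _Q_A[1]], [_Q_A[1], _Q_A[0], _Q_A[1]],
    [_Q_A[1], _Q_A[1], _Q_A[0]],
    [_Q_A[2], _Q_A[3], _Q_A[3]], [_Q_A[3], _Q_A[2], _Q_A[3]],
    [_Q_A[3], _Q_A[3], _Q_A[2]],
])


def quadrature_matrix(mesh, integrand):
    """Brute-force element-wise assembly of int integrand(psi_i, psi_j, x)
    using the degree-4 rule; integrand receives barycentric basis values and
    physical coordinates per quadrature point."""
    n = mesh.n_nodes
    A = np.zeros((n, n))
    for tri in mesh.triangles:
        p = mesh.nodes[tri]
        area = 0.5 * abs((p[1][0]-p[0][0])*(p[2][1]-p[0][1]) - (p[2][0]-p[0][0])*(p[1][1]-p[0][1]))
        for w, lam in zip(_Q_W, _Q_PTS):
            x = lam @ p
            for a in range(3):
                for b in range(3):
                    A[tri[a], tri[b]] += w * area * integrand(lam[a], lam[b], x)
    return A


class TestMass:
    def test_single_triangle_closed_form(self, unit_right_triangle):
        M = assemble_mass(unit_right_triangle).toarray()
        area = 0.5
        expected = area / 12.0 * np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]])
        np.testing.assert_allclose(M, expected, atol=1e-15)

    def test_partition_of_unity_row_sums(self, ellipse_mesh):
        M = assemble_mass(ellipse_mesh)
        assert M.sum() == pytest.approx(ellipse_mesh.area(), rel=1e-12)

    def test_matches_quadrature_oracle(self, coarse_ellipse_mesh):
        M = assemble_mass(coarse_ellipse_mesh).toarray()
        Q = quadrature_matrix(coarse_ellipse_mesh,
                              lambda pa, pb, x: pa * pb)
        np.testing.assert_allclose(M, Q, atol=1e-12)

    def test_spd(self, disc_mesh, rng):
        M = assemble_mass(disc_mesh)
        for _ in range(5):
            v = rng.standard_normal(disc_mesh.n_nodes)
            assert v @ (M @ v) > 0


class TestStiffness:
    def test_single_triangle_closed_form(self, unit_right_triangle):
        K = assemble_stiffness(unit_right_triangle, 1.0).toarray()
        expected = 0.5 * np.array([[2, -1, -1], [-1, 1, 0], [-1, 0, 1]])
        np.testing.assert_allclose(K, expected, atol=1e-15)

    def test_constants_in_kernel(self, ellipse_mesh):
        K = assemble_stiffness(ellipse_mesh, 3.0)
        np.testing.assert_allclose(np.asarray(K.sum(axis=1)).ravel(), 0.0,
                                   atol=1e-12)

    def test_dirichlet_energy_of_linear_field(self, disc_mesh):
        # u = x has |grad u|^2 = 1, so u^T K u = coeff * area
        u = disc_mesh.nodes[:, 0]
        K = assemble_stiffness(disc_mesh, 2.5)
        assert u @ (K @ u) == pytest.approx(2.5 * disc_mesh.area(), rel=1e-12)

    def test_psd_and_symmetric(self, coarse_ellipse_mesh):
        K = assemble_stiffness(coarse_ellipse_mesh, 1.0)
        assert abs(K - K.T).max() < 1e-14
        w = np.linalg.eigvalsh(K.toarray())
        assert w.min() > -1e-10


class TestDrift:
    def test_constant_potential_gives_zero(self, ellipse_mesh):
        A = assemble_drift(ellipse_mesh, np.full(ellipse_mesh.n_nodes, 3.0),
                           1e-3)
        assert abs(A).max() < 1e-15       # roundoff of cancelling gradients

    def test_single_triangle_linear_potential(self, unit_right_triangle):
        # phi = x: grad phi = (1, 0); entries = c*(grad phi . grad psi_i)*A/3
        phi = unit_right_triangle.nodes[:, 0]
        c = 2e-3
        A = assemble_drift(unit_right_triangle, phi, c).toarray()
        grads = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
        area = 0.5
        expected = np.repeat((c * grads[:, 0] * area / 3.0)[:, None], 3,
                             axis=1)
        np.testing.assert_allclose(A, expected, atol=1e-15)

    def test_linear_in_potential(self, coarse_ellipse_mesh, rng):
        phi = rng.standard_normal(coarse_ellipse_mesh.n_nodes)
        A1 = assemble_drift(coarse_ellipse_mesh, phi, 1e-3)
        A2 = assemble_drift(coarse_ellipse_mesh, 2.0 * phi, 1e-3)
        assert abs(A2 - 2.0 * A1).max() < 1e-14

    def test_columns_sum_to_zero_mass_conservation(self, coarse_ellipse_mesh,
                                                   rng):
        phi = rng.standard_normal(coarse_ellipse_mesh.n_nodes)
        A = assemble_drift(coarse_ellipse_mesh, phi, 1e-3)
        np.testing.assert_allclose(np.asarray(A.sum(axis=0)).ravel(), 0.0,
                                   atol=1e-15)

    def test_matches_quadrature_oracle(self, coarse_ellipse_mesh, rng):
        mesh = coarse_ellipse_mesh
        phi = rng.standard_normal(mesh.n_nodes)
        A = assemble_drift(mesh, phi, 1.0).toarray()
        # independent: per element grad phi is constant; integrate psi_j
        # (grad phi . grad psi_i) with the degree-4 rule
        n = mesh.n_nodes
        Q = np.zeros((n, n))
        for tri in mesh.triangles:
            p = mesh.nodes[tri]
            area = 0.5 * abs((p[1][0]-p[0][0])*(p[2][1]-p[0][1]) - (p[2][0]-p[0][0])*(p[1][1]-p[0][1]))
            T = np.column_stack([p[1] - p[0], p[2] - p[0]])
            G = np.linalg.inv(T).T @ np.array([[-1.0, -1.0],
                                               [1.0, 0.0], [0.0, 1.0]]).T
            g = phi[tri] @ G.T          # grad phi, constant on the element
            for w, lam in zip(_Q_W, _Q_PTS):
                for a in range(3):
                    for b in range(3):
                        Q[tri[a], tri[b]] += w * area * lam[b] * (g @ G[:, a])
        np.testing.assert_allclose(A, Q, atol=1e-12)

    def test_mesh_mismatch_rejected(self, ellipse_mesh):
        with pytest.raises(ValueError):
            assemble_drift(ellipse_mesh, np.zeros(3), 1.0)


class TestPointSource:
    def test_total_load_is_gaussian_integral(self):
        # int_R2 exp(-s r^2) = pi/s; boundary truncation negligible at s=1000
        mesh = generate_ellipse_mesh(1.0, 1.0, 0.1)
        b = assemble_point_source(mesh, sharpness=1000.0, subdivisions=3)
        assert b.sum() == pytest.approx(math.pi / 1000.0, rel=0.01)

    def test_doubling_sharpness_halves_total(self):
        mesh = generate_ellipse_mesh(1.0, 1.0, 0.1)
        b1 = assemble_point_source(mesh, sharpness=1000.0, subdivisions=3)
        b2 = assemble_point_source(mesh, sharpness=2000.0, subdivisions=3)
        assert b2.sum() == pytest.approx(0.5 * b1.sum(), rel=0.02)

    def test_far_nodes_get_nothing(self, ellipse_mesh):
        b = assemble_point_source(ellipse_mesh)
        r = np.linalg.norm(ellipse_mesh.nodes, axis=1)
        assert np.abs(b[r > 1.0]).max() < 1e-300  # exp(-1000) underflows

    def test_center_outside_warns(self, disc_mesh):
        with pytest.warns(UserWarning, match="outside"):
            assemble_point_source(disc_mesh, center=(5.0, 5.0))


class TestDirichlet:
    def test_boundary_values_exact(self, disc_mesh, rng):
        K = assemble_stiffness(disc_mesh, 1.0)
        M = assemble_mass(disc_mesh)
        A = (M + K).tocsr()
        rhs = rng.standard_normal(disc_mesh.n_nodes)
        bnd = disc_mesh.boundary_nodes
        A2, r2 = apply_dirichlet(A, rhs, bnd, 3.5)
        u = spla.spsolve(A2.tocsc(), r2)
        np.testing.assert_allclose(u[bnd], 3.5, atol=1e-12)

    def test_laplace_with_zero_data_is_zero(self, disc_mesh):
        K = assemble_stiffness(disc_mesh, 1.0)
        A2, r2 = apply_dirichlet(K, np.zeros(disc_mesh.n_nodes),
                                 disc_mesh.boundary_nodes, 0.0)
        u = spla.spsolve(A2.tocsc(), r2)
        np.testing.assert_allclose(u, 0.0, atol=1e-12)

    def test_poisson_on_disc_center_value(self):
        # -Lap u = 1, u=0 on the unit circle  =>  u = (1-r^2)/4, u(0) = 1/4
        errs = []
        for h in (0.2, 0.1, 0.05):
            mesh = generate_ellipse_mesh(1.0, 1.0, h)
            K = assemble_stiffness(mesh, 1.0)
            M = assemble_mass(mesh)
            rhs = M @ np.ones(mesh.n_nodes)
            A2, r2 = apply_dirichlet(K, rhs, mesh.boundary_nodes, 0.0)
            u = spla.spsolve(A2.tocsc(), r2)
            errs.append(abs(u[mesh.nearest_node((0, 0))] - 0.25))
        assert errs[-1] < 2e-3
        assert errs[0] > errs[-1]


def test_fem_field_validation(ellipse_mesh):
    with pytest.raises(ValueError):
        FemField(ellipse_mesh, np.zeros(3))
    with pytest.raises(ValueError):
        FemField(ellipse_mesh, np.full(ellipse_mesh.n_nodes, np.nan))
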