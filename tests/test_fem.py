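"""Element matrices, load vectors and norms against closed forms and
adaptive-quadrature oracles."""

import numpy as np
import pytest

from ionfem import fem
from ionfem.kinetics import BasicParams, SpeciesSpec, mm_reduced_rate
from ionfem.mesh import generate_ellipse_mesh

from oracles import p1_shape_functions, triangle_integral

UNIT_TRI_MASS = np.array(
    [[1 / 12, 1 / 24, 1 / 24], [1 / 24, 1 / 12, 1 / 24], [1 / 24, 1 / 24, 1 / 12]]
)
UNIT_TRI_STIFF = 0.5 * np.array([[2.0, -1.0, -1.0], [-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])


class TestMass:
    def test_unit_triangle_closed_form(self, unit_triangle):
        A = fem.assemble_weighted_mass(unit_triangle, None, 0.0).toarray()
        assert np.allclose(A, UNIT_TRI_MASS, atol=1e-15)

    def test_constant_potential_factors_out(self, unit_triangle):
        c, ratio = 1.7, 0.9
        A0 = fem.assemble_weighted_mass(unit_triangle, None, 0.0).toarray()
        A = fem.assemble_weighted_mass(unit_triangle, np.full(3, c), ratio).toarray()
        assert np.allclose(A, np.exp(-ratio * c) * A0, rtol=1e-13)

    def test_linear_potential_against_adaptive_quadrature(self, unit_triangle):
        """Degree-4 quadrature of the exponential weight matches scipy dblquad."""
        phi = np.array([0.0, 0.008, 0.02])
        A = fem.assemble_weighted_mass(unit_triangle, phi, 1.0, degree=4).toarray()
        verts = unit_triangle.nodes
        lam = p1_shape_functions(verts)

        def w(x, y):
            return np.exp(-(phi[0] * lam[0](x, y) + phi[1] * lam[1](x, y) + phi[2] * lam[2](x, y)))

        for i in range(3):
            for j in range(3):
                exact = triangle_integral(lambda x, y: w(x, y) * lam[i](x, y) * lam[j](x, y), verts)
                assert A[i, j] == pytest.approx(exact, rel=1e-8)

    def test_symmetry_and_nonnegativity(self, disk_mesh):
        rng = np.random.default_rng(42)
        phi = rng.normal(size=disk_mesh.n_nodes)
        A = fem.assemble_weighted_mass(disk_mesh, phi, 1.3)
        dense = A.toarray()
        assert np.allclose(dense, dense.T, rtol=1e-12)
        assert dense.min() >= 0.0

    def test_row_sums_give_area_shares(self, ellipse_mesh_coarse):
        A = fem.mass_matrix(ellipse_mesh_coarse)
        shares = np.asarray(A.sum(axis=1)).ravel()
        assert shares.sum() == pytest.approx(ellipse_mesh_coarse.area(), rel=1e-12)

    def test_nonfinite_ratio_rejected(self, unit_triangle):
        with pytest.raises(ValueError):
            fem.assemble_weighted_mass(unit_triangle, None, np.inf)

    def test_exponent_clamp_counts_events(self, unit_triangle):
        before = fem.clamp_counter["count"]
        fem.assemble_weighted_mass(unit_triangle, np.full(3, 1e3), 1.0)
        assert fem.clamp_counter["count"] > before


class TestStiffness:
    def test_unit_triangle_closed_form(self, unit_triangle):
        R = fem.assemble_weighted_stiffness(unit_triangle, None, 1.0, 0.0).toarray()
        assert np.allclose(R, UNIT_TRI_STIFF, atol=1e-15)

    def test_row_sums_vanish_for_any_weight(self, disk_mesh):
        rng = np.random.default_rng(7)
        phi = rng.normal(scale=2.0, size=disk_mesh.n_nodes)
        R = fem.assemble_weighted_stiffness(disk_mesh, phi, 0.7, 1.0)
        rows = np.asarray(R.sum(axis=1)).ravel()
        assert np.max(np.abs(rows)) <= 1e-12 * np.abs(R.toarray()).max()

    def test_linear_in_diffusivity(self, unit_triangle):
        phi = np.array([0.1, -0.2, 0.3])
        R1 = fem.assemble_weighted_stiffness(unit_triangle, phi, 1.0, 1.0).toarray()
        R2 = fem.assemble_weighted_stiffness(unit_triangle, phi, 2.0, 1.0).toarray()
        assert np.allclose(R2, 2.0 * R1, rtol=1e-14)

    def test_nonpositive_diffusivity_rejected(self, unit_triangle):
        with pytest.raises(ValueError):
            fem.assemble_weighted_stiffness(unit_triangle, None, 0.0, 0.0)


class TestLaplace:
    def test_equals_unweighted_stiffness(self, disk_mesh):
        Q = fem.assemble_laplace(disk_mesh)
        R = fem.assemble_weighted_stiffness(disk_mesh, None, 1.0, 0.0)
        assert np.allclose(Q.toarray(), R.toarray(), rtol=0, atol=0)

    def test_constants_in_kernel(self, disk_mesh):
        Q = fem.assemble_laplace(disk_mesh)
        assert np.max(np.abs(Q @ np.ones(disk_mesh.n_nodes))) < 1e-12

    def test_interior_block_positive_definite(self, disk_mesh):
        Q = fem.assemble_laplace(disk_mesh).toarray()
        Y = disk_mesh.interior_nodes
        eigs = np.linalg.eigvalsh(Q[np.ix_(Y, Y)])
        assert eigs.min() > 0


class TestLoads:
    def test_unit_charge_on_unit_triangle(self, unit_triangle):
        beta = fem.assemble_charge_load(unit_triangle, 1.0)
        assert np.allclose(beta, np.full(3, 1 / 6), rtol=1e-14)

    def test_zero_charge(self, disk_mesh):
        assert np.all(fem.assemble_charge_load(disk_mesh, 0.0) == 0.0)

    def test_total_charge_is_density_times_area(self):
        mesh = generate_ellipse_mesh(2.0, 1.0, 0.3)
        beta = fem.assemble_charge_load(mesh, 0.1)
        assert beta.sum() == pytest.approx(0.1 * 2 * np.pi, rel=0.01)

    def test_zero_rate_gives_zero_load(self, disk_mesh):
        species = [SpeciesSpec("s", 1.0, 0, 1.0)]
        Z = np.ones((1, disk_mesh.n_nodes))
        load = fem.assemble_reaction_load(
            disk_mesh, lambda c: np.zeros_like(c), None, Z, species, 0
        )
        assert np.all(load == 0.0)

    def test_constant_rate_reduces_to_charge_load(self, unit_triangle):
        species = [SpeciesSpec("s", 1.0, 0, 1.0)]
        Z = np.ones((1, 3))
        load = fem.assemble_reaction_load(
            unit_triangle, lambda c: np.full_like(c, 3.0), None, Z, species, 0
        )
        assert np.allclose(load, np.full(3, 3.0 / 6.0), rtol=1e-14)

    def test_michaelis_menten_load_against_adaptive_quadrature(self, unit_triangle):
        params = BasicParams(k2=1.4e4, km=90.0, c1_0=1.0)
        species = [SpeciesSpec("s", 1.0, 0, 1.0)]
        z_sub = np.array([700.0, 820.0, 600.0])
        load = fem.assemble_reaction_load(
            unit_triangle, lambda c: -mm_reduced_rate(c[0], params)[None],
            None, z_sub[None], species, 0, degree=4,
        )
        lam = p1_shape_functions(unit_triangle.nodes)

        def c_sub(x, y):
            return z_sub[0] * lam[0](x, y) + z_sub[1] * lam[1](x, y) + z_sub[2] * lam[2](x, y)

        for i in range(3):
            exact = triangle_integral(
                lambda x, y: -params.k2 * params.c1_0 * c_sub(x, y)
                / (c_sub(x, y) + params.km) * lam[i](x, y),
                unit_triangle.nodes,
            )
            assert load[i] == pytest.approx(exact, rel=1e-6)

    def test_nonfinite_rate_raises_with_species(self, unit_triangle):
        species = [SpeciesSpec("s", 1.0, 0, 1.0)]
        Z = np.ones((1, 3))
        with pytest.raises(FloatingPointError, match="species 0"):
            fem.assemble_reaction_load(
                unit_triangle, lambda c: np.full_like(c, np.nan), None, Z, species, 0
            )


class TestNorms:
    def test_constant_field_norm_is_sqrt_area(self):
        mesh = generate_ellipse_mesh(2.0, 1.0, 0.3)
        n = fem.l2_norm(mesh, np.ones(mesh.n_nodes))
        assert n == pytest.approx(np.sqrt(mesh.area()), rel=1e-12)

    def test_zero_field(self, disk_mesh):
        assert fem.l2_norm(disk_mesh, np.zeros(disk_mesh.n_nodes)) == 0.0

    def test_coordinate_field_on_disk(self, disk_mesh):
        # integral of x^2 over the unit disk is pi/4
        n = fem.l2_norm(disk_mesh, disk_mesh.nodes[:, 0])
        assert n == pytest.approx(np.sqrt(np.pi / 4), rel=0.02)


class TestQuadratureRefinement:
    def test_degree_2_vs_4_close_for_smooth_weight(self, disk_mesh):
        phi = 0.1 * disk_mesh.nodes[:, 0]  # smooth exponent, mild per-element variation
        A2 = fem.assemble_weighted_mass(disk_mesh, phi, 1.0, degree=2)
        A4 = fem.assemble_weighted_mass(disk_mesh, phi, 1.0, degree=4)
        diff = np.abs((A2 - A4).toarray()).max()
        assert diff <= 1e-3 * np.abs(A4.toarray()).max()
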