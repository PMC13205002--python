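"""Finite-volume potential solve: closed forms, conservation, linearity."""

import numpy as np
import pytest

import etrec as E
from etrec.field import (
    GridResolution,
    PotentialField,
    VoxelGrid,
    build_grid,
    electric_field,
    extract_field_features,
    plane_current_a,
    sample_potential_along_path,
    solve_potential,
)
from etrec.tissue import build_fingertip_model


def _uniform_top_source(grid, j_a_per_m2):
    dx = np.diff(grid.x_edges_mm) * 1e-3
    dy = np.diff(grid.y_edges_mm) * 1e-3
    return j_a_per_m2 * dy[:, None] * dx[None, :]


def _slab(layers, extent=10.0, n_lat=6):
    edges = np.linspace(-extent / 2, extent / 2, n_lat + 1)
    return VoxelGrid.from_layers(edges, edges, layers)


class TestClosedForms:
    def test_homogeneous_slab_parallel_plate_field(self):
        # uniform current density through sigma=0.2 over 5 mm: |E| = J/sigma
        grid = _slab([(5.0, 0.2, 20)])
        j = 40.0  # A/m^2 -> E = 200 V/m, drop = 1 V
        p = solve_potential(grid, top_current_a=_uniform_top_source(grid, j), current_ma=0.0)
        _, mag = electric_field(p)
        assert np.allclose(mag, j / 0.2, rtol=1e-6)
        assert p.phi[0].mean() == pytest.approx(1.0, rel=0.05)  # top potential ~ V = J*d/sigma

    def test_two_layer_series_conductor(self):
        # sigma 0.1 then 0.2 S/m, 2.5 mm each, unit potential across 5 mm:
        # J = 1 / (t1/s1 + t2/s2) = 26.667 A/m^2, E1 = 266.67, E2 = 133.33 V/m
        grid = _slab([(2.5, 0.1, 10), (2.5, 0.2, 10)])
        j = 1.0 / (2.5e-3 / 0.1 + 2.5e-3 / 0.2)
        p = solve_potential(grid, top_current_a=_uniform_top_source(grid, j), current_ma=0.0)
        _, mag = electric_field(p)
        # interior cells of each layer (central differences blend at the interface)
        e1 = np.median(mag[2:8])
        e2 = np.median(mag[12:18])
        assert e1 == pytest.approx(266.667, rel=0.02)
        assert e2 == pytest.approx(133.333, rel=0.02)

    def test_zero_current_gives_zero_potential(self):
        grid = _slab([(5.0, 0.2, 4)])
        p = solve_potential(grid, top_current_a=np.zeros(grid.shape[1:]), current_ma=0.0)
        assert np.all(p.phi == 0.0)
        assert p.residual == 0.0


@pytest.fixture(scope="module")
def disc_solution():
    subject = E.TRAINING_COHORT[0]
    cfg = E.ElectrodeConfig(3.0, 1.0)
    model = build_fingertip_model(subject)
    grid = build_grid(model, cfg)
    layout = E.electrode_centers(cfg)
    p = solve_potential(grid, layout=layout, active=(2,), current_ma=2.0)
    return grid, layout, p


class TestDiscSource:
    def test_current_conserved_through_every_horizontal_plane(self, disc_solution):
        grid, _, p = disc_solution
        injected = p.injected_current_ma * 1e-3
        for k in range(grid.shape[0]):
            assert plane_current_a(p, k) == pytest.approx(injected, rel=0.01)

    def test_solution_linear_in_current(self, disc_solution):
        grid, layout, p1 = disc_solution
        p2 = solve_potential(grid, layout=layout, active=(2,), current_ma=4.0)
        assert np.allclose(p2.phi, 2.0 * p1.phi, rtol=1e-6, atol=1e-9)

    def test_field_features_scale_with_current(self, disc_solution):
        grid, layout, p1 = disc_solution
        p2 = solve_potential(grid, layout=layout, active=(2,), current_ma=4.0)
        f1 = extract_field_features(electric_field(p1)[1], grid)
        f2 = extract_field_features(electric_field(p2)[1], grid)
        assert f2.e_max == pytest.approx(2 * f1.e_max, rel=1e-6)
        assert f2.e_avg == pytest.approx(2 * f1.e_avg, rel=1e-6)
        assert f2.e_int == pytest.approx(2 * f1.e_int, rel=1e-6)

    def test_emax_at_least_eavg_and_positive(self, disc_solution):
        grid, _, p = disc_solution
        f = extract_field_features(electric_field(p)[1], grid)
        assert f.e_max >= f.e_avg > 0.0

    def test_cg_and_direct_solvers_agree(self, disc_solution):
        grid, layout, p_cg = disc_solution
        p_lu = solve_potential(grid, layout=layout, active=(2,), current_ma=2.0, method="direct")
        assert np.allclose(p_lu.phi, p_cg.phi, rtol=1e-5, atol=1e-8)


class TestGradientAndSampling:
    def test_gradient_matches_loop_based_oracle(self):
        grid = _slab([(2.0, 0.1, 5)], extent=5.0, n_lat=5)
        rng = np.random.default_rng(7)
        phi = rng.normal(size=grid.shape)
        p = PotentialField(phi, grid, 1.0, 0.0)
        e_vec, _ = electric_field(p)
        zc, yc, xc = grid.z_centers_mm * 1e-3, grid.y_centers_mm * 1e-3, grid.x_centers_mm * 1e-3
        nz, ny, nx = grid.shape

        def central(vals, coords, i):
            if i == 0:
                return (vals[1] - vals[0]) / (coords[1] - coords[0])
            if i == len(coords) - 1:
                return (vals[-1] - vals[-2]) / (coords[-1] - coords[-2])
            return (vals[i + 1] - vals[i - 1]) / (coords[i + 1] - coords[i - 1])

        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    assert e_vec[2, iz, iy, ix] == pytest.approx(
                        -central(phi[:, iy, ix], zc, iz), rel=1e-10
                    )
                    assert e_vec[1, iz, iy, ix] == pytest.approx(
                        -central(phi[iz, :, ix], yc, iy), rel=1e-10
                    )
                    assert e_vec[0, iz, iy, ix] == pytest.approx(
                        -central(phi[iz, iy, :], xc, ix), rel=1e-10
                    )

    def test_field_points_from_high_to_low_potential(self):
        grid = _slab([(5.0, 0.2, 10)])
        p = solve_potential(grid, top_current_a=_uniform_top_source(grid, 10.0), current_ma=0.0)
        e_vec, _ = electric_field(p)
        # potential decreases with depth, so Ez (towards depth) is positive
        assert np.all(e_vec[2] > 0)

    def test_interpolation_identity_and_midpoint(self):
        grid = _slab([(5.0, 0.2, 10)])
        p = solve_potential(grid, top_current_a=_uniform_top_source(grid, 10.0), current_ma=0.0)
        zc = grid.z_centers_mm
        pts = np.array([[0.5, 0.5, z] for z in zc[2:6]])
        iy = np.searchsorted(grid.y_centers_mm, 0.5)
        ix = np.searchsorted(grid.x_centers_mm, 0.5)
        got = sample_potential_along_path(p, pts)
        # nearest lateral cell centre (lateral profile is uniform)
        assert np.allclose(got, p.phi[2:6, iy, ix], rtol=1e-9)
        mid = np.array([[0.5, 0.5, 0.5 * (zc[2] + zc[3])]])
        assert sample_potential_along_path(p, mid)[0] == pytest.approx(
            0.5 * (p.phi[2, iy, ix] + p.phi[3, iy, ix]), rel=1e-9
        )

    def test_potential_consistent_with_line_integral_of_field(self, disc_solution):
        # phi(x) should equal the integral of -E from x down to the grounded
        # face; compare against trapezoidal quadrature of Ez on a vertical line
        grid, _, p = disc_solution
        e_vec, _ = electric_field(p)
        iy = grid.shape[1] // 2
        ix = grid.shape[2] // 2
        z = grid.z_centers_mm * 1e-3
        phi_line = p.phi[:, iy, ix]
        ez = e_vec[2, :, iy, ix]
        integral = np.trapezoid(ez[2:], z[2:])  # from cell 2 down to the last centre
        drop = phi_line[2] - phi_line[-1]
        assert integral == pytest.approx(drop, rel=0.02)

    def test_out_of_domain_point_rejected(self, disc_solution):
        _, _, p = disc_solution
        with pytest.raises(ValueError):
            sample_potential_along_path(p, np.array([[100.0, 0.0, 1.0]]))


class TestGridConstruction:
    def test_four_distinct_conductivities_for_homogeneous_layers(self):
        model = build_fingertip_model(E.TRAINING_COHORT[0])
        grid = build_grid(model, E.ElectrodeConfig(2.0, 0.5))
        assert len(np.unique(grid.sigma)) == 4
        assert set(np.unique(grid.layer_index)) == {0, 1, 2, 3}

    def test_layer_boundaries_invariant_under_lateral_refinement(self):
        model = build_fingertip_model(E.TRAINING_COHORT[0])
        g1 = build_grid(model, E.ElectrodeConfig(2.0, 0.5), GridResolution(lateral_step_mm=1.0))
        g2 = build_grid(model, E.ElectrodeConfig(2.0, 0.5), GridResolution(lateral_step_mm=0.5))
        assert np.allclose(g1.z_edges_mm, g2.z_edges_mm)

    def test_cell_count_is_product_of_axis_counts(self):
        model = build_fingertip_model(E.TRAINING_COHORT[0])
        grid = build_grid(model, E.ElectrodeConfig(2.0, 0.5))
        nz, ny, nx = grid.shape
        assert grid.sigma.size == nz * ny * nx
        assert nz == sum(GridResolution().cells_per_layer)

    def test_underresolved_layer_rejected(self):
        with pytest.raises(ValueError):
            GridResolution(cells_per_layer=(1, 2, 8, 8))

    def test_array_must_fit_lateral_extent(self):
        model = build_fingertip_model(E.TRAINING_COHORT[0], lateral_extent_mm=(10.0, 10.0))
        with pytest.raises(ValueError):
            build_grid(model, E.ElectrodeConfig(4.5, 3.0))
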