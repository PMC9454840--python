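import numpy as np
import pytest

from wellfield import (
    ConfigurationError,
    InvalidGeometryError,
    InvalidScaleError,
    analytic_plate_field,
    centerline_profile,
    convergence_study,
    electrode_current_per_depth,
    homogeneity_metrics,
    rectangle_mesh,
    scale_to_voltage,
    solve_potential,
    total_current,
)
from wellfield.meshing import ELECTRODE_A, ELECTRODE_B, Mesh2D
from wellfield.solver import CurrentResult


@pytest.fixture(scope="module")
def plate_field():
    """Unit square with full-width electrodes: exact solution is a linear
    ramp, which lies in the P1 space."""
    return solve_potential(rectangle_mesh(1.0, 1.0, 8, 8), 1.0)


class TestParallelPlateOracle:
    def test_potential_is_linear_ramp(self, plate_field):
        exact = plate_field.mesh.points[:, 0] - 0.5
        np.testing.assert_allclose(plate_field.phi, exact, atol=1e-13)

    def test_field_magnitude_uniform(self, plate_field):
        np.testing.assert_allclose(
            plate_field.field_magnitude(), 1.0, rtol=1e-12
        )

    def test_identical_across_refinements(self):
        for n in (2, 4, 16):
            f = solve_potential(rectangle_mesh(1.0, 1.0, n, n), 1.0)
            np.testing.assert_allclose(f.field_magnitude(), 1.0, rtol=1e-11)

    def test_current_per_depth_sigma_v_w_over_d(self, plate_field):
        # sigma * (V/d) * W with sigma = V = W = d = 1
        cur = electrode_current_per_depth(plate_field, 1.0)
        assert cur.current_per_depth == pytest.approx(1.0, rel=1e-10)

    def test_profile_constant(self, plate_field):
        profile = centerline_profile(plate_field, 11)
        np.testing.assert_allclose(profile.magnitudes, 1.0, rtol=1e-10)

    def test_band_fraction_one(self, plate_field):
        assert homogeneity_metrics(plate_field, 0.9, 1.1) == 1.0


class TestSolveBasics:
    def test_zero_voltage_gives_zero_solution(self, chamber_mesh):
        f = solve_potential(chamber_mesh, 0.0)
        assert np.all(f.phi == 0)
        assert np.all(f.efield == 0)

    def test_dirichlet_values_exact(self, field_1v):
        mesh = field_1v.mesh
        assert field_1v.phi[mesh.boundary_nodes(ELECTRODE_A)] == pytest.approx(0.5)
        assert field_1v.phi[mesh.boundary_nodes(ELECTRODE_B)] == pytest.approx(-0.5)

    def test_discrete_maximum_principle(self, field_1v):
        assert field_1v.phi.min() >= -0.5 - 1e-12
        assert field_1v.phi.max() <= 0.5 + 1e-12

    def test_missing_electrode_tag_raises(self, chamber_mesh):
        broken = Mesh2D(
            points=chamber_mesh.points,
            triangles=chamber_mesh.triangles,
            boundary_edges={
                ELECTRODE_A: chamber_mesh.boundary_edges[ELECTRODE_A],
                ELECTRODE_B: np.empty((0, 2), dtype=int),
            },
        )
        with pytest.raises(ConfigurationError):
            solve_potential(broken, 1.0)


class TestLinearity:
    def test_scale_matches_resolve_node_for_node(self, chamber_mesh, field_1v):
        scaled = scale_to_voltage(field_1v, 5.0)
        resolved = solve_potential(chamber_mesh, 5.0)
        np.testing.assert_allclose(scaled.phi, resolved.phi, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            scaled.efield, resolved.efield, rtol=1e-10, atol=1e-9
        )

    def test_scale_identity_and_group(self, field_1v):
        same = scale_to_voltage(field_1v, field_1v.voltage_difference)
        np.testing.assert_array_equal(same.phi, field_1v.phi)
        back = scale_to_voltage(scale_to_voltage(field_1v, 2.0), 1.0)
        np.testing.assert_allclose(back.phi, field_1v.phi, rtol=1e-14)

    def test_five_volt_plateau(self, field_1v):
        scaled = scale_to_voltage(field_1v, 5.0)
        mid = centerline_profile(scaled, 201).midpoint_field
        assert mid == pytest.approx(
            5 * centerline_profile(field_1v, 201).midpoint_field, rel=1e-12
        )

    def test_cannot_scale_zero_voltage(self, chamber_mesh):
        f = solve_potential(chamber_mesh, 0.0)
        with pytest.raises(InvalidScaleError):
            scale_to_voltage(f, 1.0)


class TestChamberField:
    def test_midpoint_within_two_percent_of_plate_limit(self, chamber, field_1v):
        analytic = analytic_plate_field(1.0, chamber.electrode_gap)
        mid = centerline_profile(field_1v, 201).midpoint_field
        assert mid == pytest.approx(analytic, rel=0.02)

    def test_midpoint_robust_across_resolutions(self, convergence_table):
        assert ((convergence_table.midpoint_field > 88)
                & (convergence_table.midpoint_field < 93)).all()

    def test_profile_positions_increasing_and_span_gap(self, chamber, field_1v):
        p = centerline_profile(field_1v, 51)
        assert (np.diff(p.positions) > 0).all()
        assert p.positions[0] == pytest.approx(-chamber.electrode_gap / 2)
        assert p.positions[-1] == pytest.approx(chamber.electrode_gap / 2)
        assert (p.magnitudes >= 0).all()

    def test_min_samples(self, field_1v):
        with pytest.raises(ValueError):
            centerline_profile(field_1v, 2)

    def test_reflection_symmetry(self, field_1v):
        """|E| at mirrored sample points agrees to 0.5% for the symmetric
        chamber."""
        xs = np.array([2e-3, 4e-3])
        ys = np.array([1e-3, 3e-3])
        X, Y = np.meshgrid(xs, ys)
        base = np.hypot(*field_1v.efield_at(X.ravel(), Y.ravel()).T)
        for sx, sy in [(-1, 1), (1, -1), (-1, -1)]:
            mirrored = np.hypot(
                *field_1v.efield_at(sx * X.ravel(), sy * Y.ravel()).T
            )
            np.testing.assert_allclose(mirrored, base, rtol=5e-3)

    def test_flux_balance_under_one_percent(self, field_1v):
        cur = electrode_current_per_depth(field_1v, 1.0)
        assert cur.flux_imbalance < 0.01

    def test_current_linear_in_conductivity(self, field_1v):
        one = electrode_current_per_depth(field_1v, 1.0)
        two = electrode_current_per_depth(field_1v, 2.0)
        assert two.current_per_depth == pytest.approx(
            2 * one.current_per_depth, rel=1e-12
        )


class TestHomogeneity:
    def test_full_band_is_normalized(self, field_1v):
        assert homogeneity_metrics(field_1v, 0.0, np.inf) == 1.0

    def test_bands_nest(self, field_1v):
        narrow = homogeneity_metrics(field_1v, 85, 95)
        wide = homogeneity_metrics(field_1v, 80, 100)
        assert 0 < narrow <= wide < 1

    def test_matches_direct_area_sum(self, field_1v):
        areas = field_1v.mesh.triangle_areas()
        mags = field_1v.field_magnitude()
        expected = areas[(mags >= 80) & (mags <= 100)].sum() / areas.sum()
        assert homogeneity_metrics(field_1v, 80, 100) == pytest.approx(expected)

    def test_bad_band(self, field_1v):
        with pytest.raises(ValueError):
            homogeneity_metrics(field_1v, 100, 80)


class TestTotalCurrent:
    @pytest.mark.parametrize(
        "sigma,expected_ma",
        [(1.0, 5.95), (2.0, 11.9), (1.3, 7.735)],
    )
    def test_scaling_arithmetic(self, sigma, expected_ma):
        base = CurrentResult(
            current_per_depth=1.75, conductivity=1.0,
            electrode_currents=(1.75, -1.75),
        )
        assert total_current(base, 3.4e-3, sigma) * 1e3 == pytest.approx(
            expected_ma, rel=1e-6
        )

    def test_rescales_from_solve_conductivity(self):
        base = CurrentResult(
            current_per_depth=3.5, conductivity=2.0,
            electrode_currents=(3.5, -3.5),
        )
        assert total_current(base, 3.4e-3, 1.0) == pytest.approx(
            1.75 * 3.4e-3, rel=1e-12
        )

    def test_bad_fill_level(self):
        base = CurrentResult(1.75, 1.0, (1.75, -1.75))
        with pytest.raises(InvalidGeometryError):
            total_current(base, 0.0, 1.0)


class TestAnalyticPlateField:
    def test_printed_value(self):
        assert analytic_plate_field(1.0, 0.011) == pytest.approx(90.91, abs=5e-3)

    def test_linear_scaling(self):
        assert analytic_plate_field(5.0, 0.011) == pytest.approx(454.5, abs=0.05)

    def test_zero_voltage(self):
        assert analytic_plate_field(0.0, 0.011) == 0.0

    def test_zero_gap(self):
        with pytest.raises(InvalidGeometryError):
            analytic_plate_field(1.0, 0.0)


class TestConvergence:
    def test_midpoint_differences_shrink(self, convergence_table):
        mids = convergence_table.midpoint_field.to_numpy()
        diffs = np.abs(np.diff(mids))
        assert diffs[-1] <= diffs[0]
        assert diffs[-1] < 1e-3 * mids[-1]

    def test_current_converges_within_one_percent(self, convergence_table):
        cur = convergence_table.current_per_depth.to_numpy()
        assert abs(cur[-1] - cur[-2]) < 0.01 * cur[-1]

    def test_requires_decreasing_lengths(self, chamber):
        with pytest.raises(ValueError):
            convergence_study(chamber, 1.0, [0.5e-3, 1.0e-3])
        with pytest.raises(ValueError):
            convergence_study(chamber, 1.0, [1.0e-3])
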