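"""Sphere fitting, equal-area projection, heatmaps, occupancy and the trap test."""

import math

import numpy as np
import pytest
from scipy import integrate

from psegrowth import MissingDataError, ValidationError
from psegrowth.apical import (
    FrustumParams,
    annulus_uniformity,
    apical_occupancy,
    density_heatmap,
    division_angle_stats,
    fit_sphere,
    frustum_volume,
    project_equal_area,
    rayleigh_test,
    trap_analysis,
)
from psegrowth.synthetic import SphericalCap, generate_mitotic_coordinates


def _sphere_points(center, radius, n, rng, noise_sd=0.0):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    r = radius + (rng.normal(0.0, noise_sd, n) if noise_sd else np.zeros(n))
    return center + u * r[:, None]


class TestSphereFit:
    def test_exact_recovery(self):
        rng = np.random.default_rng(0)
        center = np.array([12.0, -7.0, 30.0])
        pts = _sphere_points(center, 100.0, 50, rng)
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, center, atol=1e-9)
        assert fit.radius == pytest.approx(100.0, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_noisy_radius_within_tolerance(self):
        rng = np.random.default_rng(1)
        pts = _sphere_points(np.zeros(3), 100.0, 500, rng, noise_sd=1.0)
        fit = fit_sphere(pts)
        assert fit.radius == pytest.approx(100.0, abs=0.2)

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.normal(size=20), rng.normal(size=20), np.zeros(20)])
        with pytest.raises(ValidationError, match="degenerate"):
            fit_sphere(pts)


class TestEqualAreaProjection:
    FIT = None

    def _fit(self, radius=1.0):
        from psegrowth.apical import SphereFit

        return SphereFit(center=np.zeros(3), radius=radius, rms_residual=0.0)

    def test_pole_maps_to_origin(self):
        xy, flag = project_equal_area(np.array([[0.0, 0.0, 1.0]]), self._fit(),
                                      pole=np.array([0.0, 0.0, 1.0]))
        assert np.allclose(xy, 0.0)
        assert not flag[0]

    def test_equator_radius_is_sqrt_two(self):
        xy, _ = project_equal_area(np.array([[1.0, 0.0, 0.0]]), self._fit(),
                                   pole=np.array([0.0, 0.0, 1.0]))
        assert np.hypot(*xy[0]) == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_antipode_flagged_on_boundary(self):
        xy, flag = project_equal_area(np.array([[0.0, 0.0, -1.0]]), self._fit(),
                                      pole=np.array([0.0, 0.0, 1.0]))
        assert flag[0]
        assert np.hypot(*xy[0]) == pytest.approx(2.0, rel=1e-12)

    def test_area_preservation_analytic(self):
        """Projected area of a spherical patch equals R² × its solid angle to 1e-9.

        For a patch [θ1,θ2]×[φ1,φ2] the image is an annular sector of area
        Δφ·(ρ(θ2)²−ρ(θ1)²)/2 with ρ(θ) = 2R sin(θ/2); this must equal
        R²·Δφ·(cos θ1 − cos θ2)."""
        rng = np.random.default_rng(3)
        R = 137.0
        fit = self._fit(R)
        pole = np.array([0.0, 0.0, 1.0])
        for _ in range(200):
            t1, t2 = np.sort(rng.uniform(0.0, math.pi, 2))
            dphi = rng.uniform(0.1, 2.0 * math.pi)
            pts = R * np.array(
                [[math.sin(t) * 1.0, 0.0, math.cos(t)] for t in (t1, t2)]
            )
            xy, _ = project_equal_area(pts, fit, pole=pole)
            rho1, rho2 = np.hypot(xy[:, 0], xy[:, 1])
            planar = dphi * (rho2**2 - rho1**2) / 2.0
            solid = dphi * (math.cos(t1) - math.cos(t2))
            assert planar == pytest.approx(R**2 * solid, rel=1e-9, abs=1e-9)

    def test_uniform_cap_projects_to_uniform_annuli(self):
        """Uniform surface density stays uniform in the plane (20 seeds, ≥17 pass)."""
        cap = SphericalCap(radius=100.0, max_colatitude=math.pi / 2)
        max_rho = 2.0 * cap.radius * math.sin(cap.max_colatitude / 2.0)
        passes = 0
        for seed in range(20):
            pts = generate_mitotic_coordinates(5000, cap, seed=seed)
            fit = fit_sphere(pts)
            xy, _ = project_equal_area(pts, fit, pole=np.array([0.0, 0.0, 1.0]))
            _, p = annulus_uniformity(xy, max_radius=max_rho)
            if p > 0.01:
                passes += 1
        assert passes >= 17


class TestHeatmap:
    def test_zero_points_all_zero(self):
        grid = density_heatmap(np.zeros((0, 2)), bins=16)
        assert np.all(grid.density == 0.0)

    def test_single_bin_density(self):
        xy = np.tile([[0.05, 0.05]], (7, 1))
        grid = density_heatmap(xy, bins=4, extent=(0, 0.4, 0, 0.4))
        assert grid.density.max() == pytest.approx(7 / grid.bin_area)

    def test_mass_conservation_exact_unsmoothed(self):
        rng = np.random.default_rng(4)
        xy = rng.normal(size=(500, 2))
        grid = density_heatmap(xy, bins=32)
        assert grid.total_mass() == pytest.approx(500.0, rel=1e-12)

    def test_mass_conservation_smoothed_away_from_boundary(self):
        rng = np.random.default_rng(5)
        xy = rng.normal(scale=0.5, size=(500, 2))
        grid = density_heatmap(xy, bins=64, extent=(-10, 10, -10, 10), smooth_bandwidth=0.3)
        assert grid.total_mass() == pytest.approx(500.0, rel=1e-6)

    def test_uniform_cap_bin_density_cv(self):
        """Uniform mitoses: CV of fully-in-cap bin densities stays Poisson-small."""
        cap = SphericalCap(radius=100.0, max_colatitude=math.pi / 2)
        max_rho = 2.0 * cap.radius * math.sin(cap.max_colatitude / 2.0)
        pts = generate_mitotic_coordinates(5000, cap, seed=6)
        fit = fit_sphere(pts)
        xy, _ = project_equal_area(pts, fit, pole=np.array([0.0, 0.0, 1.0]))
        grid = density_heatmap(xy, bins=8, extent=(-max_rho, max_rho, -max_rho, max_rho))
        xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
        XX, YY = np.meshgrid(xc, yc, indexing="ij")
        half_diag = math.hypot(grid.x_edges[1] - grid.x_edges[0],
                               grid.y_edges[1] - grid.y_edges[0]) / 2.0
        inside = np.hypot(XX, YY) <= max_rho - half_diag
        dens = grid.density[inside]
        assert dens.std() / dens.mean() < 0.25


class TestDivisionAngles:
    def test_identical_angles_reject_uniformity(self):
        stats = division_angle_stats(np.full(50, 0.7))
        assert stats.resultant_length == pytest.approx(1.0)
        assert stats.p_uniform < 1e-6

    def test_uniform_angles_small_resultant(self):
        rng = np.random.default_rng(7)
        stats = division_angle_stats(rng.uniform(0, math.pi, 1000))
        assert stats.resultant_length < 0.1

    def test_axial_identification(self):
        """0 and π are the same division axis: doubled angles coincide."""
        stats = division_angle_stats(np.array([0.0] * 10 + [math.pi] * 10))
        assert stats.resultant_length == pytest.approx(1.0)

    def test_rayleigh_matches_independent_implementation(self):
        """Cross-check against pingouin's circular Rayleigh test."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        for angles in (rng.vonmises(0.3, 2.0, 80), rng.uniform(-math.pi, math.pi, 80)):
            R, p = rayleigh_test(angles)
            z_ref, p_ref = pingouin.circ_rayleigh(angles)
            assert R**2 * len(angles) == pytest.approx(z_ref, rel=1e-9)
            assert p == pytest.approx(p_ref, rel=1e-6, abs=1e-12)


class TestOccupancy:
    def test_worked_example(self):
        occ = apical_occupancy([10.0], 100, 40_000.0)
        assert occ == pytest.approx(100 * math.pi * 25.0 / 40_000.0)
        assert occ == pytest.approx(0.19635, abs=1e-4)

    def test_zero_mitoses(self):
        assert apical_occupancy([], 0, 40_000.0) == 0.0

    def test_missing_diameters(self):
        with pytest.raises(MissingDataError):
            apical_occupancy([], 10, 40_000.0)

    def test_calibrated_stages_stay_below_20_percent(self, control_table):
        for stage, rows in control_table.groupby_stage().items():
            occ = np.mean([
                apical_occupancy(r.mitotic_diameters, r.n_mitotic, r.apical_area)
                for r in rows
            ])
            assert occ <= 0.20


class TestFrustum:
    def test_cylinder_and_cone_limits(self):
        assert frustum_volume(5.0, 2.0, 2.0) == pytest.approx(math.pi * 4.0 * 5.0)
        assert frustum_volume(5.0, 2.0, 0.0) == pytest.approx(math.pi * 4.0 * 5.0 / 3.0)

    def test_worked_example_is_seven_pi(self):
        assert frustum_volume(3.0, 2.0, 1.0) == pytest.approx(7.0 * math.pi, rel=1e-12)

    def test_against_slice_integration_oracle(self):
        """Volume agrees with ∫ π r(z)² dz over random geometries to 1e-9."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            h = rng.uniform(1.0, 80.0)
            R = rng.uniform(1.0, 10.0)
            r = rng.uniform(0.0, R)

            def radius(z):
                return R + (r - R) * z / h

            oracle, _ = integrate.quad(lambda z: math.pi * radius(z) ** 2, 0.0, h)
            assert frustum_volume(h, R, r) == pytest.approx(oracle, rel=1e-9)

    def test_inverted_radii_rejected(self):
        with pytest.raises(ValidationError):
            frustum_volume(5.0, 1.0, 2.0)


class TestTrap:
    def _frustum(self, density, t_cc=6.0, t_m=0.5):
        return FrustumParams(h=50.0, R=4.0, r=2.0, cell_density=density,
                             t_cc=t_cc, t_m=t_m)

    def test_capacity_formula(self):
        res = trap_analysis(self._frustum(1e-4, t_cc=6.0, t_m=0.5))
        assert res.n_max == pytest.approx(11.0)

    def test_boundary_equality_is_not_a_trap(self):
        from psegrowth.apical import frustum_volume as fv

        volume = fv(50.0, 4.0, 2.0)
        density = 11.0 / volume  # measured exactly at capacity
        res = trap_analysis(self._frustum(density))
        assert res.at_capacity
        assert not res.trap

    def test_strictly_above_capacity_is_a_trap(self):
        from psegrowth.apical import frustum_volume as fv

        density = 11.5 / fv(50.0, 4.0, 2.0)
        assert trap_analysis(self._frustum(density)).trap

    def test_no_trap_at_any_calibrated_stage(self, control_table, config):
        """Measured nuclei per frustum stay below the cycle-time capacity
        throughout development: no proliferative trap."""
        for stage, rows in control_table.groupby_stage().items():
            cal = config.calibration(stage)
            diameters = [d for r in rows for d in r.mitotic_diameters]
            density = float(np.mean([r.n_cells / r.tissue_volume for r in rows]))
            thickness = 0.95 * float(np.mean([np.mean(r.thickness_samples) for r in rows]))
            f = FrustumParams.from_tissue(
                thickness=thickness,
                mitotic_diameter=float(np.mean(diameters)),
                apical_to_basal_area_ratio=cal.apical_to_basal_area_ratio,
                cell_density=density,
                t_cc=cal.cell_cycle_mean,
                t_m=cal.mitosis_duration,
            )
            res = trap_analysis(f)
            assert not res.trap, f"unexpected trap at {stage} hpf"
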