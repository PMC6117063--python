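"""Generator contracts: determinism, zero-noise limits, distributional shape."""

import math

import numpy as np
import pytest
from scipy import stats

from psegrowth.apical import division_angle_stats, rayleigh_test
from psegrowth.profiles import average_profiles, detect_basal_zone
from psegrowth.synthetic import (
    SphericalCap,
    generate_cell_cycle_tracks,
    generate_division_angles,
    generate_intensity_profiles,
    generate_mitotic_coordinates,
    generate_stage_table,
)


class TestStageTable:
    def test_deterministic_under_fixed_seed(self, config):
        a = generate_stage_table(config, "control", n_embryos=4, seed=11)
        b = generate_stage_table(config, "control", n_embryos=4, seed=11)
        assert a.to_frame().equals(b.to_frame())
        c = generate_stage_table(config, "control", n_embryos=4, seed=12)
        assert not a.to_frame().equals(c.to_frame())

    def test_row_count_and_stage_grouping(self, control_table, config):
        assert len(control_table) == 10 * len(config.stages)
        assert control_table.stages == config.stages

    def test_stage_means_near_calibration(self, control_table, config):
        for stage, rows in control_table.groupby_stage().items():
            cal = config.calibration(stage)
            vols = np.array([r.tissue_volume for r in rows])
            se = cal.volume_cv * cal.mean_tissue_volume / math.sqrt(len(rows))
            assert abs(vols.mean() - cal.mean_tissue_volume) < 3.5 * se

    def test_zero_noise_limit_reproduces_calibration(self, noise_free_config):
        table = generate_stage_table(noise_free_config, "control", n_embryos=3, seed=5)
        for stage, rows in table.groupby_stage().items():
            cal = noise_free_config.calibration(stage)
            for r in rows:
                assert r.tissue_volume == pytest.approx(cal.mean_tissue_volume)
                assert np.allclose(r.thickness_samples, cal.mean_thickness)
                assert r.n_cells == round(cal.mean_cells)
                assert r.n_mitotic == round(r.n_cells * cal.mitotic_index)
                assert np.allclose(r.mitotic_diameters, cal.mean_mitotic_diameter)

    def test_hdac1_thickness_never_exceeds_cap(self, config):
        table = generate_stage_table(config, "hdac1", n_embryos=10, seed=2)
        cap = config.analysis.hdac1_thickness_cap
        for r in table.rows:
            assert max(r.thickness_samples) <= cap + 1e-12

    def test_perturbation_scenarios_suppress_proliferation(self, config):
        control = generate_stage_table(config, "control", n_embryos=8, seed=4)
        onset = config.analysis.perturbation_onset_hpf
        for scenario in ("rockout", "hua"):
            perturbed = generate_stage_table(config, scenario, n_embryos=8, seed=4)
            for stage in config.stages:
                if stage <= onset:
                    continue
                m_ctrl = np.mean([r.n_mitotic for r in control.at_stage(stage)])
                m_pert = np.mean([r.n_mitotic for r in perturbed.at_stage(stage)])
                assert m_pert < 0.2 * m_ctrl


class TestMitoticCoordinates:
    CAP = SphericalCap(center=(10.0, -5.0, 3.0), radius=120.0, max_colatitude=math.pi / 2)

    def test_empty_set(self):
        pts = generate_mitotic_coordinates(0, self.CAP, seed=1)
        assert len(pts) == 0

    def test_uniform_colatitude_cdf(self):
        """Uniform-per-area sampling has CDF (1-cos θ)/(1-cos θ_max) in colatitude."""
        pts = generate_mitotic_coordinates(5000, self.CAP, seed=1)
        d = pts.points - np.asarray(self.CAP.center)
        cos_theta = d[:, 2] / np.linalg.norm(d, axis=1)
        theta = np.arccos(np.clip(cos_theta, -1, 1))
        cos_max = math.cos(self.CAP.max_colatitude)

        def cdf(t):
            return (1.0 - np.cos(t)) / (1.0 - cos_max)

        ks = stats.kstest(theta, cdf)
        assert ks.statistic < 0.03

    def test_points_lie_on_the_cap(self):
        pts = generate_mitotic_coordinates(500, self.CAP, seed=2)
        d = np.linalg.norm(pts.points - np.asarray(self.CAP.center), axis=1)
        assert np.allclose(d, self.CAP.radius, rtol=1e-12)

    def test_gradient_mode_rejects_uniformity(self):
        """The azimuthal wave shows up as non-uniform sector counts."""
        pts = generate_mitotic_coordinates(5000, self.CAP, density_mode="gradient", seed=3)
        d = pts.points - np.asarray(self.CAP.center)
        phi = np.arctan2(d[:, 1], d[:, 0])
        counts, _ = np.histogram(phi, bins=12, range=(-math.pi, math.pi))
        assert stats.chisquare(counts).pvalue < 0.01
        uniform = generate_mitotic_coordinates(5000, self.CAP, seed=3)
        du = uniform.points - np.asarray(self.CAP.center)
        cu, _ = np.histogram(np.arctan2(du[:, 1], du[:, 0]), bins=12, range=(-math.pi, math.pi))
        assert stats.chisquare(cu).pvalue > 0.01


class TestTracks:
    def test_zero_cv_gives_equal_cycles(self, noise_free_config):
        cal = noise_free_config.calibration(30.0)
        tracks = generate_cell_cycle_tracks(20, cal, seed=1, n_cycles=3)
        for t in tracks:
            segs = t.segregation_times()
            cycles = np.diff(segs)
            assert np.allclose(cycles, cal.cell_cycle_mean)

    def test_mitosis_duration_flat_across_stages(self, config):
        """T_M is calibrated constant; the estimator must return a flat profile."""
        from psegrowth.proliferation import cycle_lengths

        durations = []
        for stage in config.stages:
            cal = config.calibration(stage)
            tracks = generate_cell_cycle_tracks(40, cal, seed=8)
            st = cycle_lengths(tracks, [stage])[0]
            durations.append(st.mean_mitosis_duration)
        assert np.allclose(durations, durations[0], atol=1e-9)

    def test_track_events_alternate(self, config):
        tracks = generate_cell_cycle_tracks(5, config.calibration(42.0), seed=3)
        for t in tracks:
            kinds = [k for k, _ in t.events]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestProfiles:
    def test_zero_noise_boundary_exact(self, noise_free_config):
        for stage in (20.0, 30.0, 36.0, 42.0):
            cal = noise_free_config.calibration(stage)
            pairs = generate_intensity_profiles(noise_free_config, stage, "control",
                                                n_profiles=1, seed=1)
            zone = detect_basal_zone(pairs[0][0])
            assert zone.basal_extent_fraction == pytest.approx(
                cal.actin_basal_extent_fraction, abs=1e-3
            )

    def test_extent_shrinks_over_development(self, config):
        extents = {}
        for stage in (30.0, 42.0):
            pairs = generate_intensity_profiles(config, stage, "control", n_profiles=9, seed=1)
            mean, _ = average_profiles([a for a, _ in pairs])
            extents[stage] = detect_basal_zone(mean).basal_extent_fraction
        assert extents[42.0] < extents[30.0]

    def test_hdac1_extent_matches_control_30(self, config):
        """No redistribution: the mutant 42-hpf plateau equals the control 30-hpf one."""
        pairs_h = generate_intensity_profiles(config, 42.0, "hdac1", n_profiles=9, seed=1)
        pairs_c = generate_intensity_profiles(config, 30.0, "control", n_profiles=9, seed=1)
        mean_h, _ = average_profiles([a for a, _ in pairs_h])
        mean_c, _ = average_profiles([a for a, _ in pairs_c])
        eh = detect_basal_zone(mean_h).basal_extent_fraction
        ec = detect_basal_zone(mean_c).basal_extent_fraction
        assert eh == pytest.approx(ec, abs=0.02)


class TestDivisionAngles:
    def test_uniform_limit_has_small_resultant(self):
        angles = generate_division_angles(1000, concentration=0.0, seed=1)
        R, _ = rayleigh_test(2.0 * angles)
        assert R < 0.1

    def test_high_concentration_collapses(self):
        angles = generate_division_angles(200, concentration=1e6, seed=1)
        R, _ = rayleigh_test(angles)  # resultant → 1 as the spread vanishes
        assert R > 0.999999

    def test_small_samples_rarely_reject_uniformity(self):
        """At the 15-embryo scale, uniform angles test non-significant >= 90% of seeds."""
        non_significant = 0
        for seed in range(100):
            angles = generate_division_angles(15, concentration=0.0, seed=seed)
            if division_angle_stats(angles).p_uniform >= 0.05:
                non_significant += 1
        assert non_significant >= 90
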