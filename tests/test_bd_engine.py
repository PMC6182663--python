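"""Particle engine: sampling, stepping, boundaries, binning, assembly."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from aucbd.bd_engine import (
    ScanSet,
    SimulationSettings,
    allocate_particles,
    apply_boundaries,
    brownian_displacement,
    counts_to_signal,
    drift_displacement,
    estimate_noise,
    interior_mask,
    sample_initial_positions,
    simulate_component,
    simulate_sample,
)
from aucbd.errors import (
    ConfigurationError,
    ConsistencyError,
    DomainError,
    NumericalError,
)
from aucbd.oracles import (
    no_diffusion_boundary_radius,
    sample_equilibrium_positions,
)
from aucbd.physics import SVEDBERG, CellGeometry, RunConditions, rpm_to_omega
from aucbd.samples import (
    DEFAULT_GEOMETRY,
    lysozyme_like,
    sv_conditions,
    two_component_sample,
)


class TestInitialPositions:
    def test_edges(self, geometry):
        class EdgeRng:
            def __init__(self, u):
                self.u = u

            def random(self, n):
                return np.full(n, self.u)

        r_low = sample_initial_positions(3, geometry, EdgeRng(0.0))
        r_high = sample_initial_positions(3, geometry, EdgeRng(1.0))
        np.testing.assert_allclose(r_low, geometry.r_m, rtol=1e-14)
        np.testing.assert_allclose(r_high, geometry.r_b, rtol=1e-14)

    def test_density_proportional_to_radius(self, geometry, rng):
        """Binned draws divided by r are flat: uniform sector concentration."""
        n = 10 ** 6
        r = sample_initial_positions(n, geometry, rng)
        edges = geometry.bin_edges(50)
        counts, _ = np.histogram(r, bins=edges)
        # expected occupancy of bin i is proportional to the shell area
        expected = np.diff(edges ** 2) / (geometry.r_b ** 2 - geometry.r_m ** 2) * n
        chi2, p = stats.chisquare(counts, expected)
        assert p > 0.001


class TestDisplacements:
    def test_drift_zero_cases(self):
        omega = rpm_to_omega(40_000)
        assert drift_displacement(6.0, 1.91 * SVEDBERG, omega, 0.0) == 0.0
        assert drift_displacement(6.0, 0.0, omega, 480.0) == 0.0

    def test_drift_benchmark_value(self):
        # 1.91 S at 40,000 rpm over 480 s starting at 6 cm
        d = drift_displacement(6.0, 1.91 * SVEDBERG, rpm_to_omega(40_000),
                               480.0)
        assert d == pytest.approx(9.66e-3, rel=1e-3)
        assert d > 0

    def test_brownian_zero_diffusion(self, rng):
        assert not brownian_displacement(100, 0.0, 480.0, rng).any()

    def test_brownian_moments(self, rng):
        d, dt, n = 1.1e-6, 480.0, 10 ** 6
        steps = brownian_displacement(n, d, dt, rng)
        var = 2 * d * dt
        assert abs(steps.mean()) < 4.0 * math.sqrt(var / n)
        assert steps.var() == pytest.approx(var, rel=0.01)


class TestBoundaries:
    def test_inside_unchanged(self, geometry):
        r = np.array([6.0, 6.5, 7.2])
        np.testing.assert_array_equal(apply_boundaries(r, geometry), r)

    def test_single_reflection(self, geometry):
        assert apply_boundaries(7.2 + 0.3, geometry) == pytest.approx(7.2 - 0.3)
        assert apply_boundaries(6.0 - 0.3, geometry) == pytest.approx(6.0 + 0.3)

    @given(st.floats(min_value=-50.0, max_value=50.0))
    def test_any_finite_position_maps_inside(self, r):
        geometry = CellGeometry(6.0, 7.2)
        folded = apply_boundaries(r, geometry)
        assert geometry.r_m <= folded <= geometry.r_b

    def test_nonfinite_rejected(self, geometry):
        with pytest.raises(NumericalError):
            apply_boundaries(np.array([6.5, np.nan]), geometry)


class TestAllocation:
    def test_single_component(self):
        assert allocate_particles([1.0], 1234).tolist() == [1234]

    def test_symmetric_split(self):
        np.testing.assert_array_equal(allocate_particles([0.5, 0.5], 10 ** 6),
                                      [500_000, 500_000])

    def test_two_thirds_power_rule(self):
        counts = allocate_particles([0.60, 0.40], 10 ** 6)
        phi1 = 0.6 ** (2 / 3) / (0.6 ** (2 / 3) + 0.4 ** (2 / 3))
        assert abs(counts[0] - round(phi1 * 10 ** 6)) <= 1
        assert counts.sum() == 10 ** 6

    def test_too_few_particles_rejected(self):
        with pytest.raises(ConfigurationError):
            allocate_particles([0.9999, 0.0001], 100)


class TestCountsToSignal:
    def test_uniform_density_gives_unity(self, geometry, rng):
        n_bins, n_part = 50, 10 ** 6
        r = sample_initial_positions(n_part, geometry, rng)
        counts, _ = np.histogram(r, bins=geometry.bin_edges(n_bins))
        z = counts_to_signal(counts[:, None], geometry, n_bins, n_part)
        # per-bin counting noise is ~1/sqrt(2e4) = 0.7%; allow ~5 sigma
        np.testing.assert_allclose(z[:, 0], 1.0, atol=0.04)
        assert z[:, 0].mean() == pytest.approx(1.0, abs=0.003)

    def test_point_mass(self, geometry):
        n_bins, n_part = 10, 500
        counts = np.zeros((n_bins, 1), dtype=int)
        counts[3, 0] = n_part
        z = counts_to_signal(counts, geometry, n_bins, n_part)
        chi = geometry.bin_width(n_bins)
        r3 = geometry.r_m + 3.5 * chi
        expected = (geometry.r_b ** 2 - geometry.r_m ** 2) / (2 * chi * r3)
        assert z[3, 0] == pytest.approx(expected, rel=1e-12)
        assert np.count_nonzero(z) == 1

    def test_invariant_under_doubling(self, geometry):
        counts = np.array([[10, 20, 30, 40]]).T
        z1 = counts_to_signal(counts, geometry, 4, 100)
        z2 = counts_to_signal(2 * counts, geometry, 4, 200)
        np.testing.assert_allclose(z1, z2, rtol=1e-14)

    def test_conservation_violation_rejected(self, geometry):
        counts = np.array([[10, 20, 30, 39]]).T
        with pytest.raises(ConsistencyError):
            counts_to_signal(counts, geometry, 4, 100)


@pytest.fixture(scope="module")
def quick_settings():
    return SimulationSettings(n_part=50_000, n_steps=20, n_bins=100, seed=7)


class TestSimulateComponent:
    def test_zero_duration_returns_initial_binning(self, geometry):
        run = RunConditions(40_000, 293.15, 0.0, scan_times=(0.0,))
        settings = SimulationSettings(n_part=20_000, n_steps=5, n_bins=50,
                                      seed=1)
        counts = simulate_component(lysozyme_like(), geometry, run, settings,
                                    np.random.default_rng(1))
        assert counts.shape == (50, 1)
        assert counts.sum() == 20_000
        z = counts_to_signal(counts, geometry, 50, 20_000)
        assert z[2:-2, 0].mean() == pytest.approx(1.0, abs=0.05)

    def test_particle_conservation_every_scan(self, geometry, quick_settings):
        run = sv_conditions()
        counts = simulate_component(lysozyme_like(), geometry, run,
                                    quick_settings, np.random.default_rng(2))
        np.testing.assert_array_equal(counts.sum(axis=0),
                                      quick_settings.n_part)

    def test_no_diffusion_boundary_matches_exponential(self, geometry):
        """With diffusion off, the boundary follows r_m exp(s w^2 t)."""
        run = sv_conditions()
        settings = SimulationSettings(n_part=100_000, n_steps=20, n_bins=100,
                                      seed=3, include_diffusion=False)
        comp = lysozyme_like()
        counts = simulate_component(comp, geometry, run, settings,
                                    np.random.default_rng(3))
        chi = geometry.bin_width(100)
        mids = geometry.bin_midpoints(100)
        omega = run.omega
        for j in (4, 7, 10):
            expected = no_diffusion_boundary_radius(comp, geometry, omega,
                                                    run.scan_times[j])
            lowest_occupied = mids[np.nonzero(counts[:, j])[0][0]]
            assert abs(lowest_occupied - expected) <= chi

    def test_equilibrium_start_shows_no_drift(self, geometry):
        """The Boltzmann profile is a fixed point of the BD dynamics."""
        comp = lysozyme_like()
        rpm, temperature = 10_000.0, 293.15
        run = RunConditions(rpm, temperature, 50 * 3600.0,
                            scan_times=(0.0, 50 * 3600.0))
        settings = SimulationSettings(n_part=100_000, n_steps=100, n_bins=50,
                                      seed=4)
        rng = np.random.default_rng(4)
        r0 = sample_equilibrium_positions(settings.n_part, comp, geometry,
                                          run.omega, temperature, rng)
        counts = simulate_component(comp, geometry, run, settings, rng, r0=r0)
        z = counts_to_signal(counts, geometry, 50, settings.n_part)
        mask = interior_mask(geometry.bin_midpoints(50), geometry)
        drift = (z[mask, 1] - z[mask, 0]).mean()
        # noise of the interior mean of a 1e5-particle binned profile
        per_bin_noise = np.sqrt(z[mask, 0].mean() * 50 / settings.n_part)
        assert abs(drift) < 3 * per_bin_noise / math.sqrt(mask.sum())


class TestSimulateSample:
    def test_single_component_matches_counts_to_signal(self, geometry):
        run = sv_conditions()
        settings = SimulationSettings(n_part=30_000, n_steps=20, n_bins=100,
                                      seed=5)
        scan_set = simulate_sample([lysozyme_like()], None, geometry, run,
                                   settings)
        counts = simulate_component(lysozyme_like(), geometry, run, settings,
                                    np.random.default_rng([settings.seed, 0]))
        z = counts_to_signal(counts, geometry, 100, 30_000)
        np.testing.assert_allclose(scan_set.z, z, rtol=1e-12)

    def test_loading_scan_is_unity(self, small_sv_scan_set):
        """At t=0 the interior mean of z/z0 is 1 within binomial noise."""
        ss = small_sv_scan_set
        mask = ss.interior_mask()
        n_part = ss.meta["settings"].n_part
        sampling_sigma = math.sqrt(ss.n_bins / n_part / mask.sum())
        mean0 = ss.z[mask, 0].mean() / ss.z0
        assert abs(mean0 - 1.0) < 3 * sampling_sigma

    def test_bitwise_deterministic(self, geometry):
        run = sv_conditions(n_scans=4)
        settings = SimulationSettings(n_part=20_000, n_steps=10, n_bins=60,
                                      seed=6)
        comps = two_component_sample()
        a = simulate_sample(comps, None, geometry, run, settings)
        b = simulate_sample(comps, None, geometry, run, settings)
        assert np.array_equal(a.z, b.z)
        c = simulate_sample(comps, None, geometry, run, settings, seed=7)
        assert not np.array_equal(a.z, c.z)

    def test_fractions_must_sum_to_one(self, geometry):
        run = sv_conditions(n_scans=3)
        settings = SimulationSettings(n_part=1_000, n_steps=5, n_bins=20,
                                      seed=1)
        with pytest.raises(DomainError):
            simulate_sample(two_component_sample(), [0.7, 0.2], geometry, run,
                            settings)

    def test_step_count_insensitivity(self, geometry):
        """Interior profiles barely depend on the number of BD steps."""
        run = sv_conditions()
        comps = two_component_sample()
        make = lambda n_steps: simulate_sample(
            comps, None, geometry, run,
            SimulationSettings(n_part=100_000, n_steps=n_steps, n_bins=100,
                               seed=8))
        coarse, fine = make(50), make(200)
        noise = estimate_noise(
            comps, None, geometry, run,
            SimulationSettings(n_part=100_000, n_steps=50, n_bins=100),
            n_replicates=3, base_seed=123)
        mask = coarse.interior_mask()
        diff = np.abs(coarse.z[mask, 1:] - fine.z[mask, 1:]).mean()
        assert diff < 3 * noise.interior_mean


class TestEstimateNoise:
    def test_requires_replicates(self, geometry):
        with pytest.raises(ConfigurationError):
            estimate_noise(two_component_sample(), None, geometry,
                           sv_conditions(n_scans=3),
                           SimulationSettings(1_000, 5, 20), 1, 0)

    def test_quadrupling_particles_halves_noise(self, geometry):
        run = sv_conditions(n_scans=5)
        comps = two_component_sample()
        noise = {}
        for n_part in (25_000, 100_000):
            noise[n_part] = estimate_noise(
                comps, None, geometry, run,
                SimulationSettings(n_part, 20, 100), n_replicates=4,
                base_seed=11).interior_mean
        assert noise[25_000] / noise[100_000] == pytest.approx(2.0, rel=0.2)

    def test_wider_bins_are_quieter(self, geometry):
        run = sv_conditions(n_scans=5)
        comps = two_component_sample()
        fine = estimate_noise(comps, None, geometry, run,
                              SimulationSettings(50_000, 20, 100),
                              n_replicates=3, base_seed=17).interior_mean
        coarse = estimate_noise(comps, None, geometry, run,
                                SimulationSettings(50_000, 20, 50),
                                n_replicates=3, base_seed=17).interior_mean
        assert coarse < fine


class TestScanSetValidation:
    def test_shape_and_monotonicity_checks(self):
        with pytest.raises(DomainError):
            ScanSet(radii=[6.0, 6.0, 6.2], times=[0.0], z=np.ones((3, 1)))
        with pytest.raises(DomainError):
            ScanSet(radii=[6.0, 6.1], times=[0.0], z=np.ones((3, 1)))
        with pytest.raises(DomainError):
            ScanSet(radii=[6.0, 6.1], times=[0.0],
                    z=np.array([[1.0], [np.inf]]))

    def test_inferred_geometry_round_trip(self, geometry):
        mids = geometry.bin_midpoints(40)
        ss = ScanSet(radii=mids, times=[0.0], z=np.ones((40, 1)))
        inferred = ss.inferred_geometry()
        assert inferred.r_m == pytest.approx(geometry.r_m, abs=1e-12)
        assert inferred.r_b == pytest.approx(geometry.r_b, abs=1e-12)
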