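"""Solver tests: stability, deposits, stencil correctness, conservation,
the Green's-function oracle, determinism, and cooling-constant fits."""

import math

import numpy as np
import pytest

from fibheat import (
    DepositError,
    GridSpec,
    ImpactEvent,
    SourceSpec,
    StabilityError,
    TemperatureField,
    analytic_fixture,
    cooling_time_constant,
    deposit_impact,
    run_simulation,
    simulate_single_impact,
    stability_timestep,
    step,
)
from fibheat.ftcs_sim import FitError, fit_exponential_decay
from fibheat._kernels import ftcs_step


class TestStabilityTimestep:
    def test_default_grid_collagen_bound_is_23ps(self, skin):
        dt = stability_timestep(skin, GridSpec())
        assert dt == pytest.approx(23e-12, abs=0.5e-12)

    def test_quadratic_in_dx(self, skin):
        assert stability_timestep(skin, GridSpec(dx=10e-9)) == pytest.approx(
            4 * stability_timestep(skin, GridSpec(dx=5e-9))
        )

    def test_stricter_than_classic_3d_cfl(self, skin):
        grid = GridSpec()
        classic = grid.dx**2 / (6 * skin.alpha)
        assert classic == pytest.approx(30.6e-12, abs=0.5e-12)
        assert stability_timestep(skin, grid) < classic


class TestDeposit:
    def test_track_rise_is_94K_for_5kev(self, skin, small_grid, source_5kev):
        # 0.9 * 5000 eV into a 10x10x20 nm cuboid of collagen
        field = TemperatureField.ambient(small_grid)
        out = deposit_impact(field, ImpactEvent(0.0, 0.0, 0.0), source_5kev, skin)
        rise = out.values.max() - small_grid.t_room
        assert rise == pytest.approx(94.38, abs=0.01)
        # uniform over exactly 2 x 2 x 4 voxels at the surface
        hot = out.values > small_grid.t_room
        assert hot.sum() == 16
        assert hot[:, :, 0].any() and not hot[:, :, 4:].any()

    def test_deposited_energy_closes_exactly(self, skin, small_grid, source_5kev):
        field = TemperatureField.ambient(small_grid)
        out = deposit_impact(field, ImpactEvent(0.0, 0.0, 0.0), source_5kev, skin)
        assert out.excess_energy(skin) == pytest.approx(
            source_5kev.heat_per_ion, rel=1e-12
        )

    def test_zero_heat_fraction_leaves_field_unchanged(self, skin, small_grid):
        src = SourceSpec(ion_energy=5.0, heat_fraction=0.0, spot_diameter=50e-9)
        field = TemperatureField.ambient(small_grid)
        out = deposit_impact(field, ImpactEvent(0.0, 0.0, 0.0), src, skin)
        np.testing.assert_array_equal(out.values, field.values)

    def test_two_deposits_at_same_site_add_exactly(self, skin, small_grid, source_5kev):
        field = TemperatureField.ambient(small_grid)
        ev = ImpactEvent(0.0, 10e-9, -5e-9)
        once = deposit_impact(field, ev, source_5kev, skin)
        twice = deposit_impact(once, ev, source_5kev, skin)
        rise1 = once.values - small_grid.t_room
        rise2 = twice.values - small_grid.t_room
        np.testing.assert_allclose(rise2, 2 * rise1, rtol=1e-12)

    def test_track_outside_domain_rejected(self, skin, small_grid, source_5kev):
        field = TemperatureField.ambient(small_grid)
        with pytest.raises(DepositError):
            deposit_impact(field, ImpactEvent(0.0, 200e-9, 0.0), source_5kev, skin)


class TestStep:
    def test_uniform_field_is_a_fixed_point(self, skin, small_grid):
        field = TemperatureField.ambient(small_grid)
        out = step(field, skin, stability_timestep(skin, small_grid))
        np.testing.assert_array_equal(out.values, field.values)

    def test_single_hot_voxel_follows_the_stencil(self, skin, small_grid):
        dt = stability_timestep(skin, small_grid)
        r = skin.alpha * dt / small_grid.dx**2
        field = TemperatureField.ambient(small_grid)
        field.values[20, 20, 10] += 100.0
        out = step(field, skin, dt)
        t0 = small_grid.t_room
        assert out.values[20, 20, 10] - t0 == pytest.approx(100 * (1 - 6 * r), rel=1e-12)
        for idx in [(19, 20, 10), (21, 20, 10), (20, 19, 10), (20, 21, 10),
                    (20, 20, 9), (20, 20, 11)]:
            assert out.values[idx] - t0 == pytest.approx(100 * r, rel=1e-12)

    def test_timestep_above_bound_rejected(self, skin, small_grid):
        field = TemperatureField.ambient(small_grid)
        with pytest.raises(StabilityError):
            step(field, skin, 1.5 * stability_timestep(skin, small_grid))

    def test_numba_and_numpy_kernels_agree(self, skin, small_grid):
        rng = np.random.default_rng(0)
        T = 300.0 + rng.random(small_grid.shape)
        r = 0.1
        for boundary in ("dirichlet5", "neumann_all"):
            a = np.empty_like(T)
            b = np.empty_like(T)
            ftcs_step(T.copy(), a, r, boundary=boundary, use_numba=True)
            ftcs_step(T.copy(), b, r, boundary=boundary, use_numba=False)
            np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)


class TestConservationAndMaximumPrinciple:
    def test_energy_conserved_under_all_neumann_stepping(self, skin, small_grid, source_5kev):
        """Total excess thermal energy is invariant to 1e-10 relative over 200 steps."""
        field = TemperatureField.ambient(small_grid)
        field = deposit_impact(field, ImpactEvent(0.0, 0.0, 0.0), source_5kev, skin)
        field = deposit_impact(field, ImpactEvent(0.0, 30e-9, -20e-9), source_5kev, skin)
        e0 = field.excess_energy(skin)
        assert e0 == pytest.approx(2 * source_5kev.heat_per_ion, rel=1e-12)
        dt = stability_timestep(skin, small_grid)
        for _ in range(200):
            field = step(field, skin, dt, boundary="neumann_all")
        assert field.excess_energy(skin) == pytest.approx(e0, rel=1e-10)

    @pytest.mark.parametrize("boundary", ["dirichlet5", "neumann_all"])
    def test_maximum_principle_without_sources(self, skin, small_grid, boundary):
        rng = np.random.default_rng(42)
        values = small_grid.t_room + 50 * rng.random(small_grid.shape)
        field = TemperatureField(values=values, time=0.0, grid=small_grid)
        dt = stability_timestep(skin, small_grid)
        hi, lo = field.values.max(), field.values.min()
        for _ in range(50):
            field = step(field, skin, dt, boundary=boundary)
            assert field.values.max() <= hi * (1 + 1e-14)
            assert field.values.min() >= lo * (1 - 1e-14)
            hi, lo = field.values.max(), field.values.min()


class TestGreensFunctionOracle:
    def test_voxel_deposit_matches_image_source_kernel(self, skin, small_grid):
        """A single-voxel surface deposit diffused n >= 10 steps agrees with the
        instantaneous point-source solution (with its insulated-surface image)
        to within 10% at the peak voxel."""
        dx = small_grid.dx
        src = SourceSpec(ion_energy=5.0, heat_fraction=0.9,
                         track_dims=(dx, dx, dx), spot_diameter=50e-9)
        field = TemperatureField.ambient(small_grid)
        field = deposit_impact(field, ImpactEvent(0.0, 0.0, 0.0), src, skin)
        Q = src.heat_per_ion
        dt = stability_timestep(skin, small_grid)
        ix, iy, iz = np.unravel_index(field.values.argmax(), field.values.shape)
        center = ((ix + 0.5) * dx, (iy + 0.5) * dx, (iz + 0.5) * dx)
        n_checks = {10, 20, 40}
        for n in range(1, 41):
            field = step(field, skin, dt)
            if n in n_checks:
                oracle = analytic_fixture(skin, Q, n * dt, small_grid, center=center)
                peak_idx = np.unravel_index(field.values.argmax(), field.values.shape)
                got = field.values[peak_idx] - small_grid.t_room
                want = oracle.values[peak_idx] - small_grid.t_room
                assert got == pytest.approx(want, rel=0.10), f"step {n}"


class TestRunSimulation:
    def test_zero_current_keeps_ambient(self, skin, small_grid, source_5kev):
        trace = run_simulation(small_grid, source_5kev, skin, current=0.0,
                               duration=2e-9, store_final_field=True)
        assert trace.n_impacts == 0
        np.testing.assert_array_equal(trace.max_trace, small_grid.t_room)
        np.testing.assert_array_equal(trace.final_field.values, small_grid.t_room)

    def test_seeded_runs_are_bit_identical(self, skin, small_grid, source_5kev):
        kwargs = dict(current=1.4e-9, duration=3e-9, seed=11)
        a = run_simulation(small_grid, source_5kev, skin, **kwargs)
        b = run_simulation(small_grid, source_5kev, skin, **kwargs)
        c = run_simulation(small_grid, source_5kev, skin, current=1.4e-9,
                           duration=3e-9, seed=12)
        np.testing.assert_array_equal(a.max_trace, b.max_trace)
        np.testing.assert_array_equal(a.final_field.values, b.final_field.values)
        assert not np.array_equal(a.max_trace, c.max_trace)

    def test_default_dt_respects_bound_and_snapshot_cadence(self, skin, small_grid,
                                                            source_5kev):
        trace = run_simulation(small_grid, source_5kev, skin, current=1e-9,
                               duration=1e-9, snapshot_interval=1e-10)
        assert trace.dt <= stability_timestep(skin, small_grid) * (1 + 1e-12)
        assert trace.dt == pytest.approx(20e-12)
        np.testing.assert_allclose(np.diff(trace.snapshot_times), 1e-10, rtol=1e-9)

    def test_spot_larger_than_domain_rejected(self, skin, small_grid):
        src = SourceSpec(ion_energy=5.0, spot_diameter=400e-9)
        with pytest.raises(Exception):
            run_simulation(small_grid, src, skin, current=1e-9, duration=1e-9)

    def test_field_never_below_ambient(self, skin, small_grid, source_5kev):
        trace = run_simulation(small_grid, source_5kev, skin, current=1.4e-9,
                               duration=2e-9, seed=5)
        assert trace.final_field.values.min() >= small_grid.t_room - 1e-9
        assert (trace.max_trace >= small_grid.t_room).all()


class TestCoolingConstant:
    def test_pure_exponential_recovered_within_one_percent(self):
        tau = 170e-12
        t = np.linspace(0, 1e-9, 200)
        fitted = fit_exponential_decay(t, 80 * np.exp(-t / tau))
        assert fitted == pytest.approx(tau, rel=0.01)

    def test_non_decaying_trace_raises(self):
        t = np.linspace(0, 1e-9, 50)
        with pytest.raises(FitError):
            fit_exponential_decay(t, np.full_like(t, 5.0))

    def test_5kev_track_cools_faster_than_30kev_track(self, skin):
        """Track-scale cooling constants: hundreds of ps for the small 5 keV
        track, of order 1 ns for the larger 30 keV-parameterized track."""
        grid = GridSpec(nx=64, ny=64, nz=48)
        src5 = SourceSpec(ion_energy=5.0, heat_fraction=0.9, spot_diameter=50e-9)
        src30 = SourceSpec(ion_energy=30.0, heat_fraction=0.9,
                           track_dims=(20e-9, 20e-9, 45e-9), spot_diameter=50e-9)
        tr5 = simulate_single_impact(grid, src5, skin, duration=1.2e-9)
        tr30 = simulate_single_impact(grid, src30, skin, duration=5e-9)
        tau5 = cooling_time_constant(tr5, (50e-12, 600e-12))
        tau30 = cooling_time_constant(tr30, (200e-12, 3e-9))
        assert tau5 < tau30
        assert 1e-10 < tau5 < 1e-9          # order 100 ps, as for the small track
        assert 3e-10 < tau30 < 5e-9         # order 1 ns for the bigger track
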