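"""Advection–diffusion transport: oracles, conservation, maximum principle."""

import numpy as np
import pytest

import spherochip as sc
from spherochip.analytic import sphere_dirichlet_concentration
from spherochip.flow import FlowBC, FlowField
from spherochip.geometry import Region, closed_box_grid, duct_grid
from spherochip.transport import (MonotonicityError, TransportProperties,
                                  effective_diffusivity, flux_fields,
                                  mass_balance_report, solve_transport)


def zero_flow(grid) -> FlowField:
    nx, ny, nz = grid.shape
    return FlowField(grid=grid, u=np.zeros((nx + 1, ny, nz)),
                     v=np.zeros((nx, ny + 1, nz)), w=np.zeros((nx, ny, nz + 1)),
                     p=np.zeros(grid.shape))


class TestEffectiveDiffusivity:
    def test_bruggeman_below_free_value_and_increasing(self):
        D = 1.6e-10
        vals = [effective_diffusivity(D, e) for e in (0.2, 0.5, 0.9)]
        assert all(v < D for v in vals)
        assert vals[0] < vals[1] < vals[2]


class TestEquilibriumAndBounds:
    def test_uniform_initial_state_is_stationary(self):
        grid = closed_box_grid((6, 6, 6), 10.0)
        props = TransportProperties(inlet_concentration=0.0)
        hist = solve_transport(grid, zero_flow(grid), props, t_end_s=50.0,
                               dt_s=5.0, c0=3.0e-3,
                               probes_um={"mid": (30.0, 30.0, 30.0)})
        assert np.allclose(hist.fields[-1][grid.fluid], 3.0e-3, rtol=1e-12)

    def test_concentration_bounded_by_inlet_value(self, ref_dsc_run):
        grid, _, hist = ref_dsc_run
        for f in hist.fields:
            assert f.min() >= -1e-12
            assert f.max() <= hist.c_in * (1 + 1e-7)

    def test_core_trace_monotone_under_constant_inlet(self, ref_ssc_run):
        _, _, hist = ref_ssc_run
        core = hist.probes["core"]
        assert np.all(np.diff(core) >= -1e-12 * hist.c_in)


@pytest.fixture(scope="module")
def sphere_run():
    """Voxelized 50 um sphere with its surface bath held at c0 = 1."""
    h, n = 5.0, 22
    grid = closed_box_grid((n, n, n), h)
    x = (np.arange(n) + 0.5) * h - n * h / 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    outside = np.sqrt(X**2 + Y**2 + Z**2) >= 50.0
    D = 1.0e-10
    tau = (50e-6) ** 2 / D
    props = TransportProperties(free_diffusivity=D, inlet_concentration=0.0)
    hist = solve_transport(grid, zero_flow(grid), props, t_end_s=tau,
                           dt_s=tau / 400,
                           probes_um={"center": (n * h / 2,) * 3},
                           fixed_mask=outside, fixed_value=1.0)
    return D, tau, hist


class TestSphereDiffusionOracle:
    def test_center_concentration_at_diffusion_time(self, sphere_run):
        D, tau, hist = sphere_run
        ref = sphere_dirichlet_concentration(0.0, tau, 50e-6, D, 1.0)
        sim = hist.probes["center"][-1]
        assert sim == pytest.approx(ref, abs=0.03)

    def test_center_transient_tracks_series(self, sphere_run):
        D, tau, hist = sphere_run
        for frac in (0.1, 0.2, 0.4):
            ref = sphere_dirichlet_concentration(0.0, frac * tau, 50e-6, D, 1.0)
            sim = hist.probes["center"][int(round(frac * 400))]
            assert sim == pytest.approx(ref, abs=0.05)


class TestAdvectionFront:
    def test_front_advances_at_mean_speed(self):
        """Plug flow with small D: the mid-height front moves at u."""
        grid = duct_grid(length_um=400, width_um=40, height_um=40, spacing_um=10)
        flow = zero_flow(grid)
        u = 1.0e-4  # uniform plug velocity m/s
        flow.u[:] = u
        props = TransportProperties(free_diffusivity=1e-13,
                                    inlet_concentration=1.0e-2)
        t_end = 2.0  # front travels 200 um = 20 cells
        hist = solve_transport(grid, flow, props, t_end_s=t_end, dt_s=0.02,
                               bc=FlowBC(q2_ml_h=0.01))
        c = hist.fields[-1][:, 2, 2] / props.inlet_concentration
        front = np.interp(0.5, c[::-1], np.arange(len(c))[::-1])
        expected = u * t_end / grid.spacing_m  # 20 cells
        # first-order upwind smears the front but its midpoint stays on u*t
        assert front == pytest.approx(expected, abs=2.5)


class TestMassBalance:
    def test_closed_domain_residual_roundoff(self):
        grid = closed_box_grid((6, 6, 6), 10.0)
        props = TransportProperties(inlet_concentration=0.0)
        hist = solve_transport(grid, zero_flow(grid), props, t_end_s=50.0,
                               dt_s=5.0, c0=1e-3)
        assert mass_balance_report(hist) < 1e-12

    def test_perfused_run_closes_within_half_percent(self, ref_dsc_run):
        _, _, hist = ref_dsc_run
        assert mass_balance_report(hist) < 0.005

    def test_halving_dt_does_not_worsen_closure(self):
        d = sc.decode_name("P5.Wr6.R12.Hr6.Wl6.Hl6")
        from spherochip.config import SolverOptions
        res = []
        for dt in (20.0, 10.0):
            sol = SolverOptions(resolution_um=20.0, t_end_s=600.0, dt_s=dt)
            _, _, hist = sc.simulate_design(d, solver=sol)
            res.append(mass_balance_report(hist))
        assert res[1] <= res[0] * 1.5 + 1e-12


class TestFluxFields:
    def test_uniform_concentration_no_diffusive_flux(self, ref_dsc_run):
        grid, flow, _ = ref_dsc_run
        props = TransportProperties()
        c = np.full(grid.shape, 5e-3)
        fx = flux_fields(c, flow, props)
        interior = ~grid.solid
        assert np.abs(fx.diffusive[interior]).max() < 1e-18

    def test_zero_velocity_no_advective_flux(self):
        grid = closed_box_grid((6, 6, 6), 10.0)
        c = np.random.default_rng(0).random(grid.shape) * 1e-3
        fx = flux_fields(c, zero_flow(grid), TransportProperties())
        assert np.all(fx.advective == 0.0)

    def test_linear_profile_gives_ficks_law_magnitude(self):
        grid = closed_box_grid((10, 6, 6), 10.0)
        D = 1.6e-10
        c0, L = 1e-2, 10 * 10e-6
        x = (np.arange(10) + 0.5) * 10e-6
        c = np.broadcast_to((c0 * x / L)[:, None, None], grid.shape).copy()
        fx = flux_fields(c, zero_flow(grid), TransportProperties(free_diffusivity=D))
        expected = D * c0 / L
        mag = np.linalg.norm(fx.diffusive, axis=-1)
        assert np.allclose(mag, expected, rtol=1e-9)

    def test_diffusive_flux_antiparallel_to_gradient(self):
        grid = closed_box_grid((10, 6, 6), 10.0)
        x = (np.arange(10) + 0.5) * 10e-6
        c = np.broadcast_to((1e-2 * x / 1e-4)[:, None, None], grid.shape).copy()
        fx = flux_fields(c, zero_flow(grid), TransportProperties())
        assert np.all(fx.diffusive[..., 0] < 0)  # gradient is +x


class TestLongTimeLimit:
    def test_domain_saturates_to_inlet_concentration(self):
        """At many advective fill times every fluid region approaches c_in."""
        d = sc.decode_name("P9.Wr6.R12.Hr6.Wl6.Hl6")
        from spherochip.config import SolverOptions
        sol = SolverOptions(resolution_um=20.0, t_end_s=7200.0, dt_s=10.0)
        grid, flow, hist = sc.simulate_design(d, solver=sol)
        final = hist.fields[-1]
        for region in (Region.CHANNEL_R, Region.WELL, Region.SPHEROID):
            mean = final[grid.region_mask(region)].mean()
            assert mean >= 0.95 * hist.c_in
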