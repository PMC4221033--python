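"""Transport operator tests: conservation, positivity, and closed-form
oracles for advection, diffusion and sinking."""

import numpy as np
import pytest

from alborun.bio import BioParams
from alborun.flow import fixture_flows
from alborun.grid import Grid
from alborun.transport import (
    CFLError,
    FlowField,
    StabilityError,
    advect,
    diffuse,
    sink,
)


def _rand_field(g, seed=0):
    return np.random.default_rng(seed).random((g.nz, g.ny, g.nx))


class TestAdvect:
    def test_zero_flow_identity(self, small_grid):
        C = _rand_field(small_grid)
        out = advect(C, fixture_flows(small_grid)["zero"], small_grid, 3600.0)
        assert np.array_equal(out, C)

    def test_uniform_tracer_invariant_under_divergence_free_flow(self, small_grid):
        C = np.ones((small_grid.nz, small_grid.ny, small_grid.nx))
        out = advect(C, fixture_flows(small_grid)["gyre"], small_grid, 3600.0)
        assert np.max(np.abs(out - 1.0)) < 1e-12

    def test_unit_cfl_pulse_shift(self):
        """At CFL exactly 1 the limited upwind scheme shifts a 1-D pulse by
        exactly one cell."""
        g = Grid.regular(nx=20, ny=1, nz=1, dx=1000.0, dy=1000.0, depth=10.0)
        u = 0.5
        flow = FlowField(
            u=np.full((1, 1, 21), u), v=np.zeros((1, 2, 20)), w=np.zeros((2, 1, 20))
        )
        C = np.zeros((1, 1, 20))
        C[0, 0, 5] = 1.0
        C[0, 0, 6] = 0.5
        out = advect(C, flow, g, dt=g.dx / u)
        expected = np.roll(C, 1, axis=2)
        assert np.allclose(out[0, 0, 2:-2], expected[0, 0, 2:-2], atol=1e-14)

    def test_cfl_violation_raises(self, small_grid):
        flow = fixture_flows(small_grid)["channel"]
        with pytest.raises(CFLError, match="sub-step"):
            advect(_rand_field(small_grid), flow, small_grid, dt=2e5)

    def test_conservation_and_positivity_long_integration(self, small_grid):
        """Mass constant to 1e-10 relative and no negatives over 1000 steps
        in the closed gyre."""
        g = small_grid
        flow = fixture_flows(g)["gyre"]
        C = _rand_field(g, seed=3)
        m0 = g.total_mass(C)
        lo, hi = C.min(), C.max()
        for _ in range(1000):
            C = advect(C, flow, g, 3600.0)
        assert abs(g.total_mass(C) - m0) / m0 < 1e-10
        assert C.min() >= lo - 1e-14 and C.max() <= hi + 1e-14

    def test_rotating_patch_grid_convergence(self):
        """Solid-body rotation of a Gaussian patch: error decreases with
        resolution."""
        errors = []
        for n in (20, 40):
            g = Grid.regular(nx=n, ny=n, nz=1, dx=200e3 / n, dy=200e3 / n, depth=10.0)
            flow = fixture_flows(g)["rotation"]
            omega = 1e-5
            quarter = 0.5 * np.pi / omega
            n_steps = 160 if n == 40 else 80
            dt = quarter / n_steps
            X, Y = np.meshgrid(g.x_centers(), g.y_centers())
            cx = cy = 100e3
            r0, sig = 40e3, 15e3
            patch = lambda x0, y0: np.exp(
                -((X - x0) ** 2 + (Y - y0) ** 2) / (2 * sig**2)
            )[None]
            C = patch(cx + r0, cy)
            for _ in range(n_steps):
                C = advect(C, flow, g, dt)
            exact = patch(cx, cy + r0)  # counterclockwise quarter turn
            errors.append(np.abs(C - exact).mean())
        assert errors[1] < errors[0]


class TestDiffuse:
    def test_uniform_field_unchanged(self, small_grid):
        C = np.full((small_grid.nz, small_grid.ny, small_grid.nx), 2.5)
        out = diffuse(C, 10.0, 1e-6, small_grid, 1800.0)
        assert np.allclose(out, 2.5, atol=1e-13)

    def test_mass_conserved_and_variance_decreases(self, small_grid):
        C = _rand_field(small_grid, seed=5)
        m0 = small_grid.total_mass(C)
        v0 = C.var()
        out = C
        for _ in range(50):
            out = diffuse(out, 50.0, 1e-4, small_grid, 1800.0)
        assert abs(small_grid.total_mass(out) - m0) / m0 < 1e-12
        assert out.var() < v0

    def test_two_box_exponential_equilibration(self):
        """Two equal layers starting at (2, 0): the difference decays by the
        discrete factor (1 - 2*kappa*dt/dz^2) each step, approaching (1, 1)."""
        g = Grid.regular(nx=1, ny=1, nz=2, dx=1e3, dy=1e3, depth=20.0)
        dz = 10.0
        kappa, dt = 1e-3, 2e4
        factor = 1 - 2 * kappa * dt / dz**2
        C = np.array([2.0, 0.0]).reshape(2, 1, 1)
        diff = 2.0
        for n in range(40):
            C = diffuse(C, 0.0, kappa, g, dt)
            diff *= factor
            assert C[0, 0, 0] - C[1, 0, 0] == pytest.approx(diff, rel=1e-12, abs=1e-13)
        assert np.all(np.abs(C - 1.0) < 0.1)
        # monotone approach from both sides
        assert 1.0 < C[0, 0, 0] < 2.0 and 0.0 < C[1, 0, 0] < 1.0

    def test_stability_violation_raises(self, small_grid):
        with pytest.raises(StabilityError):
            diffuse(_rand_field(small_grid), 1e6, 1e-6, small_grid, 3600.0)


class TestSink:
    def test_zero_field(self, small_grid, params):
        D, export = sink(np.zeros((small_grid.nz, small_grid.ny, small_grid.nx)),
                         small_grid, params, 3600.0)
        assert not D.any() and not export.any()

    def test_column_mass_balance(self, small_grid, params):
        D0 = _rand_field(small_grid, seed=11) * 2
        col0 = np.sum(D0 * small_grid.dz[:, None, None], axis=0)
        D1, export = sink(D0, small_grid, params, 86400.0)
        col1 = np.sum(D1 * small_grid.dz[:, None, None], axis=0)
        assert np.allclose(col1 - col0, -export, rtol=1e-12, atol=1e-12)
        assert np.all(export >= 0) and np.all(D1 >= 0)

    def test_first_order_transfer_from_top_layer(self, params):
        """For a small step, the upwind flux moves w_D(D)*D*dt/dz into the
        layer below."""
        g = Grid.regular(nx=1, ny=1, nz=3, dx=1e3, dy=1e3, depth=30.0)
        D = np.zeros((3, 1, 1))
        D[0] = 1.0
        dt = 60.0  # seconds; sub-CFL so no internal sub-stepping effects
        w = params.w_Dmax * 1.0 / (params.S_D + 1.0) / 86400.0  # m/s
        D1, export = sink(D, g, params, dt)
        transfer = w * 1.0 * dt / 10.0
        assert D1[1, 0, 0] == pytest.approx(transfer, rel=1e-9)
        assert D1[0, 0, 0] == pytest.approx(1.0 - transfer, rel=1e-9)
        assert export[0, 0] == 0.0


class TestMasks:
    def test_land_cells_stay_zero_and_mass_conserved(self, params):
        g = Grid.regular(nx=8, ny=6, nz=4, dx=5e3, dy=5e3, depth=100.0)
        mask = g.mask.copy()
        mask[:, :2, :3] = False  # a land block
        g = Grid(dx=g.dx, dy=g.dy, z_w=g.z_w, mask=mask)
        C = np.where(g.mask, 1.0 + _rand_field(g, seed=2), 0.0)
        m0 = g.total_mass(C)
        flow = fixture_flows(g)["gyre"].masked(g)
        flow.w[:] = 0.0
        for _ in range(20):
            C = advect(C, flow, g, 1800.0)
            C = diffuse(C, 20.0, 1e-5, g, 1800.0)
        assert not C[~g.mask].any()
        assert abs(g.total_mass(C) - m0) / m0 < 1e-11
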