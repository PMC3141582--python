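"""Boundary-coupling tests: kernel identities, spreading/interpolation,
fiber forces, and the coupled step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibcms import (
    BoundaryState,
    FiberModel,
    FluidParams,
    FluidState,
    GridSpec,
    delta_weight,
    elastic_energy,
    fiber_force,
    interpolate_velocity,
    make_ellipse_membrane,
    spread_force,
    step_fsi,
)
from ibcms.diagnostics import chamber_volume


def point_cloud_model(X):
    """Springless model for pure spread/interp tests."""
    return FiberModel(
        points=X,
        spring_i=np.empty(0, dtype=int),
        spring_j=np.empty(0, dtype=int),
        spring_k=np.empty(0),
        spring_L0=np.empty(0),
    )


class TestDeltaKernel:
    def test_center_and_node_values(self):
        assert delta_weight(0.0) == pytest.approx(0.5)
        assert delta_weight(1.0) == pytest.approx(0.25)
        assert delta_weight(-1.0) == pytest.approx(0.25)

    def test_compact_support(self):
        assert delta_weight(2.0) == 0.0
        assert delta_weight(-3.7) == 0.0
        assert delta_weight(1.999) > 0.0

    def test_nonnegative(self):
        r = np.linspace(-2.5, 2.5, 1001)
        assert np.all(delta_weight(r) >= 0.0)

    @given(st.floats(-10.0, 10.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_moment_identities(self, r):
        """Partition of unity and zero first moment for every real shift."""
        j = np.arange(np.floor(r) - 3, np.floor(r) + 4)
        w = delta_weight(r - j)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-13)
        assert np.sum((r - j) * w) == pytest.approx(0.0, abs=1e-12)


class TestSpreadInterp:
    def test_zero_force_spreads_to_zero(self, grid_cm, rng):
        X = rng.uniform(0, 16, (10, 2))
        bs = BoundaryState(X)
        f = spread_force(bs, point_cloud_model(X), grid_cm)
        assert np.all(f == 0.0)

    def test_total_force_conserved(self, grid_cm, rng):
        X = rng.uniform(0, 16, (25, 2))
        F = rng.standard_normal((25, 2))
        bs = BoundaryState(X, F)
        f = spread_force(bs, point_cloud_model(X), grid_cm)
        total = f.sum(axis=(1, 2)) * grid_cm.cell_volume
        assert np.allclose(total, F.sum(axis=0), atol=1e-12)

    def test_on_node_stencil_weights(self, grid_cm):
        # a point exactly on a cell center spreads with center weight 0.25
        # (= 0.5^2 in 2-D) onto a 4x4 stencil
        X = np.array([[8.125, 8.125]])  # cell center (32, 32)
        F = np.array([[1.0, 0.0]])
        bs = BoundaryState(X, F)
        f = spread_force(bs, point_cloud_model(X), grid_cm)
        fx = f[0] * grid_cm.cell_volume
        assert fx[32, 32] == pytest.approx(0.25)
        assert np.count_nonzero(fx) <= 16
        assert fx[33, 32] == pytest.approx(0.125)  # 0.5 * 0.25

    def test_uniform_field_interpolates_exactly(self, grid_cm, rng):
        u = np.empty((2, *grid_cm.n))
        u[0], u[1] = 3.0, -1.5
        X = rng.uniform(0, 16, (40, 2))
        bs = BoundaryState(X)
        U = interpolate_velocity(u, bs, grid_cm)
        assert np.allclose(U[:, 0], 3.0, atol=1e-13)
        assert np.allclose(U[:, 1], -1.5, atol=1e-13)

    def test_linear_field_reproduced(self, grid_cm, rng):
        X0, Y0 = grid_cm.meshgrid()
        u = np.stack([1.0 + 2 * X0 + 3 * Y0, -0.5 + 0.25 * X0 - 1.5 * Y0])
        X = rng.uniform(2, 14, (30, 2))  # away from the periodic seam
        U = interpolate_velocity(u, BoundaryState(X), grid_cm)
        exact = np.stack(
            [1 + 2 * X[:, 0] + 3 * X[:, 1], -0.5 + 0.25 * X[:, 0] - 1.5 * X[:, 1]],
            axis=1,
        )
        assert np.allclose(U, exact, atol=1e-12)

    def test_adjointness(self, grid_cm, rng):
        X = rng.uniform(0, 16, (60, 2))
        F = rng.standard_normal((60, 2))
        u = rng.standard_normal((2, *grid_cm.n))
        model = point_cloud_model(X)
        bs = BoundaryState(X, F)
        lhs = float(np.sum(F * interpolate_velocity(u, bs, grid_cm)))
        rhs = float(np.sum(spread_force(bs, model, grid_cm) * u)) * grid_cm.cell_volume
        assert abs(lhs - rhs) <= 1e-12 * abs(lhs)

    def test_periodic_wrap(self, grid_cm):
        # a point just inside the seam spreads onto both sides
        X = np.array([[0.05, 8.0]])
        F = np.array([[1.0, 1.0]])
        bs = BoundaryState(X, F)
        f = spread_force(bs, point_cloud_model(X), grid_cm)
        assert f[0][-1, :].sum() != 0.0 and f[0][0, :].sum() != 0.0
        total = f.sum(axis=(1, 2)) * grid_cm.cell_volume
        assert np.allclose(total, [1.0, 1.0], atol=1e-12)


class TestFiberForce:
    def test_equilibrium_network_is_force_free(self):
        model, bs = make_ellipse_membrane(3.0, 3.0, 64, 1e4, center=(8, 8))
        F = fiber_force(bs, model, 0.0)
        assert np.max(np.abs(F)) < 1e-9

    def test_two_point_spring_hooke(self):
        model = FiberModel(
            points=np.array([[0.0, 0.0], [2.0, 0.0]]),
            spring_i=[0], spring_j=[1], spring_k=[100.0], spring_L0=[1.5],
        )
        bs = BoundaryState(model.points.copy())
        F = fiber_force(bs, model, 0.0)
        # stretched by 0.5 -> tension 50 pulling the endpoints together
        assert np.allclose(F[0], [50.0, 0.0])
        assert np.allclose(F[1], [-50.0, 0.0])

    def test_coincident_endpoints_defined_limit(self):
        model = FiberModel(
            points=np.array([[1.0, 1.0], [1.0, 1.0 + 1e-300]]),
            spring_i=[0], spring_j=[1], spring_k=[100.0], spring_L0=[0.5],
        )
        bs = BoundaryState(np.array([[1.0, 1.0], [1.0, 1.0]]))
        F = fiber_force(bs, model, 0.0)
        assert np.all(np.isfinite(F))
        assert np.allclose(F, 0.0)

    def test_stretched_ring_net_force_zero_and_inward(self):
        model, bs = make_ellipse_membrane(3.0, 3.0, 64, 1e4, center=(8, 8),
                                          rest_length_factor=0.0)
        F = fiber_force(bs, model, 0.0)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)
        radial = (bs.X - np.array([8.0, 8.0]))
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        assert np.all(np.sum(F * radial, axis=1) < 0.0)

    def test_slack_tether_engages_beyond_slack(self):
        model = FiberModel(
            points=np.array([[0.0, 0.0]]),
            spring_i=np.empty(0, dtype=int), spring_j=np.empty(0, dtype=int),
            spring_k=np.empty(0), spring_L0=np.empty(0),
            tether_idx=[0], tether_target=[[0.0, 0.0]], tether_k=[10.0],
            tether_slack=[1.0],
        )
        inside = fiber_force(BoundaryState(np.array([[0.5, 0.0]])), model, 0.0)
        assert np.allclose(inside, 0.0)
        outside = fiber_force(BoundaryState(np.array([[2.0, 0.0]])), model, 0.0)
        assert np.allclose(outside[0], [-10.0, 0.0])  # pulls back by k*(d-slack)

    def test_activation_modulates_springs(self):
        def act(t_norm, group):
            return (2.0, 0.5) if group == "g" else (1.0, 1.0)

        model = FiberModel(
            points=np.array([[0.0, 0.0], [1.0, 0.0]]),
            spring_i=[0], spring_j=[1], spring_k=[100.0], spring_L0=[1.0],
            spring_group=np.array(["g"], dtype=object), activation=act,
        )
        bs = BoundaryState(model.points.copy())
        F0 = fiber_force(bs, model, 0.0)
        # k -> 200, L0 -> 0.5: tension 200 * 0.5 = 100
        assert np.allclose(F0[0], [100.0, 0.0])

    def test_t_norm_out_of_range_rejected(self):
        model = FiberModel(
            points=np.zeros((1, 2)),
            spring_i=np.empty(0, dtype=int), spring_j=np.empty(0, dtype=int),
            spring_k=np.empty(0), spring_L0=np.empty(0),
        )
        with pytest.raises(ValueError):
            fiber_force(BoundaryState(model.points), model, 1.5)


class TestStepFSI:
    def test_membrane_at_rest_stays_at_rest(self, grid_cm):
        params = FluidParams(rho=1.0, nu=0.03125, dt=2e-4)
        model, bs = make_ellipse_membrane(3.0, 3.0, 128, 5e4, center=(8, 8),
                                          grid=grid_cm)
        state = FluidState.zeros(grid_cm)
        for _ in range(100):
            state, bs, _ = step_fsi(state, bs, model, [], params, grid_cm)
        assert np.max(np.abs(state.u)) == 0.0
        assert np.array_equal(bs.X, model.points)

    def test_ellipse_membrane_area_conserved(self, grid_cm):
        """Tension ring immersed in incompressible fluid: enclosed area
        drifts less than 1% over 2000 coupled steps."""
        params = FluidParams(rho=1.0, nu=0.03125, dt=1e-4)
        model, bs = make_ellipse_membrane(3.0, 2.0, 256, 1e4, center=(8, 8),
                                          rest_length_factor=0.0, grid=grid_cm)
        state = FluidState.zeros(grid_cm)
        A0 = chamber_volume(bs.X)
        for _ in range(2000):
            state, bs, info = step_fsi(state, bs, model, [], params, grid_cm)
        A1 = chamber_volume(bs.X)
        assert abs(A1 - A0) / A0 < 0.01
        # and the ellipse is relaxing toward a circle
        rad = np.linalg.norm(bs.X - np.array([8.0, 8.0]), axis=1)
        assert rad.std() / rad.mean() < 0.10

    def test_free_ring_energy_nonincreasing(self, grid_cm):
        params = FluidParams(rho=1.0, nu=0.03125, dt=1e-4)
        model, bs = make_ellipse_membrane(3.0, 2.0, 192, 1e4, center=(8, 8),
                                          rest_length_factor=0.0, grid=grid_cm)
        state = FluidState.zeros(grid_cm)
        prev = None
        for i in range(300):
            state, bs, _ = step_fsi(state, bs, model, [], params, grid_cm)
            e = (
                0.5 * params.rho * float(np.sum(state.u**2)) * grid_cm.cell_volume
                + elastic_energy(bs, model)
            )
            if prev is not None:
                assert e <= prev * (1 + 1e-6)
            prev = e

    def test_laplace_law_pressure_jump(self, grid_cm):
        """Equilibrated circular tension membrane: dp = T/r within 5%."""
        params = FluidParams(rho=1.0, nu=0.03125, dt=1e-4)
        model, bs = make_ellipse_membrane(3.0, 3.0, 256, 1e4, center=(8, 8),
                                          rest_length_factor=0.0, grid=grid_cm)
        state = FluidState.zeros(grid_cm)
        for _ in range(3000):
            state, bs, _ = step_fsi(state, bs, model, [], params, grid_cm)
        seg = np.linalg.norm(np.roll(bs.X, -1, axis=0) - bs.X, axis=1)
        r_now = np.linalg.norm(bs.X - np.array([8.0, 8.0]), axis=1).mean()
        tension = 1e4 * seg.mean()
        X, Y = grid_cm.meshgrid()
        rad = np.hypot(X - 8, Y - 8)
        dp = state.p[rad < r_now - 1.0].mean() - state.p[rad > r_now + 1.0].mean()
        assert dp == pytest.approx(tension / r_now, rel=0.05)

    def test_step_is_deterministic(self, grid_cm):
        params = FluidParams(rho=1.0, nu=0.03125, dt=2e-4)
        results = []
        for _ in range(2):
            model, bs = make_ellipse_membrane(3.0, 2.0, 128, 2e4,
                                              center=(8, 8),
                                              rest_length_factor=0.0)
            state = FluidState.zeros(grid_cm)
            for _ in range(50):
                state, bs, _ = step_fsi(state, bs, model, [], params, grid_cm)
            results.append((state.u.copy(), bs.X.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])


class TestEllipsoid3D:
    def test_3d_shell_smoke(self):
        from ibcms import make_ellipsoid_membrane_3d

        grid = GridSpec.cube(3, 32, 8.0)
        params = FluidParams(rho=1.0, nu=0.03125, dt=5e-4)
        model, bs = make_ellipsoid_membrane_3d()
        state = FluidState.zeros(grid)
        for _ in range(10):
            state, bs, info = step_fsi(state, bs, model, [], params, grid)
        assert np.all(np.isfinite(state.u))
        assert np.all(np.isfinite(bs.X))
        assert info.max_div_err < 1e-10
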