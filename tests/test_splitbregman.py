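import numpy as np
import pytest

import tvtomo as tt
from tvtomo.diffops import gradient_adjoint_array, gradient_array
from tvtomo.splitbregman import SplitBregmanState


def _state(grid, geom, fk_values=None, d=None, b=None, u=None, axes=("x", "y")):
    zeros = {ax: np.zeros(grid.shape) for ax in axes}
    fk = tt.ProjectionStack(
        geom, fk_values if fk_values is not None else np.zeros(
            (geom.det_pixels_u, geom.det_pixels_v, geom.num_proj)
        )
    )
    return SplitBregmanState(
        u=u if u is not None else tt.Volume.zeros(grid),
        d=d or {ax: z.copy() for ax, z in zeros.items()},
        b=b or {ax: z.copy() for ax, z in zeros.items()},
        fk=fk,
    )


class TestShrink:
    def test_zero_field_stays_zero(self):
        out = tt.shrink({"x": np.zeros((4, 4, 1)), "y": np.zeros((4, 4, 1))}, 0.5)
        assert all(np.all(v == 0.0) for v in out.values())

    @pytest.mark.parametrize("s,threshold,expected", [(5.0, 2.0, 3.0), (1.5, 2.0, 0.0), (-4.0, 1.0, -3.0)])
    def test_single_axis_soft_threshold(self, s, threshold, expected):
        out = tt.shrink({"x": np.array([[[s]]])}, threshold)
        assert out["x"][0, 0, 0] == pytest.approx(expected)

    def test_matches_pointwise_brute_force_minimizer(self, rng):
        """shrink(s, 1/lam) minimizes |d| + (lam/2)(d-s)^2 pointwise."""
        for _ in range(100):
            s = float(rng.uniform(-3, 3))
            lam = float(rng.uniform(0.2, 5.0))
            grid = np.arange(-4.0, 4.0, 1e-4)
            objective = np.abs(grid) + 0.5 * lam * (grid - s) ** 2
            brute = grid[np.argmin(objective)]
            ours = tt.shrink({"x": np.array([[[s]]])}, 1.0 / lam)["x"][0, 0, 0]
            assert abs(ours - brute) <= 2e-4

    def test_isotropic_coupling_across_axes(self):
        # a (3, 4) gradient vector of magnitude 5 shrunk by 1 scales to 4/5
        out = tt.shrink({"x": np.array([[[3.0]]]), "y": np.array([[[4.0]]])}, 1.0)
        assert out["x"][0, 0, 0] == pytest.approx(3.0 * 4 / 5)
        assert out["y"][0, 0, 0] == pytest.approx(4.0 * 4 / 5)

    def test_never_increases_magnitude(self, rng):
        sx = rng.normal(size=(6, 6, 1))
        sy = rng.normal(size=(6, 6, 1))
        out = tt.shrink({"x": sx, "y": sy}, 0.3)
        m_in = np.sqrt(sx**2 + sy**2)
        m_out = np.sqrt(out["x"] ** 2 + out["y"] ** 2)
        assert np.all(m_out <= m_in + 1e-12)
        assert np.all(m_out[m_in <= 0.3] == 0.0)


class TestApplyK:
    def test_zero_input_gives_zero(self, small_grid, small_geom):
        out = tt.apply_K(tt.Volume.zeros(small_grid), small_geom, tt.ReconParams())
        assert np.all(out.values == 0.0)

    def test_matches_dense_normal_operator(self, small_grid, small_geom, rng):
        """K u = mu A^T A u + lam grad^T grad u + beta u, term by term."""
        params = tt.ReconParams(mu=3.0, lam=1.5, beta=0.7, matched_adjoint=True)
        A = tt.dense_system_matrix(small_geom, small_grid)
        x = rng.normal(size=small_grid.num_voxels)
        u = tt.Volume(small_grid, x.reshape(small_grid.shape))
        lap = np.zeros_like(u.values)
        for ax in params.tv_axes:
            lap += gradient_adjoint_array(gradient_array(u.values, ax), ax)
        expected = (
            params.mu * (A.T @ (A @ x))
            + params.lam * lap.reshape(-1)
            + params.beta * x
        )
        out = tt.apply_K(u, small_geom, params).values.reshape(-1)
        np.testing.assert_allclose(out, expected, rtol=1e-10, atol=1e-10)

    def test_tv_term_kills_constants(self, small_grid, small_geom):
        # with a constant input the TV block contributes nothing and
        # only mu A^T A u + beta u remains
        params = tt.ReconParams(mu=2.0, lam=5.0, beta=0.0, matched_adjoint=True)
        u = tt.Volume(small_grid, np.ones(small_grid.shape))
        out = tt.apply_K(u, small_geom, params).values
        Au = tt.forward_project(u, small_geom)
        expected = params.mu * tt.back_project(Au, small_grid, method="matched").values
        np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-12)

    def test_symmetric_in_matched_mode(self, small_grid, small_geom, rng):
        params = tt.ReconParams(matched_adjoint=True)
        u = tt.Volume(small_grid, rng.normal(size=small_grid.shape))
        v = tt.Volume(small_grid, rng.normal(size=small_grid.shape))
        Ku = tt.apply_K(u, small_geom, params).values
        Kv = tt.apply_K(v, small_geom, params).values
        lhs = np.vdot(Ku, v.values)
        rhs = np.vdot(u.values, Kv)
        assert abs(lhs - rhs) <= 1e-8 * abs(lhs)


class TestComputeRhs:
    def test_zero_state_gives_zero(self, small_grid, small_geom):
        state = _state(small_grid, small_geom)
        out = tt.compute_rhs(state, small_geom, tt.ReconParams())
        assert np.all(out.values == 0.0)

    def test_d_equals_b_cancels_tv_part(self, small_grid, small_geom, rng):
        field = {ax: rng.normal(size=small_grid.shape) for ax in ("x", "y")}
        state = _state(small_grid, small_geom, d=dict(field), b={k: v.copy() for k, v in field.items()})
        out = tt.compute_rhs(state, small_geom, tt.ReconParams())
        assert np.all(out.values == 0.0)

    def test_tv_part_matches_difference_oracle(self, small_grid, small_geom, rng):
        # with f^k = 0 and d - b = grad v the rhs is lam grad^T grad v
        v = rng.normal(size=small_grid.shape)
        params = tt.ReconParams(lam=2.5)
        d = {ax: gradient_array(v, ax) for ax in params.tv_axes}
        state = _state(small_grid, small_geom, d=d)
        out = tt.compute_rhs(state, small_geom, params)
        expected = np.zeros_like(v)
        for ax in params.tv_axes:
            expected += params.lam * gradient_adjoint_array(gradient_array(v, ax), ax)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_data_part_is_backprojection(self, small_grid, small_geom):
        fk = np.zeros((small_geom.det_pixels_u, small_geom.det_pixels_v, small_geom.num_proj))
        fk[(small_geom.det_pixels_u - 1) // 2, 0, 0] = 1.0
        params = tt.ReconParams(mu=1.0)
        state = _state(small_grid, small_geom, fk_values=fk)
        out = tt.compute_rhs(state, small_geom, params)
        expected = tt.back_project(state.fk, small_grid).values
        np.testing.assert_allclose(out.values, expected, atol=1e-14)


class TestBregmanUpdates:
    def test_data_update_fixed_point_when_consistent(self, small_grid, small_geom, rng):
        u = tt.Volume(small_grid, rng.uniform(size=small_grid.shape))
        f = tt.forward_project(u, small_geom)
        fk = tt.ProjectionStack(small_geom, rng.normal(size=f.values.shape))
        updated = tt.bregman_update_data(fk, f, u, small_geom)
        np.testing.assert_array_equal(updated.values, fk.values)

    def test_data_update_doubles_f_for_zero_volume(self, small_grid, small_geom, rng):
        f = tt.ProjectionStack(small_geom, rng.uniform(size=(13, 1, 10)))
        updated = tt.bregman_update_data(f.copy(), f, tt.Volume.zeros(small_grid), small_geom)
        np.testing.assert_allclose(updated.values, 2 * f.values)

    def test_data_update_matches_explicit_arithmetic(self, small_grid, small_geom, rng):
        u = tt.Volume(small_grid, rng.normal(size=small_grid.shape))
        f = tt.ProjectionStack(small_geom, rng.normal(size=(13, 1, 10)))
        fk = tt.ProjectionStack(small_geom, rng.normal(size=(13, 1, 10)))
        expected = fk.values + f.values - tt.forward_project(u, small_geom).values
        np.testing.assert_allclose(
            tt.bregman_update_data(fk, f, u, small_geom).values, expected, rtol=0, atol=1e-13
        )

    def test_b_update_fixed_point_when_d_equals_gradient(self, small_grid, rng):
        u = tt.Volume(small_grid, rng.normal(size=small_grid.shape))
        b = rng.normal(size=small_grid.shape)
        d = gradient_array(u.values, "x")
        np.testing.assert_array_equal(tt.bregman_update_b(b, u, d, "x"), b)

    def test_b_update_explicit_arithmetic(self, small_grid, rng):
        u = tt.Volume(small_grid, rng.normal(size=small_grid.shape))
        b = rng.normal(size=small_grid.shape)
        d = rng.normal(size=small_grid.shape)
        expected = b + gradient_array(u.values, "y") - d
        np.testing.assert_allclose(
            tt.bregman_update_b(b, u, d, "y"), expected, rtol=0, atol=1e-13
        )


class TestReconstructTV:
    def test_zero_data_gives_zero_volume(self, small_grid, small_geom):
        data = tt.ProjectionStack.zeros(small_geom)
        vol, trace = tt.reconstruct_tv(
            data, small_grid, tt.ReconParams(outer_iterations=3, stop_rel_change=1.0)
        )
        assert np.all(vol.values == 0.0)
        assert len(trace) >= 1

    def test_noise_free_data_residual_below_one_percent(self, small_geom):
        # two-disc phantom at 32x32: after the Bregman loop the data
        # residual ||A u - f|| falls below 1% of ||f||
        grid = tt.VolumeGrid(32, 32, 1, 0.5)
        geom = tt.default_geometry(grid, 24, 360.0)
        truth = tt.make_phantom(
            tt.PhantomSpec(kind="discs", dims=(32, 32, 1), voxel_size=0.5, n_objects=2, seed=5)
        )
        data = tt.simulate_acquisition(truth, geom)
        vol, trace = tt.reconstruct_tv(data, grid, tt.ReconParams(outer_iterations=15))
        assert trace.data_residual[-1] < 0.01 * np.linalg.norm(data.values)

    def test_output_respects_constraints(self, small_geom, small_grid, rng):
        data = tt.ProjectionStack(small_geom, np.abs(rng.normal(size=(13, 1, 10))))
        params = tt.ReconParams(outer_iterations=2, apply_fov_mask=True)
        vol, _ = tt.reconstruct_tv(data, small_grid, params)
        assert np.all(vol.values >= 0.0)
        outside = tt.fov_mask(small_grid).values == 0.0
        assert np.all(vol.values[outside] == 0.0)

    def test_non_finite_data_rejected(self, small_grid, small_geom):
        values = np.zeros((13, 1, 10))
        stack = tt.ProjectionStack(small_geom, values)
        stack.values[0, 0, 0] = np.nan  # bypass constructor validation
        with pytest.raises(ValueError):
            tt.reconstruct_tv(stack, small_grid, tt.ReconParams(outer_iterations=1))

    def test_trace_has_one_record_per_iteration(self, small_geom, small_grid, rng):
        data = tt.ProjectionStack(small_geom, np.abs(rng.normal(size=(13, 1, 10))))
        params = tt.ReconParams(outer_iterations=4, stop_rel_change=1e-9)
        _, trace = tt.reconstruct_tv(data, small_grid, params)
        assert trace.iterations == list(range(1, len(trace) + 1))

    def test_fdk_warm_start_runs(self, phantom64):
        grid = phantom64.grid
        geom = tt.default_geometry(grid, 30, 360.0)
        data = tt.simulate_acquisition(phantom64, geom)
        params = tt.ReconParams(outer_iterations=3, init="fdk", stop_rel_change=1e-6)
        vol, trace = tt.reconstruct_tv(data, grid, params, reference=phantom64)
        assert np.all(vol.values >= 0.0)
        assert trace.rmse[-1] < 0.1


class TestReconParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu=0.0),
            dict(lam=-1.0),
            dict(alpha=0.0),
            dict(beta=-0.1),
            dict(outer_iterations=0),
            dict(stop_rel_change=0.0),
            dict(stop_rel_change=1.5),
            dict(tv_axes=("q",)),
            dict(init="random"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tt.ReconParams(**kwargs)

    def test_shrink_threshold_is_alpha_over_lambda(self):
        params = tt.ReconParams(alpha=0.006, lam=3.0)
        assert params.shrink_threshold == pytest.approx(0.002)
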