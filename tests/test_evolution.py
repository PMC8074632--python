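import numpy as np
import pytest

import coevnet as cn
from coevnet import _kernels
from coevnet.domain import apply_fixed_faces
from coevnet.evolution import DiffusionSolver, cfl_bound, diffusion_step


class TestDiffusionStep:
    def test_linear_ramp_is_invariant(self):
        dom = cn.make_domain((8, 12))
        h = cn.linear_ramp(dom, 1.0)
        out = diffusion_step(h, dom, D=1.0, dt=0.2 * cfl_bound(dom, 1.0))
        assert np.allclose(out, h, atol=1e-15)

    def test_spike_obeys_maximum_principle(self):
        dom = cn.make_domain((9, 9))
        h = cn.linear_ramp(dom, 1.0)
        h[4, 4] += 0.5
        out = diffusion_step(h, dom, D=1.0, dt=cfl_bound(dom, 1.0))
        assert out[4, 4] < h[4, 4]
        assert out.max() <= h.max() + 1e-15 and out.min() >= h.min() - 1e-15

    def test_dirichlet_mode_damped_by_discrete_heat_factor(self):
        """One explicit step multiplies a sine mode by 1 - dt*D*(2-2cos k)/dx^2."""
        dom = cn.make_domain((5, 41))
        n = 41
        m = 3
        k = np.pi * m / (n - 1)
        ramp = cn.linear_ramp(dom, 1.0)
        mode = np.sin(np.arange(n) * k)
        h = ramp + 1e-3 * mode[None, :]
        dt = 0.5 * cfl_bound(dom, 1.0)
        out = diffusion_step(h, dom, D=1.0, dt=dt)
        factor = 1.0 - dt * (2.0 - 2.0 * np.cos(k))
        expected = ramp + 1e-3 * factor * mode[None, :]
        assert np.allclose(out, expected, atol=1e-13)

    def test_explicit_rejects_unstable_dt(self):
        dom = cn.make_domain((6, 6))
        h = cn.linear_ramp(dom, 1.0)
        with pytest.raises(ValueError, match="stability bound"):
            diffusion_step(h, dom, D=1.0, dt=2.0 * cfl_bound(dom, 1.0))

    def test_implicit_matches_explicit_at_small_dt(self):
        dom = cn.make_domain((7, 9))
        rng = np.random.default_rng(2)
        h = cn.linear_ramp(dom, 1.0) + rng.normal(0, 0.05, dom.shape)
        apply_fixed_faces(h, dom, 1.0)
        dt = 1e-3
        ex = diffusion_step(h, dom, D=1.0, dt=dt, mode="explicit")
        im = diffusion_step(h, dom, D=1.0, dt=dt, mode="implicit",
                            solver=DiffusionSolver(dom, 1.0, dt))
        # schemes agree to O(dt^2) per step
        assert np.abs(ex - im).max() < 5e-6


class TestReactionSweep:
    def test_zero_density_is_identity(self):
        dom = cn.make_domain((6, 8))
        rng = np.random.default_rng(4)
        h = cn.linear_ramp(dom, 1.0) + rng.normal(0, 0.1, dom.shape)
        apply_fixed_faces(h, dom, 1.0)
        routing = cn.route(h, dom, "descent")
        out, _ = cn.reaction_sweep(h, routing, np.zeros(dom.shape), 1.0, 1, 1,
                                   0.5, -1, dom)
        assert np.array_equal(out, h)

    def test_three_cell_chain_closed_form(self):
        """Receiver-first implicit update on h=[2,1,0] with unit dt*K.

        Independent oracle: the two coupled implicit equations solved as a
        dense linear system.
        """
        h = np.array([2.0, 1.0, 0.0])
        recv = np.array([1, 2, 2], dtype=np.int64)
        dist = np.ones(3)
        dens = np.array([1.0, 2.0, 3.0])
        order = np.array([0, 1, 2], dtype=np.int64)
        fixed = np.zeros(3, dtype=np.uint8)
        out = h.copy()
        _kernels.sink_sweep_flat(out, recv, dist, dens, order, fixed,
                                 1.0, 1.0, 1e-12, 50)
        # oracle: x0 - 2 + 1*(x0 - x1) = 0 ; x1 - 1 + 2*(x1 - 0) = 0
        A = np.array([[2.0, -1.0], [0.0, 3.0]])
        b = np.array([2.0, 1.0])
        x = np.linalg.solve(A, b)
        assert np.allclose(out, [x[0], x[1], 0.0])
        assert np.allclose(out, [7.0 / 6.0, 1.0 / 3.0, 0.0])

    def test_newton_matches_brentq_for_nonunit_exponent(self):
        from scipy.optimize import brentq

        n_exp = 1.7
        h = np.array([3.0, 1.2, 0.0])
        recv = np.array([1, 2, 2], dtype=np.int64)
        dist = np.array([1.0, np.sqrt(2), 1.0])
        dens = np.array([2.0, 5.0, 9.0])
        order = np.array([0, 1, 2], dtype=np.int64)
        fixed = np.zeros(3, dtype=np.uint8)
        w = 0.8
        out = h.copy()
        _kernels.sink_sweep_flat(out, recv, dist, dens, order, fixed,
                                 w, n_exp, 1e-14, 80)
        # sequential independent root-finds, receiver first
        x1 = brentq(lambda x: x - h[1] + w * dens[1] * ((x - 0.0) / dist[1]) ** n_exp,
                    0.0, h[1], xtol=1e-14)
        x0 = brentq(lambda x: x - h[0] + w * dens[0] * ((x - x1) / dist[0]) ** n_exp,
                    x1, h[0], xtol=1e-14)
        assert np.allclose(out, [x0, x1, 0.0], atol=1e-10)

    @pytest.mark.parametrize("n_exp", [0.5, 1.0, 2.0])
    def test_sink_never_drops_below_receiver(self, n_exp):
        dom = cn.make_domain((8, 10))
        rng = np.random.default_rng(6)
        h = cn.linear_ramp(dom, 1.0) + rng.normal(0, 0.2, dom.shape)
        apply_fixed_faces(h, dom, 1.0)
        routing = cn.route(h, dom, "descent")
        dens = cn.accumulate(routing, dom)
        out, _ = cn.reaction_sweep(h, routing, dens, 0.05, 1, n_exp, 1.0, -1, dom)
        flat = out.ravel()
        nonself = routing.receiver != np.arange(routing.n_cells)
        assert np.all(flat[nonself] >= flat[routing.receiver[nonself]] - 1e-12)
        # erosion only lowers the field
        assert np.all(out <= h + 1e-15)


class TestStep:
    def test_pure_diffusion_reaches_linear_ramp(self):
        dom = cn.make_domain((10, 16))
        params = cn.ModelParams(K=0.0, H=2.0)
        cfg = cn.RunConfig(noise_amplitude=5e-2, seed=9, max_iter=20000,
                           steady_tol=1e-9)
        state = cn.init_state(dom, params, cfg)
        state, trace = cn.run_to_steady(state, dom, params, cfg)
        assert state.converged
        assert np.abs(state.h - cn.linear_ramp(dom, 2.0)).max() < 1e-5
        # dh_max decreases in a time-averaged sense toward convergence
        k = len(trace) // 4
        smoothed = np.convolve(trace, np.ones(k) / k, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_fixed_faces_pinned_every_step(self):
        dom = cn.make_domain((8, 12))
        params = cn.params_from_indices(5.0, 5.0, L=dom.length)
        cfg = cn.RunConfig(noise_amplitude=1e-3, seed=1)
        state = cn.init_state(dom, params, cfg)
        for _ in range(5):
            state, _ = cn.step(state, dom, params, cfg)
            assert np.all(state.h[:, 0] == params.H)
            assert np.all(state.h[:, -1] == 0.0)
            assert state.a_plus.min() >= 0 and state.a_minus.min() >= 0

    def test_split_step_first_order_consistency(self):
        """One step of dt vs two steps of dt/2 differ at O(dt^2)."""
        dom = cn.make_domain((6, 30))
        params = cn.params_from_indices(5.0, 5.0, L=dom.length)
        cfg = cn.RunConfig(noise_amplitude=0.0, seed=0)

        def gap(dt):
            s0 = cn.init_state(dom, params, cfg)
            one, _ = cn.step(s0, dom, params, cfg, dt=dt)
            half, _ = cn.step(s0, dom, params, cfg, dt=dt / 2)
            half, _ = cn.step(half, dom, params, cfg, dt=dt / 2)
            return np.abs(one.h - half.h).max()

        dt0 = cfl_bound(dom, params.D)
        ratio = gap(dt0) / gap(dt0 / 2)
        assert 2.5 < ratio < 6.0

    def test_mirror_symmetry_of_trajectories(self):
        """Swapping (CI+, CI-) with mirrored noise gives h -> H - mirror(h).

        Exact discrete duality: the source sweep is the sink sweep on the
        inverted field, so the dual run must execute the sweeps in the
        opposite order.
        """
        dom = cn.make_domain((9, 15))
        H = 1.0
        ci_a, ci_b = 3.0, 7.0
        p1 = cn.params_from_indices(ci_a, ci_b, L=dom.length)
        p2 = cn.params_from_indices(ci_b, ci_a, L=dom.length)
        cfg1 = cn.RunConfig(noise_amplitude=1e-3, seed=5, sweep_order="sink_first")
        cfg2 = cn.RunConfig(noise_amplitude=1e-3, seed=5, sweep_order="source_first")
        s1 = cn.init_state(dom, p1, cfg1)
        # state 2: the mirrored, inverted field of state 1
        s2 = s1.copy()
        s2.h = np.ascontiguousarray(H - s1.h[:, ::-1])
        s2.a_plus = np.ascontiguousarray(s1.a_minus[:, ::-1])
        s2.a_minus = np.ascontiguousarray(s1.a_plus[:, ::-1])
        dt = 0.5 * cfl_bound(dom, 1.0)
        for _ in range(10):
            s1, _ = cn.step(s1, dom, p1, cfg1, dt=dt)
            s2, _ = cn.step(s2, dom, p2, cfg2, dt=dt)
            assert np.abs(s2.h - (H - s1.h[:, ::-1])).max() < 1e-12
        assert np.abs(s2.a_plus - s1.a_minus[:, ::-1]).max() < 1e-9

    def test_sweep_order_effect_shrinks_with_dt(self):
        dom = cn.make_domain((8, 20))
        params = cn.params_from_indices(4.0, 4.0, L=dom.length)

        def steady_gap(dt):
            outs = []
            for order in ("sink_first", "source_first"):
                cfg = cn.RunConfig(noise_amplitude=0.0, seed=0, dt=dt,
                                   sweep_order=order, max_iter=60000,
                                   steady_tol=1e-10)
                st = cn.init_state(dom, params, cfg)
                st, _ = cn.run_to_steady(st, dom, params, cfg)
                assert st.converged
                outs.append(st.h)
            return np.abs(outs[0] - outs[1]).max()

        dt0 = cfl_bound(dom, params.D)
        g1, g2 = steady_gap(dt0), steady_gap(dt0 / 2)
        assert g2 < 0.75 * g1  # first-order splitting signature

    def test_profile_converges_to_closed_form_under_refinement(self):
        errs = []
        for length in (40, 80):
            dom = cn.make_domain((6, length))
            params = cn.params_from_indices(2.0, 2.0, L=dom.length)
            cfg = cn.RunConfig(noise_amplitude=0.0, seed=0, max_iter=60000,
                               steady_tol=1e-10)
            st = cn.init_state(dom, params, cfg)
            st, _ = cn.run_to_steady(st, dom, params, cfg)
            assert st.converged
            ref, _ = cn.closed_form_profile(dom.y_hat(), 2.0, 2.0)
            errs.append(np.sqrt(np.mean((st.h[0] - ref) ** 2)))
        assert errs[1] < errs[0]
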