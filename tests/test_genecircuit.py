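"""Gene-circuit model: regulation function, RHS structure, integration
against closed forms and a brute-force Euler oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from gapscale.genecircuit import (
    BcdGradient,
    CircuitError,
    CircuitParams,
    ExternalInputs,
    N_NUCLEI_NC13,
    N_NUCLEI_NC14,
    Schedule,
    divide_nuclei,
    g,
    nuclear_grid,
    regulatory_input,
    rhs,
    simulate,
    synthetic_external_inputs,
)

from conftest import make_params


def zero_ext(n):
    """External-input sampler returning zeros (for isolated dynamics)."""
    return lambda t: np.zeros((2, n))


class TestRegulationFunction:
    def test_half_activation_at_zero(self):
        assert g(0.0) == pytest.approx(0.5)

    def test_closed_form_at_one(self):
        assert g(1.0) == pytest.approx(0.5 * (1 / np.sqrt(2) + 1), abs=1e-12)

    @given(st.floats(min_value=-50, max_value=50))
    @settings(max_examples=200, deadline=None)
    def test_odd_symmetry_and_range(self, u):
        assert g(-u) == pytest.approx(1.0 - g(u), abs=1e-12)
        assert 0.0 < g(u) < 1.0

    def test_strictly_increasing(self):
        u = np.linspace(-20, 20, 1000)
        assert (np.diff(g(u)) > 0).all()


class TestRegulatoryInput:
    def test_zero_state_gives_threshold(self):
        p = make_params(2, h=np.array([1.5, -2.0]))
        u = regulatory_input(np.zeros((2, 3)), np.zeros(3), np.zeros((2, 3)), p)
        np.testing.assert_allclose(u, [[1.5] * 3, [-2.0] * 3])

    def test_identity_like_interconnectivity(self):
        p = make_params(2, T=np.eye(2))
        v = np.full((2, 4), 2.0)
        u = regulatory_input(v, np.zeros(4), np.zeros((2, 4)), p)
        np.testing.assert_allclose(u, 2.0)

    def test_matches_triple_loop_oracle(self, rng):
        ng, n = 4, 7
        p = make_params(
            ng,
            T=rng.normal(0, 0.1, (ng, ng)),
            m=rng.normal(0, 0.1, ng),
            E=rng.normal(0, 0.1, (ng, 2)),
            h=rng.normal(0, 1, ng),
        )
        v = rng.uniform(0, 100, (ng, n))
        bcd = rng.uniform(0, 50, n)
        ext = rng.uniform(0, 50, (2, n))
        u = regulatory_input(v, bcd, ext, p)
        expected = np.zeros((ng, n))
        for a in range(ng):
            for i in range(n):
                s = p.h[a] + p.m[a] * bcd[i]
                for b in range(ng):
                    s += p.T[a, b] * v[b, i]
                for e in range(2):
                    s += p.E[a, e] * ext[e, i]
                expected[a, i] = s
        np.testing.assert_allclose(u, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        p = make_params(2)
        with pytest.raises(CircuitError):
            regulatory_input(np.zeros((3, 4)), np.zeros(4), np.zeros((2, 4)), p)


class TestRhs:
    def test_diffusion_conserves_mass(self):
        p = make_params(1, R=[0.0], delta=[0.0], D=[1.0])
        v = np.array([[2.0, 0.0]])
        dv = rhs(0.0, v, p, np.zeros(2), zero_ext(2))
        np.testing.assert_allclose(dv, [[-2.0, 2.0]])
        assert dv.sum() == pytest.approx(0.0)

    def test_relaxation_to_closed_form(self):
        # D=0, constant input: v(t) = v_inf + (v0-v_inf) e^{-delta t}
        R, delta, h = 10.0, 0.5, 0.7
        p = make_params(1, R=[R], delta=[delta], D=[0.0], h=[h])
        v_inf = R * g(h) / delta
        v0 = np.array([[1.0]])
        sol = solve_ivp(
            lambda t, y: rhs(t, y.reshape(1, 1), p, np.zeros(1), zero_ext(1)).ravel(),
            (0, 8), v0.ravel(), rtol=1e-10, atol=1e-12, dense_output=True,
        )
        for t in (1.0, 4.0, 8.0):
            expected = v_inf + (1.0 - v_inf) * np.exp(-delta * t)
            assert sol.sol(t)[0] == pytest.approx(expected, abs=1e-6)

    def test_strong_negative_threshold_silences_synthesis(self):
        p = make_params(1, h=[-1e6], D=[0.0], delta=[0.1])
        dv = rhs(0.0, np.zeros((1, 3)), p, np.zeros(3), zero_ext(3))
        np.testing.assert_allclose(dv, 0.0, atol=1e-3)

    def test_mitotic_gate_removes_synthesis_only(self):
        p = make_params(1, D=[0.0], delta=[0.2], h=[5.0])
        v = np.array([[3.0]])
        gated = rhs(0.0, v, p, np.zeros(1), zero_ext(1), synthesis_gate=0.0)
        np.testing.assert_allclose(gated, -0.2 * v)


class TestSimulate:
    def test_pure_decay(self, default_circuit):
        params, bcd, sched, ext = default_circuit
        p = CircuitParams(
            R=np.zeros(4), D=np.zeros(4), delta=params.delta, T=params.T,
            m=params.m, E=params.E, h=params.h, genes=params.genes,
        )
        init = np.full((4, N_NUCLEI_NC13), 50.0)
        traj = simulate(p, bcd, ext, init=init, output_times=[0.0, 10.0])
        expected = 50.0 * np.exp(-p.delta[:, None] * 10.0)
        np.testing.assert_allclose(
            traj.states[1], np.broadcast_to(expected, (4, N_NUCLEI_NC13)), rtol=1e-5
        )

    def test_division_doubles_and_inherits(self, default_circuit, rng):
        state = rng.uniform(0, 100, (4, N_NUCLEI_NC13))
        doubled = divide_nuclei(state)
        assert doubled.shape == (4, N_NUCLEI_NC14)
        np.testing.assert_array_equal(doubled[:, 0::2], state)
        np.testing.assert_array_equal(doubled[:, 1::2], state)

    def test_division_event_in_full_run(self, default_circuit):
        params, bcd, sched, ext = default_circuit
        traj = simulate(
            params, bcd, ext, schedule=sched,
            output_times=[sched.division_time - 0.5, sched.division_time],
        )
        assert traj.states[0].shape[1] == N_NUCLEI_NC13
        assert traj.states[1].shape[1] == N_NUCLEI_NC14

    def test_matches_forward_euler_oracle(self, rng):
        # 4 nuclei x 2 genes, 1 min, dt = 1e-4: brute-force integrator
        ng, n = 2, 4
        p = make_params(
            ng,
            R=[8.0, 12.0], D=[0.3, 0.6], delta=[0.4, 0.2],
            T=rng.normal(0, 0.05, (ng, ng)),
            m=[0.1, 0.05], E=rng.normal(0, 0.02, (ng, 2)),
            h=[0.2, -0.5],
        )
        bcd_vals = np.array([40.0, 20.0, 10.0, 5.0])
        ext_vals = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 5.0, 10.0]])
        ext_at = lambda t: ext_vals
        v0 = rng.uniform(0, 10, (ng, n))

        dt, t_end = 1e-4, 1.0
        v = v0.copy()
        for _ in range(int(round(t_end / dt))):
            v = v + dt * rhs(0.0, v, p, bcd_vals, ext_at)
        sol = solve_ivp(
            lambda t, y: rhs(t, y.reshape(ng, n), p, bcd_vals, ext_at).ravel(),
            (0, t_end), v0.ravel(), rtol=1e-9, atol=1e-11,
        )
        assert np.max(np.abs(sol.y[:, -1].reshape(ng, n) - v)) < 1e-3

    def test_diffusion_only_mass_conservation(self):
        p = make_params(1, R=[0.0], delta=[0.0], D=[2.0])
        bcd = BcdGradient()
        sched = Schedule(nc13_interphase=5.0, mitosis=1.0, nc14_duration=5.0)
        ext = synthetic_external_inputs(sched)
        init = np.zeros((1, N_NUCLEI_NC13))
        init[0, 10:15] = 100.0
        traj = simulate(
            p, bcd, ext, init=init, schedule=sched,
            output_times=np.linspace(0, sched.t_end, 8),
        )
        masses = []
        for s in traj.states:
            # after division the per-nucleus mass is split across daughters
            masses.append(s.sum() / (s.shape[1] / N_NUCLEI_NC13))
        np.testing.assert_allclose(masses, 500.0, rtol=1e-6)

    def test_non_negativity(self, default_circuit):
        params, bcd, sched, ext = default_circuit
        traj = simulate(params, bcd, ext, schedule=sched,
                        output_times=np.linspace(0, sched.t_end, 20))
        for s in traj.states:
            assert s.min() > -1e-6

    def test_deterministic_rerun(self, default_circuit):
        params, bcd, sched, ext = default_circuit
        t1 = simulate(params, bcd, ext, schedule=sched, output_times=[30.0, 60.0])
        t2 = simulate(params, bcd, ext, schedule=sched, output_times=[30.0, 60.0])
        for a, b in zip(t1.states, t2.states):
            np.testing.assert_array_equal(a, b)

    def test_solver_refinement_converges(self, default_circuit):
        params, bcd, sched, ext = default_circuit
        out = [sched.t_end]
        loose = simulate(params, bcd, ext, schedule=sched, output_times=out,
                         solver_opts={"rtol": 1e-6, "atol": 1e-6})
        tight = simulate(params, bcd, ext, schedule=sched, output_times=out,
                         solver_opts={"rtol": 1e-9, "atol": 1e-9})
        assert np.max(np.abs(loose.states[-1] - tight.states[-1])) < 1e-2

    def test_steady_state_matches_fixed_point(self):
        # D=0, frozen inputs, 1-gene instance with self-activation:
        # v* solves v = R g(T v + h)/delta; damped fixed-point iteration oracle
        R, delta, T_self, h = 10.0, 0.5, 0.02, -0.3
        p = make_params(1, R=[R], delta=[delta], D=[0.0], T=[[T_self]], h=[h])
        v = 5.0
        for _ in range(10_000):
            v = 0.9 * v + 0.1 * (R * g(T_self * v + h) / delta)
        sol = solve_ivp(
            lambda t, y: rhs(t, y.reshape(1, 1), p, np.zeros(1), zero_ext(1)).ravel(),
            (0, 200), [5.0], rtol=1e-10, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(v, abs=1e-5)


class TestExternalInputs:
    def test_tables_interpolate_in_time(self):
        x = np.linspace(0.35, 0.92, 10)
        times = np.array([0.0, 10.0])
        vals = {
            "Cad": np.vstack([np.zeros(10), np.full(10, 20.0)]),
            "Tll": np.zeros((2, 10)),
        }
        ext = ExternalInputs(times, x, vals)
        f = ext.sampler(x)
        np.testing.assert_allclose(f(5.0)[0], 10.0)
        np.testing.assert_allclose(f(-1.0)[0], 0.0)  # clamped
        np.testing.assert_allclose(f(99.0)[0], 20.0)

    def test_synthetic_stand_ins_shapes(self):
        ext = synthetic_external_inputs()
        assert set(ext.values) == {"Cad", "Tll"}
        assert (ext.values["Cad"] >= 0).all() and (ext.values["Tll"] >= 0).all()
        # Cad decays, Tll ramps up
        assert ext.values["Cad"][0].max() > ext.values["Cad"][-1].max()
        assert ext.values["Tll"][0].max() < ext.values["Tll"][-1].max()

    def test_negative_table_rejected(self):
        x = np.linspace(0.35, 0.92, 5)
        with pytest.raises(CircuitError):
            ExternalInputs(
                [0.0, 1.0], x,
                {"Cad": -np.ones((2, 5)), "Tll": np.zeros((2, 5))},
            )
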