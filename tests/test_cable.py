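"""Passive nodal cable: closed forms, dense ODE oracle, drive coupling."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import etrec as E
from etrec.cable import (
    BiphasicWaveform,
    CableParams,
    CableTrajectory,
    DriveSeries,
    FiberGeometry,
    _sealed_laplacian,
    integrate_cable,
    neural_features,
    node_positions,
)


def _params(**kw):
    return CableParams.from_geometry(FiberGeometry(), **kw)


def _drive(ve, dt=1e-6, waveform=None):
    return DriveSeries(ve=ve, dt_s=dt, waveform=waveform or BiphasicWaveform())


class TestWaveform:
    def test_biphasic_phases_and_quiet_tail(self):
        w = BiphasicWaveform(amplitude_ma=2.0, phase_width_us=100.0)
        t = np.array([-1e-6, 50e-6, 150e-6, 250e-6])
        assert np.allclose(w.current_ma(t), [0.0, -2.0, 2.0, 0.0])

    def test_phase_width_outside_device_range_rejected(self):
        with pytest.raises(ValueError):
            BiphasicWaveform(phase_width_us=5.0)
        with pytest.raises(ValueError):
            BiphasicWaveform(phase_width_us=600.0)


class TestNodePositions:
    def test_span_centering_and_depth(self):
        fiber = FiberGeometry(n_nodes=21, internode_mm=0.9)
        layout = E.electrode_centers(E.ElectrodeConfig(3.0, 1.0))
        pts = node_positions(fiber, layout)
        ys = pts[:, 1]
        assert ys.max() - ys.min() == pytest.approx(18.0)
        # middle node at the array centroid's lateral coordinates
        assert pts[10, 0] == 0.0 and pts[10, 1] == 0.0
        assert np.all(pts[:, 2] == fiber.depth_mm)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            FiberGeometry(n_nodes=4)
        with pytest.raises(ValueError):
            FiberGeometry(depth_mm=2.0)  # below the dermis


class TestIntegration:
    def test_zero_drive_zero_trajectory(self):
        p = _params()
        traj = integrate_cable(p, _drive(np.zeros((5, 200))))
        assert np.all(traj.v == 0.0)

    def test_single_node_rc_decay(self):
        # with one node the axial term vanishes: pure RC decay Cm/Gm
        p = CableParams(c_m=1.4e-12, g_a=1e-15, g_m=2.1e-8, v_rest_mv=-70.0)
        v0 = np.array([5e-3])
        dt = 1e-6
        traj = integrate_cable(p, _drive(np.zeros((1, 400)), dt=dt), v0=v0)
        t = np.arange(400) * dt
        expected = v0[0] * np.exp(-t * p.g_m / p.c_m)
        assert np.allclose(traj.v[0], expected, rtol=1e-9, atol=1e-12)

    def test_steady_state_matches_dense_linear_solve(self):
        # constant drive on a 5-node cable: Gm V = Ga L (V + Ve)
        p = _params()
        ve_profile = np.array([0.0, 0.2, 0.5, 0.2, 0.0])
        nt = 4000  # 4 ms >> Cm/Gm ~ 66 us
        ve = np.tile(ve_profile[:, None], (1, nt))
        traj = integrate_cable(p, _drive(ve))
        L = _sealed_laplacian(5)
        v_eq = np.linalg.solve(p.g_m * np.eye(5) - p.g_a * L, p.g_a * L @ ve_profile)
        assert np.allclose(traj.v[:, -1], v_eq, rtol=1e-6, atol=1e-12)

    def test_trajectory_matches_dense_ode_oracle(self):
        # independent high-accuracy integration of the same nodal equations
        p = _params()
        w = BiphasicWaveform(amplitude_ma=2.0, phase_width_us=100.0)
        phi_per_ma = np.array([0.01, 0.05, 0.2, 0.05, 0.01])  # V/mA spatial profile
        dt = 1e-6
        nt = 500
        t = np.arange(nt) * dt
        ve = np.outer(phi_per_ma, w.current_ma(t))
        traj = integrate_cable(p, _drive(ve, dt=dt, waveform=w))

        def rhs_factory(i_ma):
            ve_now = phi_per_ma * i_ma

            def rhs(_, v):
                out = np.empty_like(v)
                for i in range(5):
                    u = lambda j: v[j] + ve_now[j]
                    if i == 0:
                        lap = u(1) - u(0)
                    elif i == 4:
                        lap = u(3) - u(4)
                    else:
                        lap = u(i - 1) - 2 * u(i) + u(i + 1)
                    out[i] = (p.g_a * lap - p.g_m * v[i]) / p.c_m
                return out

            return rhs

        pw = w.phase_width_us * 1e-6
        segments = [(0.0, pw, -2.0), (pw, 2 * pw, 2.0), (2 * pw, t[-1], 0.0)]
        v = np.zeros(5)
        oracle = np.zeros((5, nt))
        for t0, t1, amp in segments:
            t_eval = t[(t > t0) & (t <= t1 + 1e-15)]
            sol = solve_ivp(
                rhs_factory(amp), (t0, t1), v, t_eval=t_eval, rtol=1e-11, atol=1e-16
            )
            idx = np.searchsorted(t, sol.t)
            oracle[:, idx] = sol.y
            v = sol.y[:, -1]
        scale = np.abs(traj.v).max()
        assert np.abs(traj.v - oracle).max() / scale < 1e-6

    def test_linearity_of_peak_depolarisation_in_amplitude(self):
        p = _params()
        phi = np.array([0.0, 0.1, 0.4, 0.1, 0.0])
        dt = 1e-6
        t = np.arange(500) * dt

        def peak(amp):
            w = BiphasicWaveform(amplitude_ma=amp)
            ve = np.outer(phi, w.current_ma(t))
            traj = integrate_cable(p, _drive(ve, dt=dt, waveform=w))
            return traj.v.max()

        assert peak(4.0) == pytest.approx(2.0 * peak(2.0), rel=1e-9)

    def test_halving_dt_changes_peak_less_than_half_percent(self):
        p = _params()
        phi = np.array([0.0, 0.1, 0.4, 0.1, 0.0])

        def peak(dt):
            t = np.arange(0.0, 5e-4, dt)
            w = BiphasicWaveform()
            ve = np.outer(phi, w.current_ma(t))
            return integrate_cable(p, _drive(ve, dt=dt, waveform=w)).v.max()

        assert peak(0.5e-6) == pytest.approx(peak(1e-6), rel=5e-3)

    def test_euler_requires_stability_bound_and_agrees_when_stable(self):
        p = _params()
        phi = np.array([0.0, 0.1, 0.4, 0.1, 0.0])
        with pytest.raises(ValueError):
            integrate_cable(p, _drive(np.zeros((5, 10)), dt=10 * p.stability_dt_s), method="euler")
        dt = 0.2e-6
        t = np.arange(0.0, 3e-4, dt)
        w = BiphasicWaveform()
        ve = np.outer(phi, w.current_ma(t))
        exact = integrate_cable(p, _drive(ve, dt=dt, waveform=w))
        euler = integrate_cable(p, _drive(ve, dt=dt, waveform=w), method="euler")
        scale = np.abs(exact.v).max()
        assert np.abs(exact.v - euler.v).max() / scale < 0.02


class TestNeuralFeatures:
    def test_zero_drive_rests_at_baseline(self):
        p = _params()
        traj = integrate_cable(p, _drive(np.zeros((5, 50))))
        nf = neural_features(traj, p)
        assert nf.v_peak_mv == pytest.approx(p.v_rest_mv)
        assert not nf.activated

    def test_threshold_boundary_counts_as_activated(self):
        p = _params()
        v = np.zeros((3, 10))
        v[1, 4] = 15e-3  # deviation bringing absolute potential exactly to -55
        nf = neural_features(CableTrajectory(v=v, dt_s=1e-6, params=p), p)
        assert nf.v_peak_mv == pytest.approx(-55.0)
        assert nf.activated
        assert nf.t_peak_s == pytest.approx(4e-6)

    def test_peak_of_single_cathodic_phase_occurs_at_or_after_phase_end(self):
        # passive RC response to a rectangular step keeps rising until the
        # step ends, so the peak cannot occur strictly inside the phase
        p = _params()
        w = BiphasicWaveform(amplitude_ma=2.0, phase_width_us=100.0)
        phi = np.array([0.0, 0.1, 0.4, 0.1, 0.0])
        dt = 1e-6
        t = np.arange(0.0, 4e-4, dt)
        i_t = np.where(t < 100e-6, -2.0, 0.0)  # cathodic phase only
        ve = np.outer(phi, i_t)
        traj = integrate_cable(p, _drive(ve, dt=dt, waveform=w))
        nf = neural_features(traj, p)
        assert nf.t_peak_s >= 100e-6 - 1e-9


def test_extracellular_drive_scales_with_waveform():
    subject = E.TRAINING_COHORT[0]
    cfg = E.ElectrodeConfig(3.0, 1.0)
    model = E.build_fingertip_model(subject)
    grid = E.build_grid(model, cfg)
    layout = E.electrode_centers(cfg)
    pot = E.solve_potential(grid, layout=layout, active=(2,), current_ma=2.0)
    fiber = FiberGeometry()
    nodes = node_positions(fiber, layout)
    d1 = E.extracellular_drive(pot, nodes, BiphasicWaveform(amplitude_ma=1.0))
    d2 = E.extracellular_drive(pot, nodes, BiphasicWaveform(amplitude_ma=2.0))
    assert np.allclose(d2.ve, 2.0 * d1.ve)
    d0 = E.extracellular_drive(pot, nodes, BiphasicWaveform(amplitude_ma=0.0))
    assert np.all(d0.ve == 0.0)
    # the activating function at the node nearest the cathode depolarises
    # during the cathodic (first) phase
    ve_phase = d2.ve[:, 10]  # inside first phase
    n_near = int(np.argmax(np.abs(ve_phase)))
    lap = ve_phase[n_near - 1] - 2 * ve_phase[n_near] + ve_phase[n_near + 1]
    assert lap > 0
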