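"""Cell-model unit and property tests against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from ping_assembly import cell_models as cm


def _scipy_reference(params, drive, duration, v0=None, rtol=1e-10):
    """Adaptive high-accuracy integration of one cell (independent oracle)."""
    rest = cm.resting_state(params, 0.0)
    y0 = [float(rest.v[0]) if v0 is None else v0, float(rest.h[0]), float(rest.n[0])]

    def rhs(t, y):
        state = cm.CellState(np.array([y[0]]), np.clip([y[1]], 0, 1), np.clip([y[2]], 0, 1))
        dv, dh, dn = cm.cell_derivatives(state, params, drive)
        return [dv[0], dh[0], dn[0]]

    sol = solve_ivp(rhs, (0.0, duration), y0, rtol=rtol, atol=1e-12,
                    dense_output=True, max_step=0.5)
    return sol


class TestRestingState:
    def test_derivatives_vanish_at_root_found_rest(self):
        """An independently root-found rest state has ~zero derivatives."""
        for params in (cm.E_CELL, cm.I_CELL):
            def f(y):
                state = cm.CellState(np.array([y[0]]), np.array([min(max(y[1], 0), 1)]),
                                     np.array([min(max(y[2], 0), 1)]))
                dv, dh, dn = cm.cell_derivatives(state, params, 0.0)
                return [dv[0], dh[0], dn[0]]

            y = fsolve(f, [-65.0, 0.8, 0.1], full_output=False)
            state = cm.CellState(np.array([y[0]]), np.array([y[1]]), np.array([y[2]]))
            dv, dh, dn = cm.cell_derivatives(state, params, 0.0)
            assert abs(dv[0]) < 1e-8 and abs(dh[0]) < 1e-10 and abs(dn[0]) < 1e-10
            # package's own rest finder agrees
            rest = cm.resting_state(params, 0.0)
            assert rest.v[0] == pytest.approx(y[0], abs=1e-6)

    def test_suprathreshold_drive_has_no_rest(self):
        with pytest.raises(ValueError):
            cm.resting_state(cm.I_CELL, 0.3)


class TestFiring:
    def test_ecell_period_matches_adaptive_reference(self):
        """Fixed-step period agrees with an adaptive-step integrator < 0.1 %."""
        drive = 1.0
        tr = cm.integrate_cell(cm.E_CELL, drive, 300.0, dt=0.01)
        isi_fixed = np.diff(tr.spikes[0][-5:]).mean()
        ref = _scipy_reference(cm.E_CELL, drive, 300.0)
        t_dense = np.arange(0.0, 300.0, 0.005)
        v_dense = ref.sol(t_dense)[0]
        sp_ref = cm.detect_spikes(v_dense, 0.005)
        isi_ref = np.diff(sp_ref[-5:]).mean()
        assert isi_fixed == pytest.approx(isi_ref, rel=1e-3)

    def test_icell_subthreshold_silent(self):
        """Wang-Buzsáki cell with zero drive stays quiescent for 500 ms."""
        rest = cm.resting_state(cm.I_CELL, 0.0)
        tr = cm.integrate_cell(cm.I_CELL, 0.0, 500.0, dt=0.02, state=rest)
        assert tr.spikes[0].size == 0

    def test_icell_fi_curve_monotone(self):
        drives = np.array([0.3, 0.5, 0.8, 1.2, 2.0])
        tr = cm.integrate_cell(cm.I_CELL, drives, 300.0, dt=0.02)
        rates = np.array([sp[sp > 100].size for sp in tr.spikes])
        assert np.all(np.diff(rates) > 0)

    def test_ecell_period_decreases_with_drive(self):
        drives = np.array([0.8, 1.2, 1.6, 2.0])
        tr = cm.integrate_cell(cm.E_CELL, drives, 300.0, dt=0.02)
        periods = [np.diff(sp[-4:]).mean() for sp in tr.spikes]
        assert np.all(np.diff(periods) < 0)


class TestGatingSteadyState:
    @pytest.mark.parametrize("params", [cm.E_CELL, cm.I_CELL], ids=["E", "I"])
    def test_clamped_gating_derivative_zero(self, params):
        v = -50.0
        m, h, n = cm.gating_steady_state(v, params)
        state = cm.CellState(np.array([v]), np.array([h]), np.array([n]))
        _, dh, dn = cm.cell_derivatives(state, params, 0.0)
        assert abs(dh[0]) < 1e-12 and abs(dn[0]) < 1e-12


class TestSynapseGate:
    def test_zero_is_absorbing(self):
        assert cm.synapse_gate_step(0.0, False, cm.EXC_KINETICS, 1.0) == 0.0

    def test_decay_closed_form(self):
        k = cm.EXC_KINETICS
        s = cm.synapse_gate_step(1.0, False, k, k.tau_decay)
        assert s == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_periodic_train_steady_state_matches_closed_form(self):
        """Event-driven gate under a periodic spike train reaches the fixed
        point solvable in closed form, and its cycle mean matches."""
        k = cm.INH_KINETICS
        period, spike_len = 25.0, 1.0
        decay_len = period - spike_len
        a = np.exp(-spike_len / k.tau_rise)
        b = np.exp(-decay_len / k.tau_decay)
        # fixed point of s -> (1 + (s·b − 1)·a) over one cycle
        s_after_spike = (1.0 - a) / (1.0 - a * b)
        s = 0.3
        for _ in range(200):
            s = cm.synapse_gate_step(s, True, k, spike_len)
            s = cm.synapse_gate_step(s, False, k, decay_len)
        assert s == pytest.approx(s_after_spike * b, rel=1e-9)

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            cm.synapse_gate_step(0.5, True, cm.EXC_KINETICS, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(s0=st.floats(0.0, 1.0),
           flags=st.lists(st.booleans(), min_size=1, max_size=50),
           dt=st.floats(0.01, 5.0))
    def test_gate_stays_in_unit_interval(self, s0, flags, dt):
        s = s0
        for flag in flags:
            s = cm.synapse_gate_step(s, flag, cm.EXC_KINETICS, dt)
            assert 0.0 <= s <= 1.0


class TestDetectSpikes:
    def test_constant_trace_empty(self):
        assert cm.detect_spikes(np.full(1000, -65.0), 0.01).size == 0

    def test_single_ramp_interpolated(self):
        dt = 0.1
        v = np.linspace(-60.0, 20.0, 81)  # crosses −20 at sample 40
        sp = cm.detect_spikes(v, dt)
        assert sp.size == 1
        assert sp[0] == pytest.approx(40 * dt, abs=dt)

    def test_tonic_ecell_isi_regular(self):
        tr = cm.integrate_cell(cm.E_CELL, 1.4, 300.0, dt=0.02)
        isi = np.diff(tr.spikes[0][3:])
        assert np.ptp(isi) / isi.mean() < 0.005

    def test_nonfinite_trace_rejected(self):
        with pytest.raises(ValueError):
            cm.detect_spikes(np.array([0.0, np.nan]), 0.01)


class TestNumerics:
    def test_rk4_order_of_convergence(self):
        """Halving dt shrinks the error against an adaptive reference by
        roughly the scheme's order (subthreshold trajectory, no spikes)."""
        drive = 0.05
        ref = _scipy_reference(cm.I_CELL, drive, 20.0, rtol=1e-12)
        v_ref = ref.sol(20.0)[0]
        errs = []
        for dt in (0.08, 0.04):
            rest = cm.resting_state(cm.I_CELL, 0.0)
            tr = cm.integrate_cell(cm.I_CELL, drive, 20.0, dt=dt, state=rest)
            errs.append(abs(tr.v[-1, 0] - v_ref))
        ratio = errs[0] / errs[1]
        assert ratio > 8.0  # 4th order would give ~16; allow slack

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(drive=st.floats(0.0, 2.0))
    def test_gating_bounded_under_random_drive(self, drive):
        tr = cm.integrate_cell(cm.E_CELL, drive, 50.0, dt=0.02)
        for g in (tr.h, tr.n):
            assert np.all((g >= 0.0) & (g <= 1.0))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            cm.NeuronParams(c_m=1.0, g_na=-1.0, g_k=1.0, g_leak=0.1,
                            e_na=50.0, e_k=-100.0, e_leak=-67.0)
        with pytest.raises(ValueError):
            cm.NeuronParams(c_m=1.0, g_na=1.0, g_k=1.0, g_leak=0.1,
                            e_na=-100.0, e_k=50.0, e_leak=-67.0)
        with pytest.raises(ValueError):
            cm.CellState(np.array([-65.0]), np.array([1.5]), np.array([0.1]))
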