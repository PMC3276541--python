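"""Single-cell dynamics for the PING network models.

Two conductance-based point neurons are used throughout:

* **E-cells** — reduced Traub-Miles pyramidal cells: Hodgkin-Huxley-type
  sodium/potassium/leak dynamics with the sodium activation variable ``m``
  slaved to its voltage-dependent steady state.
* **I-cells** — Wang-Buzsáki fast-spiking interneurons, with the standard
  temperature factor φ = 5 applied to the ``h`` and ``n`` kinetics and ``m``
  likewise instantaneous.

A leaky integrate-and-fire cell with an elementary closed-form response is
provided as an analytic oracle (see :mod:`ping_assembly.single_cell`).

Units are fixed package-wide: time in ms, voltage in mV, conductance
densities in mS/cm², current densities in µA/cm², capacitance in µF/cm².

All rate functions are vectorized over arrays of cells, which is what the
network integrator relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

__all__ = [
    "NeuronParams",
    "SynapseKinetics",
    "CellState",
    "E_CELL",
    "I_CELL",
    "EXC_KINETICS",
    "INH_KINETICS",
    "ecell_derivatives",
    "icell_derivatives",
    "cell_derivatives",
    "gating_steady_state",
    "resting_state",
    "synapse_gate_step",
    "gate_open_rate",
    "detect_spikes",
    "integrate_cell",
    "SPIKE_THRESHOLD_MV",
    "REFRACTORY_MS",
]

SPIKE_THRESHOLD_MV = -20.0  # upward crossing defines a spike
REFRACTORY_MS = 1.0  # guard against double-counting one action potential


@dataclass(frozen=True)
class NeuronParams:
    """Intrinsic parameters of a conductance-based point neuron.

    ``cell_class`` is ``"E"`` for the reduced Traub-Miles pyramidal cell and
    ``"I"`` for the Wang-Buzsáki interneuron; it selects the rate functions.
    """

    c_m: float  # µF/cm²
    g_na: float  # mS/cm²
    g_k: float
    g_leak: float
    e_na: float  # mV
    e_k: float
    e_leak: float
    cell_class: str = "E"

    def __post_init__(self) -> None:
        if min(self.g_na, self.g_k, self.g_leak) < 0:
            raise ValueError("conductance densities must be non-negative")
        if not (self.e_na > self.e_leak > self.e_k):
            raise ValueError("require E_Na > E_leak > E_K")
        if self.cell_class not in ("E", "I"):
            raise ValueError("cell_class must be 'E' or 'I'")


#: Reduced Traub-Miles pyramidal cell.
E_CELL = NeuronParams(c_m=1.0, g_na=100.0, g_k=80.0, g_leak=0.1,
                      e_na=50.0, e_k=-100.0, e_leak=-67.0, cell_class="E")

#: Wang-Buzsáki fast-spiking interneuron.
I_CELL = NeuronParams(c_m=1.0, g_na=35.0, g_k=9.0, g_leak=0.1,
                      e_na=55.0, e_k=-90.0, e_leak=-65.0, cell_class="I")


@dataclass(frozen=True)
class SynapseKinetics:
    """First-order synaptic gating kinetics.

    The gating variable obeys ds/dt = ρ(v_pre)·(1−s)/τ_rise − s/τ_decay with
    ρ(v) = (1 + tanh(v/10))/2, so s rises toward 1 during the presynaptic
    action potential and decays exponentially between spikes.
    """

    tau_rise: float  # ms
    tau_decay: float  # ms
    e_rev: float  # mV

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("synaptic time constants must be positive")


#: AMPA-like kinetics of E-cell output synapses.
EXC_KINETICS = SynapseKinetics(tau_rise=0.1, tau_decay=3.0, e_rev=0.0)
#: GABA_A-like kinetics of I-cell output synapses.
INH_KINETICS = SynapseKinetics(tau_rise=0.3, tau_decay=9.0, e_rev=-75.0)


@dataclass
class CellState:
    """Dynamical state of one cell (or an array of identically-typed cells)."""

    v: np.ndarray
    h: np.ndarray
    n: np.ndarray
    last_spike: float | None = None

    def __post_init__(self) -> None:
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        self.n = np.atleast_1d(np.asarray(self.n, dtype=float))
        if np.any((self.h < 0) | (self.h > 1)) or np.any((self.n < 0) | (self.n > 1)):
            raise ValueError("gating variables must lie in [0, 1]")


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    denom = -np.expm1(-x / y)
    safe = np.abs(denom) > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(safe, x / np.where(safe, denom, 1.0), y)
    return out


# --- reduced Traub-Miles rate functions -------------------------------------

def _rtm_rates(v):
    am = 0.32 * _vtrap(v + 54.0, 4.0)
    bm = 0.28 * _vtrap(-(v + 27.0), 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * _vtrap(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return am, bm, ah, bh, an, bn


# --- Wang-Buzsáki rate functions (φ = 5 folded into h, n) --------------------

_WB_PHI = 5.0


def _wb_rates(v):
    am = 0.1 * _vtrap(v + 35.0, 10.0)
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = _WB_PHI * 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = _WB_PHI * 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    an = _WB_PHI * 0.01 * _vtrap(v + 34.0, 10.0)
    bn = _WB_PHI * 0.125 * np.exp(-(v + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


def _rates(v, cell_class: str):
    return _rtm_rates(v) if cell_class == "E" else _wb_rates(v)


def gating_steady_state(v, params: NeuronParams):
    """Voltage-clamped steady-state values (m∞, h∞, n∞)."""
    am, bm, ah, bh, an, bn = _rates(np.asarray(v, dtype=float), params.cell_class)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _deriv_arrays(v, h, n, params: NeuronParams, i_input):
    """Lean array path of the right-hand side (no state validation)."""
    am, bm, ah, bh, an, bn = _rates(v, params.cell_class)
    m = am / (am + bm)
    i_ion = (params.g_na * m ** 3 * h * (params.e_na - v)
             + params.g_k * n ** 4 * (params.e_k - v)
             + params.g_leak * (params.e_leak - v))
    dv = (i_ion + i_input) / params.c_m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dv, dh, dn


def cell_derivatives(state: CellState, params: NeuronParams, i_input):
    """Time derivatives (dv/dt, dh/dt, dn/dt) given total input current density.

    ``i_input`` bundles tonic drive plus any synaptic currents, in µA/cm².
    The sodium activation m is instantaneous: m = m∞(v).
    """
    v, h, n = state.v, state.h, state.n
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(h)) and np.all(np.isfinite(n))):
        raise ValueError("non-finite cell state")
    am, bm, ah, bh, an, bn = _rates(v, params.cell_class)
    m = am / (am + bm)
    i_ion = (params.g_na * m ** 3 * h * (params.e_na - v)
             + params.g_k * n ** 4 * (params.e_k - v)
             + params.g_leak * (params.e_leak - v))
    dv = (i_ion + np.asarray(i_input, dtype=float)) / params.c_m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dv, dh, dn


def ecell_derivatives(state: CellState, params: NeuronParams = E_CELL, i_input=0.0):
    """Reduced Traub-Miles right-hand side."""
    if params.cell_class != "E":
        raise ValueError("ecell_derivatives requires E-class parameters")
    return cell_derivatives(state, params, i_input)


def icell_derivatives(state: CellState, params: NeuronParams = I_CELL, i_input=0.0):
    """Wang-Buzsáki right-hand side."""
    if params.cell_class != "I":
        raise ValueError("icell_derivatives requires I-class parameters")
    return cell_derivatives(state, params, i_input)


def resting_state(params: NeuronParams, drive: float = 0.0) -> CellState:
    """Resting fixed point of an isolated cell under tonic drive.

    Solves dv/dt = 0 with h and n at their steady states. Raises if no stable
    subthreshold rest exists (the cell is driven above rheobase).
    """

    def f(v):
        m, h, n = gating_steady_state(v, params)
        return (params.g_na * m ** 3 * h * (params.e_na - v)
                + params.g_k * n ** 4 * (params.e_k - v)
                + params.g_leak * (params.e_leak - v) + drive)

    v0 = None
    # scan below spike threshold for a bracketed root
    grid = np.linspace(-90.0, -40.0, 201)
    vals = np.array([f(v) for v in grid])
    for k in range(len(grid) - 1):
        if vals[k] == 0.0 or vals[k] * vals[k + 1] < 0:
            v0 = brentq(f, grid[k], grid[k + 1], xtol=1e-12)
            break
    if v0 is None:
        raise ValueError("no subthreshold resting point: drive above rheobase?")
    m, h, n = gating_steady_state(v0, params)
    return CellState(v=np.array([v0]), h=np.array([h]), n=np.array([n]))


def gate_open_rate(v):
    """Presynaptic gate-opening function ρ(v) = (1 + tanh(v/10)) / 2."""
    return 0.5 * (1.0 + np.tanh(np.asarray(v, dtype=float) / 10.0))


def synapse_gate_step(s, spiking, kinetics: SynapseKinetics, dt: float):
    """Event-driven update of a synaptic gating value over one interval dt.

    Between spikes the gate decays exponentially toward 0 with τ_decay; while
    the presynaptic cell is spiking it relaxes toward 1 with τ_rise. Both
    branches use the exact exponential map, so the result stays in [0, 1] for
    any dt > 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("gating value outside [0, 1]")
    spiking = np.asarray(spiking, dtype=bool)
    rise = 1.0 + (s - 1.0) * np.exp(-dt / kinetics.tau_rise)
    decay = s * np.exp(-dt / kinetics.tau_decay)
    out = np.where(spiking, rise, decay)
    return out if out.ndim else float(out)


def detect_spikes(v_trace: np.ndarray, dt: float,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  refractory: float = REFRACTORY_MS,
                  t0: float = 0.0) -> np.ndarray:
    """Spike times from a sampled voltage trace.

    A spike is an upward crossing of ``threshold``; the crossing time is
    linearly interpolated between samples. Crossings within ``refractory`` ms
    of the previous spike are ignored (one spike per action potential).
    """
    v = np.asarray(v_trace, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite values")
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    times = []
    last = -np.inf
    for k in idx:
        frac = (threshold - v[k]) / (v[k + 1] - v[k])
        t = t0 + (k + frac) * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)


@dataclass
class SingleCellTrace:
    """Result of integrating isolated cells: trace arrays sampled at dt."""

    t: np.ndarray
    v: np.ndarray  # shape (n_steps+1, n_cells)
    h: np.ndarray
    n: np.ndarray
    spikes: list = field(default_factory=list)  # list of per-cell spike-time arrays


def integrate_cell(params: NeuronParams, drive, duration: float, dt: float = 0.01,
                   state: CellState | None = None,
                   exc_pulse=None, inh_pulse=None,
                   record: bool = True) -> SingleCellTrace:
    """Fixed-step RK4 integration of one or more *uncoupled* cells.

    ``drive`` may be a scalar or per-cell vector of tonic current densities.
    ``exc_pulse`` / ``inh_pulse`` optionally describe instantaneous-rise,
    exponentially decaying conductance pulses as ``(g_peak, t_arrival, tau)``
    with scalar or per-cell entries; the pulse current is
    g_peak·exp(−(t−t_arrival)/τ)·(E_rev − v) for t ≥ t_arrival, with the
    excitatory/inhibitory reversal potential of the package-wide kinetics.

    Used by the single-cell response analyses and as the reference for
    asynchronous network initialization.
    """
    if state is None:
        # Zero-drive rest: a driven cell then starts away from its (possibly
        # unstable) driven equilibrium and settles onto its limit cycle.
        state = resting_state(params, 0.0)
    drive = np.asarray(drive, dtype=float)
    n_cells = max(state.v.size, drive.size if drive.ndim else 1)
    v = np.broadcast_to(state.v, (n_cells,)).astype(float).copy()
    h = np.broadcast_to(state.h, (n_cells,)).astype(float).copy()
    n_g = np.broadcast_to(state.n, (n_cells,)).astype(float).copy()
    drive = np.broadcast_to(drive, (n_cells,)).astype(float)

    pulses = []
    for pulse, e_rev in ((exc_pulse, EXC_KINETICS.e_rev), (inh_pulse, INH_KINETICS.e_rev)):
        if pulse is not None:
            g0, t_arr, tau = pulse
            pulses.append((np.broadcast_to(np.asarray(g0, float), (n_cells,)),
                           np.broadcast_to(np.asarray(t_arr, float), (n_cells,)),
                           float(tau), e_rev))

    n_steps = int(round(duration / dt))

    def rhs(t, vv, hh, nn):
        i_in = drive
        for g0, t_arr, tau, e_rev in pulses:
            g = np.where(t >= t_arr, g0 * np.exp(-np.maximum(t - t_arr, 0.0) / tau), 0.0)
            i_in = i_in + g * (e_rev - vv)
        return _deriv_arrays(vv, hh, nn, params, i_in)

    v_rec = np.empty((n_steps + 1, n_cells)) if record else None
    h_rec = np.empty((n_steps + 1, n_cells)) if record else None
    n_rec = np.empty((n_steps + 1, n_cells)) if record else None
    if record:
        v_rec[0], h_rec[0], n_rec[0] = v, h, n_g

    for k in range(n_steps):
        t = k * dt
        k1 = rhs(t, v, h, n_g)
        k2 = rhs(t + dt / 2, v + dt / 2 * k1[0], h + dt / 2 * k1[1], n_g + dt / 2 * k1[2])
        k3 = rhs(t + dt / 2, v + dt / 2 * k2[0], h + dt / 2 * k2[1], n_g + dt / 2 * k2[2])
        k4 = rhs(t + dt, v + dt * k3[0], h + dt * k3[1], n_g + dt * k3[2])
        v = v + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        h = np.clip(h + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]), 0.0, 1.0)
        n_g = np.clip(n_g + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]), 0.0, 1.0)
        if record:
            v_rec[k + 1], h_rec[k + 1], n_rec[k + 1] = v, h, n_g

    t_grid = np.arange(n_steps + 1) * dt
    spikes = []
    if record:
        for j in range(n_cells):
            spikes.append(detect_spikes(v_rec[:, j], dt))
    else:
        v_rec = v[None, :]
        h_rec = h[None, :]
        n_rec = n_g[None, :]
        t_grid = np.array([duration])
    return SingleCellTrace(t=t_grid, v=v_rec, h=h_rec, n=n_rec, spikes=spikes)
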