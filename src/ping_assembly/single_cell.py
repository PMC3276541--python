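"""Single-cell pulse-response analyses underlying the network phenomena.

Three analyses connect cellular excitability to the network-level rhythm:

* **I-cell delay δ** — a Wang-Buzsáki interneuron, held subthreshold and at
  rest, receives an instantaneous-rise, exponentially decaying excitatory
  conductance pulse at t = 0. δ is the delay from pulse arrival to the
  elicited spike (or "no spike"). The sensitivity of δ to the pulse
  strength and to the background drive collapses as the pulse strength
  rises above threshold — which is why heterogeneity in inputs to I-cells
  only matters when E-to-I synapses are marginal.

* **E-cell inhibition response t_E(s)** — a reduced Traub-Miles pyramidal
  cell driven above threshold spikes at time 0; an inhibitory pulse arrives
  at time s ∈ (0, T), T the intrinsic period. t_E(s) is the time from the
  pulse to the next spike. A flat t_E(s) means one inhibitory pulse erases
  the cell's phase history and synchronizes a population; for zero pulse
  strength t_E(s) = T − s exactly.

* **Integrate-and-fire oracle** — a leaky integrate-and-fire cell whose
  response delay to a step input has an elementary closed form, used to
  cross-check the sensitivity-collapse property analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ping_assembly._kernels import _pulse_core
from ping_assembly.cell_models import (
    E_CELL,
    EXC_KINETICS,
    I_CELL,
    INH_KINETICS,
    REFRACTORY_MS,
    SPIKE_THRESHOLD_MV,
    resting_state,
)

__all__ = [
    "DelayCurve",
    "ECellResponse",
    "icell_pulse_delay",
    "icell_delay_curve",
    "ecell_inhibition_response",
    "intrinsic_period",
    "lif_pulse_delay_analytic",
    "lif_pulse_delay_numeric",
]


@dataclass
class DelayCurve:
    """I-cell response delays over a grid of pulse strengths.

    ``delta`` holds δ in ms, NaN where the pulse fails to elicit a spike;
    ``threshold`` is the interpolated pulse strength below which no spike
    occurs.
    """

    pulse_g: np.ndarray  # mS/cm²
    drive: float  # µA/cm²
    delta: np.ndarray  # ms; NaN = no spike
    threshold: float | None = None

    def delta_change(self, other: "DelayCurve") -> np.ndarray:
        """Δδ = other.δ − self.δ, defined only where both conditions spike."""
        return other.delta - self.delta


@dataclass
class ECellResponse:
    """E-cell inhibition-response map t_E(s) for one drive and pulse strength."""

    s: np.ndarray  # inhibition arrival offsets, ms
    t_e: np.ndarray  # time from inhibition to next spike, ms
    period: float  # intrinsic period T, ms
    drive: float
    g_inh: float

    @property
    def f(self) -> np.ndarray:
        """f(s) = s + t_E(s): next-spike time after the previous spike."""
        return self.s + self.t_e


def _run_pulses(params, state, drive, gx, tx, taux, gi, ti, taui,
                duration, dt):
    """Vectorized pulse integration; returns per-cell spike-time lists."""
    n = drive.size
    n_steps = int(round(duration / dt))
    cap = n * (int(duration) // 4 + 8)
    sp_cell = np.empty(cap, dtype=np.int64)
    sp_time = np.empty(cap)
    cross = [np.empty(n) for _ in range(4)]
    n_sp = _pulse_core(params.cell_class == "E",
                       state[0].copy(), state[1].copy(), state[2].copy(),
                       np.ascontiguousarray(drive, dtype=float),
                       np.ascontiguousarray(gx, dtype=float),
                       np.ascontiguousarray(tx, dtype=float), float(taux),
                       np.ascontiguousarray(gi, dtype=float),
                       np.ascontiguousarray(ti, dtype=float), float(taui),
                       float(dt), n_steps, SPIKE_THRESHOLD_MV, REFRACTORY_MS,
                       sp_cell, sp_time, *cross)
    out = [[] for _ in range(n)]
    for k in range(n_sp):
        out[sp_cell[k]].append(sp_time[k])
    return [np.asarray(x) for x in out], cross


def icell_pulse_delay(pulse_g, drive: float = 0.0, tau: float | None = None,
                      t_max: float = 100.0, dt: float = 0.01):
    """Delay δ from an excitatory pulse to the I-cell's spike.

    The Wang-Buzsáki cell sits at its stable rest under the (subthreshold)
    tonic ``drive``; at t = 0 an excitatory conductance pulse of peak
    ``pulse_g`` mS/cm² with decay ``tau`` ms (default: the package's E-synapse
    decay, 3 ms) arrives. Returns δ in ms, or NaN if no spike occurs within
    ``t_max``. ``pulse_g`` may be an array (vectorized sweep).

    Raises ``ValueError`` if the background drive is itself suprathreshold,
    which would void the premise of the analysis.
    """
    tau = EXC_KINETICS.tau_decay if tau is None else tau
    rest = resting_state(I_CELL, drive)  # raises if drive suprathreshold
    g = np.atleast_1d(np.asarray(pulse_g, dtype=float))
    n = g.size
    state = (np.full(n, rest.v[0]), np.full(n, rest.h[0]), np.full(n, rest.n[0]))
    spikes, _ = _run_pulses(I_CELL, state, np.full(n, float(drive)),
                            g, np.zeros(n), tau,
                            np.zeros(n), np.zeros(n), INH_KINETICS.tau_decay,
                            t_max, dt)
    delta = np.array([sp[0] if sp.size else np.nan for sp in spikes])
    return delta if np.ndim(pulse_g) else float(delta[0])


def icell_delay_curve(pulse_g: np.ndarray, drive: float = 0.0,
                      **kwargs) -> DelayCurve:
    """δ over a grid of pulse strengths, with the no-spike threshold located."""
    g = np.asarray(pulse_g, dtype=float)
    delta = icell_pulse_delay(g, drive=drive, **kwargs)
    spiking = ~np.isnan(delta)
    threshold = None
    if spiking.any() and not spiking.all():
        threshold = float(g[spiking].min())
    return DelayCurve(pulse_g=g, drive=drive, delta=delta, threshold=threshold)


def intrinsic_period(drive, params=E_CELL, dt: float = 0.01,
                     settle: float = 400.0):
    """Intrinsic firing period T (ms) and the limit-cycle spike state.

    Integrates the isolated cell long enough to settle onto its limit cycle
    and returns (T, spike_state) where spike_state is the (v, h, n) state at
    the last threshold crossing. Raises if the drive is subthreshold.
    """
    drive_arr = np.atleast_1d(np.asarray(drive, dtype=float))
    n = drive_arr.size
    rest = resting_state(params, 0.0)
    state = (np.full(n, rest.v[0]), np.full(n, rest.h[0]), np.full(n, rest.n[0]))
    z = np.zeros(n)
    spikes, cross = _run_pulses(params, state, drive_arr, z, z, 1.0, z, z, 1.0,
                                settle, dt)
    periods = np.empty(n)
    for j, sp in enumerate(spikes):
        if sp.size < 3:
            raise ValueError(f"drive {drive_arr[j]} is subthreshold: no limit cycle")
        periods[j] = float(np.mean(np.diff(sp[-4:])))
    spike_state = (cross[0], cross[1], cross[2])
    if np.ndim(drive):
        return periods, spike_state
    return float(periods[0]), (cross[0][:1], cross[1][:1], cross[2][:1])


def ecell_inhibition_response(drive: float, g_inh: float,
                              s_grid: np.ndarray | None = None,
                              n_s: int = 200, dt: float = 0.01,
                              tau: float | None = None) -> ECellResponse:
    """t_E(s): response of a tonically driven E-cell to one inhibitory pulse.

    The cell is placed on its limit cycle with a spike at time 0; an
    exponentially decaying inhibitory conductance pulse (peak ``g_inh``,
    decay ``tau`` ms, default the package's I-synapse decay of 9 ms) arrives
    at each offset s of the grid (default: ``n_s`` points evenly spaced in
    (0, T)). t_E is the time from the pulse's arrival to the next spike.
    """
    tau = INH_KINETICS.tau_decay if tau is None else tau
    if g_inh < 0:
        raise ValueError("inhibitory pulse conductance must be non-negative")
    T, spike_state = intrinsic_period(drive, E_CELL, dt=dt)  # raises if subthreshold
    if s_grid is None:
        s_grid = np.linspace(0.0, T, n_s + 2)[1:-1]
    s_grid = np.asarray(s_grid, dtype=float)
    n = s_grid.size
    state = (np.full(n, spike_state[0][0]), np.full(n, spike_state[1][0]),
             np.full(n, spike_state[2][0]))
    z = np.zeros(n)
    horizon = float(s_grid.max() + 6.0 * T + 5.0 * tau)
    spikes, _ = _run_pulses(E_CELL, state, np.full(n, float(drive)),
                            z, z, EXC_KINETICS.tau_decay,
                            np.full(n, float(g_inh)), s_grid, tau,
                            horizon, dt)
    t_e = np.empty(n)
    for j, sp in enumerate(spikes):
        after = sp[sp > s_grid[j]]
        t_e[j] = after[0] - s_grid[j] if after.size else np.nan
    return ECellResponse(s=s_grid, t_e=t_e, period=T, drive=float(drive),
                         g_inh=float(g_inh))


# --- leaky integrate-and-fire oracle ----------------------------------------

def lif_pulse_delay_analytic(tau_m: float, v_th: float, amplitude: float,
                             drive: float = 0.0) -> float:
    """Closed-form spike delay of a leaky integrate-and-fire cell.

    The membrane obeys τ_m·dv/dt = −v + τ_m·(I + A) for t ≥ 0, starting from
    the subthreshold equilibrium v(0) = τ_m·I; the pulse is a step of
    amplitude A (instantaneous rise, slow decay limit). The delay to
    threshold v_th is

        δ = τ_m · ln((v∞ − v₀) / (v∞ − v_th)),   v∞ = τ_m·(I + A).

    Returns NaN ("no spike") when v∞ ≤ v_th; δ → ∞ as v∞ ↓ v_th (tangency),
    and |dδ/dA| decreases as the amplitude rises above that boundary.
    """
    if tau_m <= 0:
        raise ValueError("membrane time constant must be positive")
    v0 = tau_m * drive
    if v0 >= v_th:
        raise ValueError("background drive is suprathreshold")
    v_inf = tau_m * (drive + amplitude)
    if v_inf <= v_th:
        return float("nan")
    return float(tau_m * np.log((v_inf - v0) / (v_inf - v_th)))


def lif_pulse_delay_numeric(tau_m: float, v_th: float, amplitude: float,
                            drive: float = 0.0, dt: float = 1e-4,
                            t_max: float = 500.0) -> float:
    """Brute-force RK4 integration of the same LIF problem (test oracle)."""
    v = tau_m * drive
    def f(vv):
        return (-vv + tau_m * (drive + amplitude)) / tau_m
    t = 0.0
    while t < t_max:
        k1 = f(v)
        k2 = f(v + dt / 2 * k1)
        k3 = f(v + dt / 2 * k2)
        k4 = f(v + dt * k3)
        v_new = v + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if v_new >= v_th:
            # linear sub-step interpolation of the crossing
            return t + dt * (v_th - v) / (v_new - v)
        v = v_new
        t += dt
    return float("nan")
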