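"""Phase-locking fixed-point analysis of the reduced 20E + 1I network.

In a phase-locked PING rhythm every cell fires once per period P. Writing
s_i for the delay from E-cell i's spike to the next I-cell spike and
t_E(s, I_i) for the single-cell inhibition-response map at drive I_i, the
locked state satisfies, for every i,

    s_i + t_E(s_i, I_i) = P.                                        (*)

Geometrically: the curves f_i(s) = s + t_E(s, I_i) for all drives must be
intersected by one horizontal line at height P. Each curve is generally cut
twice; the smaller root is the physical one, because in PING the inhibitory
volley follows the excitatory volley closely. The period is closed by the
requirement that the I-cell fires immediately after the least-driven (hence
last-spiking) E-cell: s_least = δ̂, the I-cell's own response delay to the
excitatory volley.

When inhibition is weak the ascending branches of the f_i are too shallow:
the maximum of the lowest curve (most-driven cell) falls below the minimum
of the highest (least-driven), no horizontal line crosses them all, and no
phase-locked solution exists — the rhythm cannot merely degrade, it
disappears. The sweep utilities here certify that the solver's existence
flag flips where direct simulation of the same network loses once-per-cycle
participation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ping_assembly._kernels import _pulse_core
from ping_assembly.cell_models import (
    E_CELL,
    EXC_KINETICS,
    I_CELL,
    INH_KINETICS,
    REFRACTORY_MS,
    SPIKE_THRESHOLD_MV,
)
from ping_assembly.network_builder import DriveSpec, NetworkSpec
from ping_assembly.simulator import SimulationResult, run_simulation
from ping_assembly.single_cell import ECellResponse, icell_pulse_delay, intrinsic_period, _run_pulses

__all__ = [
    "ReducedNetworkSpec",
    "LockingSolution",
    "locking_map",
    "solve_locking",
    "locking_period",
    "solve_locking_selfconsistent",
    "simulate_reduced",
    "participation_table",
    "existence_sweep",
]


@dataclass
class ReducedNetworkSpec:
    """The simplified network: 20 E-cells, 1 I-cell, all-to-all coupling.

    Drives to the E-cells increase linearly with cell index from
    ``drive_lo`` to ``drive_hi``; ``g_ie`` is the inhibitory conductance
    density each E-cell receives from the I-cell (the sweep parameter), and
    ``g_ei_total`` the summed excitatory conductance density onto the
    I-cell.

    The I-cell is hyperpolarized (``drive_i`` < 0) so that it acts as a
    coincidence detector: the sustained dribble of excitation from an
    asynchronous E-population leaves it silent, while a coherent spike
    volley makes it fire within ~2 ms. Without this the single I-cell fires
    tonically under asynchronous input and no clean once-per-cycle rhythm
    can be probed.
    """

    n_e: int = 20
    drive_lo: float = 1.4
    drive_hi: float = 1.8
    g_ie: float = 0.2
    g_ei_total: float = 0.25
    drive_i: float = -1.5

    def __post_init__(self) -> None:
        if self.drive_lo >= self.drive_hi:
            raise ValueError("drives must increase with index")

    @property
    def drives(self) -> np.ndarray:
        return np.linspace(self.drive_lo, self.drive_hi, self.n_e)

    def to_network(self) -> tuple[NetworkSpec, DriveSpec]:
        g_ei = np.full((self.n_e, 1), self.g_ei_total / self.n_e)
        g_ie = np.full((1, self.n_e), self.g_ie)
        g_ii = np.zeros((1, 1))
        net = NetworkSpec(n_e=self.n_e, n_i=1, g_ei=g_ei, g_ie=g_ie, g_ii=g_ii)
        dr = DriveSpec(drive_e=self.drives, drive_i=np.array([self.drive_i]))
        return net, dr


@dataclass
class LockingSolution:
    """Solution of the fixed-point system (*) or a certified non-existence."""

    period: float
    s: np.ndarray  # per-cell delays s_i (NaN where no root)
    exists: bool
    drives: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def locking_map(drives: np.ndarray, g_inh: float,
                n_s: int = 200, dt: float = 0.01,
                tau: float | None = None) -> list[ECellResponse]:
    """The family of curves f_i(s) = s + t_E(s, I_i), one per drive.

    All (drive, s) combinations are integrated in a single vectorized batch.
    Curves are returned in the order of ``drives`` (ascending drive ⇒ lower
    curve).
    """
    tau = INH_KINETICS.tau_decay if tau is None else tau
    drives = np.asarray(drives, dtype=float)
    periods, spike_state = intrinsic_period(drives, E_CELL, dt=dt)
    n_d = drives.size
    # per-drive s grids, concatenated into one batch
    s_all = []
    for T in periods:
        s_all.append(np.linspace(0.0, T, n_s + 2)[1:-1])
    s_flat = np.concatenate(s_all)
    drive_flat = np.repeat(drives, n_s)
    v0 = np.repeat(spike_state[0], n_s)
    h0 = np.repeat(spike_state[1], n_s)
    n0 = np.repeat(spike_state[2], n_s)
    z = np.zeros(s_flat.size)
    horizon = float(s_flat.max() + 6.0 * periods.max() + 5.0 * tau)
    spikes, _ = _run_pulses(E_CELL, (v0, h0, n0), drive_flat,
                            z, z, EXC_KINETICS.tau_decay,
                            np.full(s_flat.size, float(g_inh)), s_flat, tau,
                            horizon, dt)
    curves = []
    for i in range(n_d):
        sl = slice(i * n_s, (i + 1) * n_s)
        s_grid = s_flat[sl]
        t_e = np.empty(n_s)
        for j, sp in enumerate(spikes[sl]):
            after = sp[sp > s_grid[j]]
            t_e[j] = after[0] - s_grid[j] if after.size else np.nan
        curves.append(ECellResponse(s=s_grid, t_e=t_e, period=float(periods[i]),
                                    drive=float(drives[i]), g_inh=float(g_inh)))
    return curves


def _smaller_root(curve: ECellResponse, P: float) -> float:
    """Leftmost solution of f(s) = P on the curve's grid, NaN if none."""
    f = curve.f
    s = curve.s
    good = ~np.isnan(f)
    f, s = f[good], s[good]
    if f.size < 2:
        return np.nan
    d = f - P
    if d[0] == 0.0:
        return float(s[0])
    sign_change = np.nonzero(d[:-1] * d[1:] <= 0)[0]
    if sign_change.size == 0:
        return np.nan
    k = sign_change[0]
    if d[k + 1] == d[k]:
        return float(s[k])
    frac = -d[k] / (d[k + 1] - d[k])
    return float(s[k] + frac * (s[k + 1] - s[k]))


def solve_locking(curves: list[ECellResponse], P: float) -> LockingSolution:
    """Solve f_i(s_i) = P for every cell, taking the smaller root.

    The existence flag is True only when every curve is crossed; a curve
    whose admissible branch never reaches P (inhibition too weak for the
    most-driven cells, or P out of range) yields NaN and certifies that no
    phase-locked once-per-cycle rhythm exists at this period.
    """
    drives = np.array([c.drive for c in curves])
    s = np.array([_smaller_root(c, P) for c in curves])
    exists = bool(np.all(~np.isnan(s)))
    return LockingSolution(period=float(P), s=s, exists=exists, drives=drives,
                           diagnostics={
                               "f_max": [float(np.nanmax(c.f)) for c in curves],
                               "f_min": [float(np.nanmin(c.f)) for c in curves],
                           })


def icell_volley_delay(spike_times: np.ndarray, g_each: float, drive: float,
                       dt: float = 0.01, t_max: float = 40.0) -> float:
    """Spike time of the I-cell receiving a staggered excitatory volley.

    The Wang-Buzsáki cell sits at rest under its (subthreshold) drive; each
    presynaptic spike at t_k contributes a conductance g_each·exp(−(t−t_k)/τ_E)
    for t ≥ t_k. Returns the absolute threshold-crossing time (same time base
    as ``spike_times``), or NaN if the volley fails.
    """
    from ping_assembly.cell_models import _deriv_arrays, resting_state as _rest

    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    rest = _rest(I_CELL, drive)
    v = rest.v.copy()
    h = rest.h.copy()
    n = rest.n.copy()
    tau = EXC_KINETICS.tau_decay
    t0 = float(spike_times[0])

    def g_at(t):
        act = spike_times[spike_times <= t]
        return g_each * float(np.exp(-(t - act) / tau).sum()) if act.size else 0.0

    def rhs(t, vv, hh, nn):
        i_in = drive + g_at(t) * (0.0 - vv)
        return _deriv_arrays(vv, hh, nn, I_CELL, i_in)

    n_steps = int(round(t_max / dt))
    for k in range(n_steps):
        t = t0 + k * dt
        vp = float(v[0])
        k1 = rhs(t, v, h, n)
        k2 = rhs(t + dt / 2, v + dt / 2 * k1[0], h + dt / 2 * k1[1], n + dt / 2 * k1[2])
        k3 = rhs(t + dt / 2, v + dt / 2 * k2[0], h + dt / 2 * k2[1], n + dt / 2 * k2[2])
        k4 = rhs(t + dt, v + dt * k3[0], h + dt * k3[1], n + dt * k3[2])
        v = v + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        h = np.clip(h + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]), 0, 1)
        n = np.clip(n + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]), 0, 1)
        if vp < SPIKE_THRESHOLD_MV <= float(v[0]):
            frac = (SPIKE_THRESHOLD_MV - vp) / (float(v[0]) - vp)
            return t + frac * dt
    return float("nan")


def locking_period(curves: list[ECellResponse], spec: ReducedNetworkSpec,
                   dt: float = 0.01) -> float:
    """Initial period estimate: P = f_least(δ̂) with δ̂ the I-cell's delay in
    response to the whole excitatory conductance arriving as one pulse."""
    least = curves[int(np.argmin([c.drive for c in curves]))]
    delta = icell_pulse_delay(spec.g_ei_total, drive=spec.drive_i, dt=dt)
    if np.isnan(delta):
        raise ValueError("excitatory volley fails to make the I-cell spike")
    return float(np.interp(delta, least.s, least.f))


def solve_locking_selfconsistent(spec: ReducedNetworkSpec,
                                 n_s: int = 200, dt: float = 0.01,
                                 tol: float = 0.01,
                                 max_iter: int = 25) -> LockingSolution:
    """Build the curve family for the reduced network and solve (*) with the
    period closed self-consistently.

    Iteration: given P, solve for the delays s_i; the E-spikes then fall at
    times −s_i relative to the putative I-spike; integrating the I-cell
    against that staggered volley yields its actual spike time, hence a new
    delay for the least-driven (last-spiking) cell and a new P = f_least(s).
    Stops when P changes by less than ``tol`` ms. The point-pulse estimate
    seeds the iteration and is kept when no locked solution exists.
    """
    curves = locking_map(spec.drives, spec.g_ie, n_s=n_s, dt=dt)
    least = int(np.argmin([c.drive for c in curves]))
    g_each = spec.g_ei_total / spec.n_e
    P = locking_period(curves, spec, dt=dt)
    sol = solve_locking(curves, P)
    for _ in range(max_iter):
        if not sol.exists:
            break
        t_spikes = -sol.s  # E-spike times relative to the putative I-spike
        t_i = icell_volley_delay(t_spikes, g_each, spec.drive_i, dt=dt)
        if np.isnan(t_i):
            break
        s_least = t_i - t_spikes[least]
        s_min = float(curves[least].s[0])
        s_least = max(s_least, s_min)
        P_new = float(np.interp(s_least, curves[least].s, curves[least].f))
        converged = abs(P_new - P) < tol
        P = P_new
        sol = solve_locking(curves, P)
        if converged:
            break
    sol.diagnostics["g_ie"] = spec.g_ie
    return sol


def simulate_reduced(spec: ReducedNetworkSpec, duration: float = 400.0,
                     dt: float = 0.02, seed: int | None = 0,
                     init: str = "rest") -> SimulationResult:
    """Direct simulation of the reduced network.

    The default start is from rest (a near-coherent first volley): the
    once-per-cycle locked state coexists with multi-cluster attractors in
    which the I-cell answers each sub-volley separately, and a fully
    asynchronous start can be captured by those instead.
    """
    net, dr = spec.to_network()
    return run_simulation(net, dr, duration=duration, dt=dt, seed=seed, init=init)


def participation_table(result: SimulationResult,
                        transient: float = 100.0) -> np.ndarray:
    """Spikes per E-cell per cycle; cycles delimited by I-cell spikes.

    Returns an (n_cycles, n_e) integer array. A once-per-cycle locked rhythm
    has every entry equal to 1.
    """
    sp_i = result.population_spikes("I")
    t_i = sp_i[sp_i[:, 1] >= transient][:, 1]
    sp_e = result.population_spikes("E")
    if t_i.size < 2:
        return np.zeros((0, result.n_e), dtype=int)
    table = np.zeros((t_i.size - 1, result.n_e), dtype=int)
    for k in range(t_i.size - 1):
        in_cycle = sp_e[(sp_e[:, 1] >= t_i[k]) & (sp_e[:, 1] < t_i[k + 1])]
        for cell in in_cycle[:, 0].astype(int):
            table[k, cell] += 1
    return table


def once_per_cycle_fraction(result: SimulationResult,
                            transient: float = 100.0) -> float:
    """Fraction of cycles in which every E-cell fired exactly once."""
    table = participation_table(result, transient=transient)
    if table.shape[0] == 0:
        return 0.0
    return float(np.mean(np.all(table == 1, axis=1)))


def existence_sweep(g_ie_values: np.ndarray,
                    spec: ReducedNetworkSpec | None = None,
                    duration: float = 400.0, n_s: int = 200,
                    dt_solver: float = 0.01, dt_sim: float = 0.02,
                    seed: int = 0,
                    participation_threshold: float = 0.9) -> dict:
    """Sweep the inhibitory strength; compare solver existence with simulated
    once-per-cycle participation.

    Returns a dict of aligned arrays: g_ie, exists (solver), period,
    participation fraction, locked (simulation).
    """
    base = spec or ReducedNetworkSpec()
    g_vals = np.asarray(g_ie_values, dtype=float)
    exists = np.zeros(g_vals.size, dtype=bool)
    locked = np.zeros(g_vals.size, dtype=bool)
    period = np.full(g_vals.size, np.nan)
    particip = np.empty(g_vals.size)
    for k, g in enumerate(g_vals):
        sp = ReducedNetworkSpec(n_e=base.n_e, drive_lo=base.drive_lo,
                                drive_hi=base.drive_hi, g_ie=float(g),
                                g_ei_total=base.g_ei_total, drive_i=base.drive_i)
        sol = solve_locking_selfconsistent(sp, n_s=n_s, dt=dt_solver)
        exists[k] = sol.exists
        period[k] = sol.period
        res = simulate_reduced(sp, duration=duration, dt=dt_sim, seed=seed)
        particip[k] = once_per_cycle_fraction(res, transient=duration / 2)
        locked[k] = particip[k] >= participation_threshold
    return {"g_ie": g_vals, "exists": exists, "period": period,
            "participation": particip, "locked": locked}
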