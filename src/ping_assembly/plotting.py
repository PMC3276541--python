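"""Publication-style figures: rastergrams, gating traces, locking curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from ping_assembly.metrics import rhythmicity_gamma
from ping_assembly.simulator import SimulationResult

__all__ = ["plot_raster", "plot_sbar_spectrum", "plot_locking_curves"]


def plot_raster(result: SimulationResult, path, order: np.ndarray | None = None,
                title: str | None = None) -> None:
    """Spike rastergram: I-cells (blue) below, E-cells (red) above.

    ``order`` optionally permutes E-cell indices (e.g. by distance from the
    center in spatial runs).
    """
    sp_e = result.population_spikes("E")
    sp_i = result.population_spikes("I")
    fig, ax = plt.subplots(figsize=(7, 4))
    if sp_i.size:
        ax.plot(sp_i[:, 1], sp_i[:, 0] + 1, ".", ms=2, color="tab:blue")
    if sp_e.size:
        idx = sp_e[:, 0].astype(int)
        if order is not None:
            rank = np.empty_like(order)
            rank[order] = np.arange(order.size)
            idx = rank[idx]
        ax.plot(sp_e[:, 1], idx + result.n_i + 1, ".", ms=2, color="tab:red")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    ax.set_xlim(0, result.duration)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)


def plot_sbar_spectrum(result: SimulationResult, path,
                       band=(25.0, 100.0), transient: float = 100.0) -> None:
    """Mean E-gating trace s̄(t) and its periodogram with the band shaded."""
    g = rhythmicity_gamma(result.s_bar, result.dt, band=band, transient=transient)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    ax1.plot(result.t, result.s_bar, lw=0.8)
    ax1.set_xlabel("time (ms)")
    ax1.set_ylabel("s̄")
    if g.freqs.size:
        sel = g.freqs <= 200.0
        ax2.plot(g.freqs[sel], g.power[sel], lw=0.8)
        ax2.axvspan(*band, alpha=0.15, color="tab:green")
    ax2.set_xlabel("frequency (Hz)")
    ax2.set_ylabel("power")
    ax2.set_title(f"γ = {g.gamma:.2f}")
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)


def plot_locking_curves(curves, path, P: float | None = None) -> None:
    """The family f_i(s) = s + t_E(s, I_i) with the period line P."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        ax.plot(c.s, c.f, lw=0.8, color="tab:blue", alpha=0.6)
    if P is not None:
        ax.axhline(P, color="tab:red", lw=1.2)
    ax.set_xlabel("s (ms)")
    ax.set_ylabel("s + t_E(s, I)")
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)
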