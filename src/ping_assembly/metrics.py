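"""Rhythmicity, synchrony, frequency, volley and entrainment measures.

The central quantity is the gamma rhythmicity γ: the fraction of the
spectral energy of the population-mean E-synaptic gating trace s̄(t) that
falls in the gamma band, computed from a Hann-windowed periodogram of the
post-transient trace. The denominator is the energy of the whole signal,
*including* its mean (DC) component: an asynchronous population whose s̄
hovers around a constant with small finite-size fluctuations then scores
γ ≈ 0 even though those fluctuations concentrate near the single-cell
firing rate, while a strongly modulated rhythmic s̄ scores high. γ is
dimensionless, lies in [0, 1], and is invariant under amplitude scaling.

Spike volleys are contiguous above-threshold regions of the smoothed
population spike histogram; they support the entrainment-ratio measure
(number of E-volleys per I-volley) and the synchrony measure σ (mean
resultant length of spike phases relative to the detected population cycle).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import periodogram

__all__ = [
    "GAMMA_BAND",
    "KAINATE_BAND",
    "RhythmicityResult",
    "VolleySet",
    "rhythmicity_gamma",
    "mean_population_frequency",
    "detect_volleys",
    "entrainment_ratio",
    "synchrony_measure",
    "synchronization_time",
]

#: Default gamma band (Hz).
GAMMA_BAND = (25.0, 100.0)
#: Low-gamma band of the kainate-background analyses (Hz).
KAINATE_BAND = (25.0, 50.0)


@dataclass
class RhythmicityResult:
    """Gamma-band energy fraction of s̄ with its spectrum."""

    gamma: float
    band: tuple[float, float]
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class VolleySet:
    """Population spike volleys: center-of-mass times, widths, spike counts."""

    times: np.ndarray  # ms, sorted
    widths: np.ndarray  # ms
    counts: np.ndarray  # spikes per volley

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("volley times must be sorted")
        if np.any(self.widths < 0):
            raise ValueError("volley widths must be non-negative")


def rhythmicity_gamma(s_bar: np.ndarray, dt: float,
                      band: tuple[float, float] = GAMMA_BAND,
                      transient: float = 100.0) -> RhythmicityResult:
    """Gamma-band energy fraction of the mean E-gating trace.

    ``s_bar`` is sampled at ``dt`` ms; the first ``transient`` ms are
    discarded. Returns γ = (energy in ``band``) / (total energy including
    the DC component). An all-constant trace has γ = 0.
    """
    s = np.asarray(s_bar, dtype=float)
    k0 = int(round(transient / dt))
    s = s[k0:]
    fs = 1000.0 / dt  # Hz
    if s.size < 8 or np.allclose(s, s[0]):
        return RhythmicityResult(0.0, band, np.empty(0), np.empty(0))
    freqs, power = periodogram(s, fs=fs, window="hann", detrend=False)
    total = power.sum()
    if total <= 0:
        return RhythmicityResult(0.0, band, freqs, power)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    gamma = float(power[in_band].sum() / total)
    return RhythmicityResult(min(gamma, 1.0), band, freqs, power)


def mean_population_frequency(spikes: np.ndarray, n_cells: int,
                              window: tuple[float, float]) -> float:
    """Mean firing rate (Hz) of a population over a time window.

    ``spikes`` is an (n, 2) array of (cell_id, t_ms) for the population;
    rate = total spikes / (n_cells × window length).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty or inverted window")
    if n_cells <= 0:
        raise ValueError("population size must be positive")
    spikes = np.asarray(spikes, dtype=float).reshape(-1, 2)
    t = spikes[:, 1]
    count = int(np.sum((t >= t0) & (t < t1)))
    return 1000.0 * count / (n_cells * (t1 - t0))


def detect_volleys(spikes: np.ndarray, t_max: float,
                   bin_ms: float = 1.0, smooth_ms: float = 1.0,
                   threshold: float | None = None,
                   threshold_factor: float = 3.0) -> VolleySet:
    """Volleys from the smoothed population spike histogram.

    The zero-padded histogram (``bin_ms`` bins, Gaussian smoothing
    σ = ``smooth_ms``) is compared against a threshold; by default ``threshold_factor`` times the
    mean rate, i.e. the level a rate-matched Poisson surrogate rarely
    exceeds. A volley is one contiguous above-threshold region, reported by
    the center of mass of its spikes and its above-threshold extent.
    """
    spikes = np.asarray(spikes, dtype=float).reshape(-1, 2)
    t = spikes[:, 1]
    if t.size == 0:
        return VolleySet(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    edges = np.arange(0.0, t_max + bin_ms, bin_ms)
    hist, _ = np.histogram(t, bins=edges)
    rate = gaussian_filter1d(hist.astype(float), smooth_ms / bin_ms, mode="constant")
    thr = threshold if threshold is not None else threshold_factor * rate.mean()
    above = rate > thr
    times, widths, counts = [], [], []
    k = 0
    while k < above.size:
        if above[k]:
            j = k
            while j < above.size and above[j]:
                j += 1
            lo, hi = edges[k], edges[j]
            in_v = (t >= lo) & (t < hi)
            if in_v.any():
                times.append(float(t[in_v].mean()))
                widths.append(hi - lo)
                counts.append(int(in_v.sum()))
            k = j
        else:
            k += 1
    order = np.argsort(times)
    return VolleySet(np.asarray(times)[order], np.asarray(widths)[order],
                     np.asarray(counts, dtype=int)[order])


def entrainment_ratio(e_volleys: VolleySet, i_volleys: VolleySet) -> int:
    """Modal number of E-population volleys per I-population volley.

    Each E-volley is attributed to the first I-volley at or after it; the
    ratio is the modal count over I-volleys that receive at least one
    E-volley. 1 means intact PING (one E-volley triggers each I-volley);
    2 means 2:1 entrainment (two E-volleys are needed per I-volley).

    Raises ``ValueError`` when there are fewer than 3 I-volleys, so absence
    of an I-rhythm is signalled distinctly from a ratio of 1.
    """
    ti = i_volleys.times
    te = e_volleys.times
    if ti.size < 3:
        raise ValueError("need at least 3 I-volleys to define an entrainment ratio")
    # count E-volleys mapped to each I-volley (first I-volley at/after the E-volley)
    idx = np.searchsorted(ti, te, side="left")
    idx = idx[idx < ti.size]  # E-volleys after the last I-volley are unattributed
    counts = Counter(idx.tolist())
    if not counts:
        raise ValueError("no E-volleys precede any I-volley")
    modal = Counter(counts.values()).most_common(1)[0][0]
    return int(modal)


def synchrony_measure(spikes: np.ndarray, t_max: float,
                      volleys: VolleySet | None = None,
                      **volley_kwargs) -> float:
    """Synchrony σ ∈ [0, 1]: mean resultant length of spike phases.

    The population cycle is defined by the detected volley times (or an
    externally supplied ``VolleySet``); each spike between consecutive cycle
    markers t_k, t_{k+1} gets phase 2π(t−t_k)/(t_{k+1}−t_k), and σ is the
    circular mean resultant length |⟨e^{iφ}⟩|. Perfectly synchronous spiking
    gives 1; phases uniform on the cycle give ≈ 0 (within 1/√N).
    """
    spikes = np.asarray(spikes, dtype=float).reshape(-1, 2)
    t = spikes[:, 1]
    if t.size < 2:
        raise ValueError("need at least 2 spikes")
    if volleys is None:
        volleys = detect_volleys(spikes, t_max, **volley_kwargs)
    marks = volleys.times
    if marks.size < 2:
        raise ValueError("degenerate input: fewer than two population cycles detected")
    phases = []
    for k in range(marks.size - 1):
        lo, hi = marks[k], marks[k + 1]
        sel = t[(t >= lo) & (t < hi)]
        phases.append(2.0 * np.pi * (sel - lo) / (hi - lo))
    phases = np.concatenate(phases) if phases else np.empty(0)
    if phases.size == 0:
        raise ValueError("no spikes within the detected cycles")
    return float(np.abs(np.exp(1j * phases).mean()))


def synchronization_time(e_volleys: VolleySet, tight_width_ms: float = 5.0) -> float | None:
    """Time at which the E-population first becomes tightly synchronous.

    Returns the time of the first E-volley from which on all subsequent
    volleys have width ≤ ``tight_width_ms``; ``None`` if that never happens.
    Used to compare how quickly homogeneous networks lock.
    """
    w = e_volleys.widths
    if w.size == 0:
        return None
    tight = w <= tight_width_ms
    # last index where the volley is NOT tight
    not_tight = np.nonzero(~tight)[0]
    k0 = 0 if not_tight.size == 0 else not_tight[-1] + 1
    if k0 >= w.size:
        return None
    return float(e_volleys.times[k0])
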