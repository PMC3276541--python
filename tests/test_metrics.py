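"""Metric tests on constructed rasters and traces with known answers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ping_assembly import metrics as met


def _periodic_raster(n_cells, period, t_max, jitter=0.0, rng=None):
    """(cell, t) raster: all cells fire each cycle with Gaussian jitter."""
    rng = rng or np.random.default_rng(0)
    times = np.arange(period, t_max - 1.0, period)
    rows = []
    for t in times:
        for c in range(n_cells):
            rows.append((c, t + (rng.normal(0.0, jitter) if jitter else 0.0)))
    out = np.array(rows)
    return out[np.argsort(out[:, 1])]


class TestRhythmicityGamma:
    def test_pure_sinusoid_in_band(self):
        dt = 0.05
        t = np.arange(0, 500.0, dt)
        s = np.sin(2 * np.pi * 40.0 * t / 1000.0)
        g = met.rhythmicity_gamma(s, dt, band=(25.0, 100.0), transient=0.0)
        assert g.gamma >= 0.99

    def test_constant_trace_zero(self):
        g = met.rhythmicity_gamma(np.full(5000, 0.3), 0.05)
        assert g.gamma == 0.0

    def test_white_noise_band_fraction(self):
        dt = 0.5  # 1 kHz Nyquist
        rng = np.random.default_rng(1)
        gs = [met.rhythmicity_gamma(rng.normal(size=20000), dt,
                                    band=(25.0, 100.0), transient=0.0).gamma
              for _ in range(5)]
        expected = 75.0 / 1000.0
        assert np.mean(gs) == pytest.approx(expected, rel=0.15)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 100.0])
    def test_amplitude_scaling_invariance(self, scale):
        dt = 0.05
        t = np.arange(0, 400.0, dt)
        s = 0.1 + 0.05 * np.sin(2 * np.pi * 40.0 * t / 1000.0)
        g1 = met.rhythmicity_gamma(s, dt).gamma
        g2 = met.rhythmicity_gamma(scale * s, dt).gamma
        assert g2 == pytest.approx(g1, rel=1e-9)

    def test_gamma_decreases_with_jitter(self):
        """Independent noise added to a synthetic periodic trace lowers γ
        monotonically as the noise amplitude grows."""
        dt = 0.05
        t = np.arange(0, 400.0, dt)
        rng = np.random.default_rng(2)
        eta = rng.normal(size=t.size)
        gammas = []
        for noise in (0.0, 0.05, 0.2):
            s = 0.1 + 0.05 * np.sin(2 * np.pi * 40.0 * t / 1000.0) + noise * eta
            gammas.append(met.rhythmicity_gamma(s, dt).gamma)
        assert gammas[0] > gammas[1] > gammas[2]


class TestMeanFrequency:
    def test_no_spikes_zero(self):
        assert met.mean_population_frequency(np.empty((0, 2)), 10, (0, 1000)) == 0.0

    def test_forty_hertz_exact(self):
        raster = _periodic_raster(5, 25.0, 1000.0)
        f = met.mean_population_frequency(raster, 5, (0.0, 1000.0))
        assert f == pytest.approx(40.0, rel=0.03)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            met.mean_population_frequency(np.empty((0, 2)), 10, (100.0, 100.0))


class TestDetectVolleys:
    def test_synchronous_raster_volley_times(self):
        raster = _periodic_raster(30, 25.0, 500.0)
        vs = met.detect_volleys(raster, 500.0)
        expected = np.arange(25.0, 499.0, 25.0)
        assert vs.times.size == expected.size
        assert np.allclose(vs.times, expected, atol=0.6)
        assert np.all(vs.widths <= 3.0)

    def test_poisson_raster_no_volleys(self, rng):
        n, t_max, rate = 30, 1000.0, 40.0
        rows = []
        for c in range(n):
            k = rng.poisson(rate * t_max / 1000.0)
            for t in rng.uniform(0, t_max, k):
                rows.append((c, t))
        raster = np.array(sorted(rows, key=lambda r: r[1]))
        vs = met.detect_volleys(raster, t_max)
        assert vs.times.size <= 2  # rare threshold excursions only

    def test_jittered_raster_width_tracks_jitter(self, rng):
        sigma = 1.0
        raster = _periodic_raster(50, 25.0, 500.0, jitter=sigma, rng=rng)
        vs = met.detect_volleys(raster, 500.0)
        assert vs.times.size >= 15
        assert 1.5 * sigma <= vs.widths.mean() <= 4.5 * sigma


class TestEntrainmentRatio:
    def test_identical_trains_ratio_one(self):
        v = met.VolleySet(np.arange(0.0, 500.0, 25.0), np.ones(20), np.ones(20, int))
        assert met.entrainment_ratio(v, v) == 1

    @pytest.mark.parametrize("ratio", [1, 2, 3, 4])
    def test_constructed_ratios(self, ratio):
        """E-volleys at ratio×f, I-volleys at f (1–2 ms after their E-volley)
        recover the construction ratio for every offset."""
        period_i = 50.0
        t_i = np.arange(period_i, 500.0, period_i)
        t_e = np.arange(period_i / ratio, 500.0, period_i / ratio) - 1.5
        ev = met.VolleySet(np.sort(t_e), np.ones(t_e.size), np.ones(t_e.size, int))
        iv = met.VolleySet(t_i, np.ones(t_i.size), np.ones(t_i.size, int))
        assert met.entrainment_ratio(ev, iv) == ratio

    def test_too_few_i_volleys_signalled(self):
        ev = met.VolleySet(np.arange(0.0, 100.0, 10.0), np.ones(10), np.ones(10, int))
        iv = met.VolleySet(np.array([10.0, 30.0]), np.ones(2), np.ones(2, int))
        with pytest.raises(ValueError):
            met.entrainment_ratio(ev, iv)


class TestSynchronyMeasure:
    def test_perfectly_synchronous_is_one(self):
        raster = _periodic_raster(30, 25.0, 500.0)
        assert met.synchrony_measure(raster, 500.0) == pytest.approx(1.0, abs=0.02)

    def test_uniform_phases_near_zero(self, rng):
        """Spikes spread uniformly over each cycle: σ ≈ 0 within 1/√N."""
        t_max, period = 1000.0, 25.0
        marks = np.arange(0.0, t_max + period, period)
        rows = []
        n_spikes = 4000
        for t in rng.uniform(0.0, t_max, n_spikes):
            rows.append((0, t))
        raster = np.array(sorted(rows, key=lambda r: r[1]))
        volleys = met.VolleySet(marks, np.ones(marks.size), np.ones(marks.size, int))
        sigma = met.synchrony_measure(raster, t_max, volleys=volleys)
        assert sigma < 3.0 / np.sqrt(n_spikes)

    def test_single_volley_degenerate(self):
        raster = np.column_stack([np.zeros(20), np.full(20, 100.0)])
        with pytest.raises(ValueError):
            met.synchrony_measure(raster, 400.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(jit=st.floats(0.0, 3.0))
    def test_sigma_bounded(self, jit):
        raster = _periodic_raster(20, 25.0, 400.0, jitter=jit,
                                  rng=np.random.default_rng(5))
        try:
            sigma = met.synchrony_measure(raster, 400.0)
        except ValueError:
            return
        assert 0.0 <= sigma <= 1.0


class TestSynchronizationTime:
    def test_tight_from_start(self):
        vs = met.VolleySet(np.arange(25.0, 400.0, 25.0), np.full(15, 2.0),
                           np.ones(15, int))
        assert met.synchronization_time(vs) == pytest.approx(25.0)

    def test_never_tight(self):
        vs = met.VolleySet(np.arange(25.0, 400.0, 25.0), np.full(15, 12.0),
                           np.ones(15, int))
        assert met.synchronization_time(vs) is None

    def test_tightens_midway(self):
        widths = np.r_[np.full(5, 10.0), np.full(10, 3.0)]
        vs = met.VolleySet(np.arange(25.0, 400.0, 25.0), widths, np.ones(15, int))
        assert met.synchronization_time(vs) == pytest.approx(25.0 * 6)
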