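"""Statistical tests of the network/drive generators against closed forms."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from ping_assembly import network_builder as nb


class TestRandomNetwork:
    def test_all_to_all_row_sums_exact(self):
        net = nb.build_all_to_all(80, 20, 0.25, 0.2, 0.1)
        assert np.allclose(net.G("ei"), 0.25)
        assert np.allclose(net.G("ie"), 0.2)
        assert np.allclose(net.G("ii"), 0.1)
        assert net.Gbar("ei") == pytest.approx(0.25)

    def test_sparse_compensation_binomial_moments(self):
        """At p = 0.5 survivors are doubled; per-target G has the
        Binomial-predicted mean and variance."""
        n_e, n_i, p, gbar = 80, 20, 0.5, 0.08
        g_pair = gbar / n_e
        samples = []
        for seed in range(400):
            net = nb.build_random_network(n_e, n_i, p, gbar, 0.2, 0.1, seed=seed)
            samples.append(net.G("ei"))
        G = np.concatenate(samples)
        assert (net.g_ei[net.g_ei > 0] == pytest.approx(2 * g_pair))
        assert G.mean() == pytest.approx(gbar, rel=0.01)
        var_expected = n_e * (g_pair / p) ** 2 * p * (1 - p)
        assert G.var() == pytest.approx(var_expected, rel=0.05)

    @pytest.mark.parametrize("gbar", [0.08, 0.04])
    def test_fig3_style_network(self, gbar):
        """80 E / 20 I at 50 % connectivity preserves the target mean."""
        net = nb.build_random_network(80, 20, 0.5, gbar, 0.2, 0.1, seed=0)
        assert net.g_ei.shape == (80, 20)
        frac = np.mean(net.g_ei > 0)
        assert frac == pytest.approx(0.5, abs=0.05)
        means = [nb.build_random_network(80, 20, 0.5, gbar, 0.2, 0.1, seed=s).Gbar("ei")
                 for s in range(50)]
        assert np.mean(means) == pytest.approx(gbar, rel=0.02)

    def test_p_zero_with_target_rejected(self):
        with pytest.raises(ValueError):
            nb.build_random_network(10, 5, 0.0, 0.1, 0.1, 0.1)

    def test_no_self_inhibition(self):
        net = nb.build_all_to_all(10, 5, 0.1, 0.1, 0.1)
        assert np.all(np.diag(net.g_ii) == 0.0)

    def test_serialization_roundtrip(self):
        net = nb.build_random_network(10, 5, 0.5, 0.1, 0.2, 0.1, seed=3)
        back = nb.NetworkSpec.from_json(net.to_json())
        assert np.array_equal(back.g_ei, net.g_ei)
        assert np.array_equal(back.g_ii, net.g_ii)


class TestHeterogeneousDrives:
    def test_zero_heterogeneity_uniform(self):
        d = nb.make_heterogeneous_drives(50, 1.6, 0.0, seed=0)
        assert np.all(d == 1.6)

    def test_spread_and_exact_mean(self):
        d = nb.make_heterogeneous_drives(80, 1.6, 15.0, seed=1)
        assert d.max() - d.min() == pytest.approx(2 * 0.15 * 1.6, rel=1e-12)
        assert d.mean() == pytest.approx(1.6, abs=1e-12)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            nb.make_heterogeneous_drives(10, -1.0, 10.0)


class TestPoissonDrive:
    def test_zero_rate_empty(self):
        sched = nb.make_poisson_drive(5, 0.0, 400.0, seed=0)
        assert all(s.size == 0 for s in sched)

    def test_counts_follow_poisson_law(self):
        """Event counts across 500 cells pass a χ² GOF test vs Poisson(rW)."""
        rate, window = 20.0, 1000.0
        sched = nb.make_poisson_drive(500, rate, window, seed=42)
        counts = np.array([s.size for s in sched])
        lam = rate * window / 1000.0
        kmax = int(stats.poisson.ppf(0.999, lam))
        edges = np.arange(0, kmax + 1)
        obs = np.array([(counts == k).sum() for k in edges], dtype=float)
        exp = stats.poisson.pmf(edges, lam) * counts.size
        keep = exp > 5
        obs_k, exp_k = obs[keep], exp[keep]
        exp_k *= obs_k.sum() / exp_k.sum()
        chi2 = ((obs_k - exp_k) ** 2 / exp_k).sum()
        p = stats.chi2.sf(chi2, df=keep.sum() - 1)
        assert p > 0.01

    def test_streams_independent(self):
        sched = nb.make_poisson_drive(2, 100.0, 5000.0, seed=7)
        edges = np.arange(0.0, 5000.0 + 50.0, 50.0)
        a, _ = np.histogram(sched[0], bins=edges)
        b, _ = np.histogram(sched[1], bins=edges)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(a))


class TestSpatialNetwork:
    def test_large_ell_limit_all_to_all(self):
        net, _ = nb.build_spatial_network(40, 10, 1e6, 0.01, 0.01, 0.01, seed=0)
        assert np.mean(net.g_ei > 0) == pytest.approx(1.0, abs=0.01)

    def test_exponential_distance_decay(self):
        """Binned connection frequency vs distance has slope −1/ℓ ± 10 %."""
        ell = 0.25
        rng = np.random.default_rng(0)
        freqs, mids = [], []
        net, lay = nb.build_spatial_network(400, 400, ell, 1e-3, 1e-3, 1e-3, seed=1)
        d = np.hypot(lay.pos_e[:, None, 0] - lay.pos_i[None, :, 0],
                     lay.pos_e[:, None, 1] - lay.pos_i[None, :, 1])
        conn = net.g_ei > 0
        edges = np.linspace(0.05, 1.2, 14)
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (d >= lo) & (d < hi)
            if sel.sum() > 200:
                freqs.append(conn[sel].mean())
                mids.append(0.5 * (lo + hi))
        slope = np.polyfit(mids, np.log(freqs), 1)[0]
        assert slope == pytest.approx(-1.0 / ell, rel=0.10)

    def test_doubling_size_halving_strength_preserves_gbar(self):
        net1, _ = nb.build_spatial_network(320, 80, 0.25, 0.02, 0.04, 0.02, seed=2)
        net2, _ = nb.build_spatial_network(640, 160, 0.25, 0.01, 0.02, 0.01, seed=3)
        assert net2.Gbar("ei") == pytest.approx(net1.Gbar("ei"), rel=0.1)
        assert net2.Gbar("ie") == pytest.approx(net1.Gbar("ie"), rel=0.1)

    def test_positions_inside_disk(self):
        _, lay = nb.build_spatial_network(100, 30, 0.3, 0.01, 0.01, 0.01, seed=4)
        assert np.all(np.hypot(*lay.pos_e.T) <= 1.0)
        assert np.all(np.hypot(*lay.pos_i.T) <= 1.0)

    def test_geometric_heterogeneity_edge_vs_center(self):
        """Cells near the edge of the driven patch receive less input from
        the driven (active) population than cells at its center, because
        connection probability decays with distance."""
        rho = 0.5
        ratios = []
        for seed in range(5):
            net, lay = nb.build_spatial_network(320, 80, 0.25, 0.015, 0.045,
                                                0.02, rho=rho, seed=seed)
            driven = nb.select_driven_patch(lay, rho)
            # excitatory input onto I-cells, restricted to driven presynaptic E
            g_from_driven = net.g_ei[driven, :].sum(axis=0)
            r_i = np.hypot(*lay.pos_i.T)
            center = g_from_driven[r_i < 0.5 * rho].mean()
            edge = g_from_driven[(r_i > 0.8 * rho) & (r_i <= rho)].mean()
            ratios.append(center / edge)
        assert np.mean(ratios) > 1.1


class TestDrivenPatch:
    def test_rho_one_selects_all(self):
        _, lay = nb.build_spatial_network(50, 10, 0.3, 0.01, 0.01, 0.01, seed=0)
        assert nb.select_driven_patch(lay, 1.0).size == 50

    def test_tiny_rho_near_empty(self):
        _, lay = nb.build_spatial_network(50, 10, 0.3, 0.01, 0.01, 0.01, seed=0)
        assert nb.select_driven_patch(lay, 0.02).size <= 2

    def test_expected_count_area_ratio(self):
        counts = []
        for seed in range(30):
            _, lay = nb.build_spatial_network(200, 10, 0.3, 0.01, 0.01, 0.01,
                                              seed=seed)
            counts.append(nb.select_driven_patch(lay, 0.5).size)
        assert np.mean(counts) == pytest.approx(200 * 0.5 ** 2, rel=0.1)


class TestStatisticalHeterogeneity:
    def test_cv_of_input_scales_with_inverse_sqrt_driven_count(self):
        """Law of Large Numbers: CV of summed excitatory conductance per
        I-cell falls as 1/√n_driven."""
        p, g_pair = 0.5, 0.01
        cvs = {}
        for n_driven in (25, 100, 400):
            vals = []
            for seed in range(40):
                rng = np.random.default_rng(seed)
                mask = rng.random((n_driven, 50)) < p
                G = (mask * (g_pair / p)).sum(axis=0)
                vals.append(G.std() / G.mean())
            cvs[n_driven] = np.mean(vals)
        assert cvs[25] / cvs[100] == pytest.approx(2.0, rel=0.15)
        assert cvs[100] / cvs[400] == pytest.approx(2.0, rel=0.15)
        # matches the closed form sqrt((1-p)/(p n))
        assert cvs[100] == pytest.approx(np.sqrt((1 - p) / (p * 100)), rel=0.1)
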