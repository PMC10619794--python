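import numpy as np
import pytest

import gaitstab as g
from oracles import brute_force_divergence, brute_force_embed


class TestTimeNormalize:
    def test_uniform_strides_are_resampling_identity(self):
        # 20 strides of exactly 1.0 s at 100 Hz: grid hits original samples
        time = np.arange(2101) / 100.0
        signal = np.sin(2 * np.pi * time) + 0.3 * np.cos(4 * np.pi * time)
        hs = np.arange(21) * 1.0
        out = g.time_normalize(signal, time, hs, samples_per_stride=100)
        assert out.size == 2000
        np.testing.assert_allclose(out, signal[:2000], atol=1e-9)

    def test_variable_strides_forced_length(self):
        rng = np.random.default_rng(0)
        hs = np.cumsum(np.concatenate([[0.5], rng.uniform(0.9, 1.3, 30)]))
        time = np.arange(0, hs[-1] + 1.0, 0.01)
        out = g.time_normalize(np.sin(time), time, hs, samples_per_stride=100)
        assert out.size == 3000

    def test_linear_ramp_preserved(self):
        time = np.arange(1500) / 100.0
        signal = 0.25 * time - 3.0
        hs = np.arange(12) * 1.17 + 0.3
        out = g.time_normalize(signal, time, hs, samples_per_stride=100)
        grid = hs[0] + (hs[-1] - hs[0]) * np.arange(1100) / 1100
        np.testing.assert_allclose(out, 0.25 * grid - 3.0, atol=1e-9)

    def test_too_few_strides_rejected(self):
        time = np.arange(300) / 100.0
        with pytest.raises(ValueError, match="strides"):
            g.time_normalize(np.sin(time), time, np.array([0.0, 1.0, 2.0]))


class TestDelayEmbed:
    def test_point_count(self):
        E = g.delay_embed(np.arange(200.0), embedding_dim=6, delay=25)
        assert E.shape == (75, 6)

    def test_dim_one_is_identity(self):
        x = np.random.default_rng(1).normal(size=50)
        np.testing.assert_array_equal(g.delay_embed(x, 1, 25)[:, 0], x)

    def test_matches_index_arithmetic_oracle(self):
        x = g.simulate_reference_series("logistic_map", 2000)[:300]
        E = g.delay_embed(x, embedding_dim=4, delay=7)
        np.testing.assert_allclose(
            E, np.array(brute_force_embed(x, 4, 7)), atol=1e-15
        )

    def test_short_series_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="126"):
            g.delay_embed(np.arange(100.0), embedding_dim=6, delay=25)


class TestSlope:
    def test_exact_line(self):
        assert g.lde_slope(np.arange(100) * 0.01, 50) == pytest.approx(0.01, abs=1e-14)

    def test_constant_curve(self):
        assert g.lde_slope(np.full(100, 2.5), 50) == pytest.approx(0.0, abs=1e-14)

    def test_quadratic_closed_form(self):
        k = np.arange(60, dtype=float)
        curve = 0.02 * k + 1e-4 * k**2
        n = 50
        kk = np.arange(n)
        beta = np.polyfit(kk, curve[:n], 1)[0]
        # closed-form OLS slope on 50 points
        slope = (np.sum(kk * curve[:n]) - n * kk.mean() * curve[:n].mean()) / (
            np.sum(kk**2) - n * kk.mean() ** 2
        )
        assert g.lde_slope(curve, n) == pytest.approx(slope, abs=1e-12)
        assert beta == pytest.approx(slope, abs=1e-12)

    def test_fit_range_exceeding_curve_rejected(self):
        with pytest.raises(ValueError):
            g.lde_slope(np.arange(10.0), 20)


class TestDivergence:
    def test_agrees_with_brute_force_oracle(self):
        """Neighbor sets, curve and slope identical to the O(n²) reference."""
        x = g.simulate_reference_series("logistic_map", 2000)[:420]
        params = g.LdeParams(
            embedding_dim=2, delay=1, n_neighbors=5, theiler_window=10,
            horizon=30, fit_range=10,
        )
        res = g.divergence_exponent(x, params)
        pairs, curve, slope = brute_force_divergence(x, params)
        assert res.n_pairs_used == len(pairs)
        np.testing.assert_allclose(res.mean_log_divergence, curve, atol=1e-12)
        assert res.lde == pytest.approx(slope, abs=1e-12)

    def test_oracle_equivalence_on_noisy_cycle(self):
        x = g.simulate_reference_series(
            "noisy_limit_cycle", 500, {"jitter_sd": 0.05, "period": 50}, seed=3
        )
        params = g.LdeParams(
            embedding_dim=3, delay=5, n_neighbors=3, theiler_window=25,
            horizon=40, fit_range=20,
        )
        res = g.divergence_exponent(x, params)
        pairs, curve, _ = brute_force_divergence(x, params)
        assert res.n_pairs_used == len(pairs)
        np.testing.assert_allclose(res.mean_log_divergence, curve, atol=1e-12)

    def test_theiler_window_respected(self):
        # neighbor pairs are exposed indirectly: with a huge Theiler window
        # on a short series no admissible neighbors remain
        x = g.simulate_reference_series("periodic", 400, {"period": 40})
        params = g.LdeParams(
            embedding_dim=2, delay=1, n_neighbors=2, theiler_window=390,
            horizon=10, fit_range=5,
        )
        with pytest.raises(ValueError, match="neighbor"):
            g.divergence_exponent(x, params)

    def test_scale_invariance(self):
        x = g.simulate_reference_series(
            "noisy_limit_cycle", 3000, {"jitter_sd": 0.03}, seed=5
        )
        params = g.LdeParams(horizon=200, fit_range=50)
        a = g.divergence_exponent(x, params)
        b = g.divergence_exponent(7.5 * x, params)
        assert b.lde == pytest.approx(a.lde, abs=1e-10)
        np.testing.assert_allclose(
            b.mean_log_divergence - a.mean_log_divergence,
            np.log(7.5), atol=1e-10,
        )

    def test_periodic_signal_does_not_diverge(self):
        x = g.simulate_reference_series("periodic", 5000)
        res = g.divergence_exponent(x, g.LdeParams())
        assert abs(res.lde) <= 0.005

    def test_more_jitter_means_larger_exponent(self):
        params = g.LdeParams(horizon=400, fit_range=50)
        ldes = []
        for jitter in (0.01, 0.05):
            x = g.simulate_reference_series(
                "noisy_limit_cycle", 4000, {"jitter_sd": jitter}, seed=17
            )
            ldes.append(g.divergence_exponent(x, params).lde)
        assert ldes[1] > ldes[0]
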