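"""Generator statistics against closed-form expectations, and seeded
determinism."""

import numpy as np
import pytest

from devmea.datasets import load_presets
from devmea.io import ArrayGeometry, SpikeTrainSet
from devmea.synth import (
    ExpressionCurveSpec,
    NetworkPreset,
    SpikeTemplate,
    expression_curves,
    simulate_expression,
    simulate_network,
    simulate_raw,
)


class TestSimulateNetwork:
    def test_tonic_count_matches_poisson_mean(self):
        # 100 electrodes at 10^-0.5 Hz for 600 s
        p = NetworkPreset(n_active=100, rate_mu_log10=-0.5, rate_sigma_log10=0.0,
                          nb_rate_per_min=0.0)
        s, _ = simulate_network(p, 600.0, seed=1)
        mean = 100 * 10 ** -0.5 * 600
        assert abs(s.n_spikes - mean) < 4 * np.sqrt(mean)

    def test_nb_count_matches_poisson_mean(self):
        p = NetworkPreset(n_active=100, nb_rate_per_min=6.0)
        _, truth = simulate_network(p, 600.0, seed=2)
        assert abs(truth.nb_times.size - 60) < 4 * np.sqrt(60)

    def test_same_seed_identical_output(self):
        p = NetworkPreset(n_active=50, nb_rate_per_min=4.0, burst_trains_fraction=0.2)
        s1, t1 = simulate_network(p, 60.0, seed=7)
        s2, t2 = simulate_network(p, 60.0, seed=7)
        assert s1 == s2
        assert np.array_equal(t1.nb_times, t2.nb_times)

    def test_different_seed_differs(self):
        p = NetworkPreset(n_active=50)
        s1, _ = simulate_network(p, 60.0, seed=1)
        s2, _ = simulate_network(p, 60.0, seed=2)
        assert s1 != s2

    def test_rates_clipped_and_recorded(self):
        p = NetworkPreset(n_active=200, rate_mu_log10=0.0, rate_sigma_log10=2.0)
        _, truth = simulate_network(p, 10.0, seed=3)
        r = truth.rates_hz[truth.active_electrodes]
        assert r.min() >= 0.01 and r.max() <= 20.0

    def test_no_active_with_nbs_rejected(self):
        p = NetworkPreset(n_active=0, nb_rate_per_min=5.0)
        with pytest.raises(ValueError):
            simulate_network(p, 10.0)

    def test_tonic_dead_time_respected(self):
        p = NetworkPreset(n_active=20, rate_mu_log10=0.8, rate_sigma_log10=0.0,
                          nb_rate_per_min=0.0)
        s, _ = simulate_network(p, 60.0, seed=4)
        for e in s.electrodes:
            assert np.diff(s.times[e]).min() > 0.002


class TestPresets:
    def test_named_fixtures_present(self):
        presets = load_presets()
        assert {"WT-8div", "WT-16div", "Lgdel-8div", "Lgdel-16div", "Dgcr8-16div"} <= set(presets)

    def test_developmental_contrasts(self):
        presets = load_presets()
        # Lgdel networks lack NBs at 8 DIV
        assert presets["Lgdel-8div"].nb_rate_per_min == 0.0
        assert presets["WT-8div"].nb_rate_per_min > 0.0
        # Lgdel hyper-excitable at 16 DIV: higher mean rate than WT
        assert presets["Lgdel-16div"].rate_mu_log10 > presets["WT-16div"].rate_mu_log10


class TestSimulateRaw:
    def test_noise_sd_concentrates(self, single_geom):
        s = SpikeTrainSet(single_geom, 10.0)  # zero spikes, pure noise
        rec = simulate_raw(s, noise_sd=5.0, seed=0)
        assert rec.traces.shape == (1, 78000)
        assert abs(np.std(rec.traces[0]) - 5.0) / 5.0 < 0.02

    def test_noiseless_insertion_exact(self, single_geom):
        s = SpikeTrainSet(single_geom, 1.0, {0: [0.5]}, {0: [-90.0]})
        rec = simulate_raw(s, SpikeTemplate(), noise_sd=0.0)
        i = int(np.argmin(rec.traces[0]))
        assert rec.traces[0].min() == pytest.approx(-90.0)
        assert i == round(0.5 * rec.sampling_rate)

    def test_overlapping_templates_sum(self, single_geom):
        s = SpikeTrainSet(single_geom, 1.0, {0: [0.5, 0.5004]}, {0: [-50.0, -50.0]})
        rec = simulate_raw(s, SpikeTemplate(), noise_sd=0.0)
        assert rec.traces[0].min() < -50.0  # lobes overlap and add

    def test_edge_spike_truncated_with_warning(self, single_geom, caplog):
        s = SpikeTrainSet(single_geom, 1.0, {0: [0.9999]}, {0: [-90.0]})
        with caplog.at_level("WARNING"):
            rec = simulate_raw(s, SpikeTemplate(), noise_sd=0.0)
        assert "truncated" in caplog.text
        assert rec.n_samples == round(1.0 * rec.sampling_rate)

    def test_seeded_determinism(self, single_geom):
        s = SpikeTrainSet(single_geom, 2.0, {0: [1.0]}, {0: [-60.0]})
        r1 = simulate_raw(s, noise_sd=5.0, seed=9)
        r2 = simulate_raw(s, noise_sd=5.0, seed=9)
        assert np.array_equal(r1.traces, r2.traces)


class TestSpikeTemplate:
    def test_waveform_contract(self):
        w = SpikeTemplate(peak_uv=-80, width_ms=2.0).waveform(7800.0)
        assert w.min() == pytest.approx(-1.0)
        assert w[0] == 0.0 and w[-1] == 0.0
        assert w.max() > 0  # biphasic

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SpikeTemplate(peak_uv=10.0)
        with pytest.raises(ValueError):
            SpikeTemplate(width_ms=0.0)


class TestSimulateExpression:
    def test_noiseless_curves_cross_at_requested_div(self):
        spec = ExpressionCurveSpec(crossing_div=20.5, sem_pct=0.0)
        t = np.linspace(8, 26, 1801)
        nkcc1, kcc2 = expression_curves(spec, t)
        d = kcc2 - nkcc1
        i = np.flatnonzero(np.diff(np.sign(d)))[0]
        assert t[i] <= 20.5 <= t[i + 1]
        # monotone in the right directions
        assert np.all(np.diff(nkcc1) <= 0) and np.all(np.diff(kcc2) >= 0)

    def test_noiseless_series_bracket_crossing(self):
        spec = ExpressionCurveSpec(crossing_div=20.5, sem_pct=0.0)
        (nkcc1, kcc2), true = simulate_expression(spec)[0], 20.5
        from devmea.switch import estimate_switch

        est = estimate_switch(nkcc1, kcc2)
        assert 16.0 <= est.crossing_div <= 26.0  # bracketing sample interval

    def test_boundary_crossing_at_first_div(self):
        spec = ExpressionCurveSpec(crossing_div=8.0, sem_pct=0.0)
        (nkcc1, kcc2), _ = simulate_expression(spec)
        assert np.all(kcc2.mean_pct >= nkcc1.mean_pct)
        from devmea.switch import estimate_switch

        assert estimate_switch(nkcc1, kcc2).crossing_div == 8.0

    def test_seeded_determinism(self):
        spec = ExpressionCurveSpec(sem_pct=3.0, seed=11)
        (a1, b1), _ = simulate_expression(spec)
        (a2, b2), _ = simulate_expression(spec)
        assert np.array_equal(a1.mean_pct, a2.mean_pct)
        assert np.array_equal(b1.mean_pct, b2.mean_pct)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ExpressionCurveSpec(steepness=0.0)
        with pytest.raises(ValueError):
            ExpressionCurveSpec(crossing_div=50.0)
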