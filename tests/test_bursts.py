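"""Burst, network-burst and IBI-distribution behaviour, checked against
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_spikes
from devmea.bursts import detect_bursts, detect_network_bursts, ibi_distribution
from devmea.datasets import load_presets
from devmea.io import ArrayGeometry, SpikeTrainSet
from devmea.synth import NetworkPreset, simulate_network


def oracle_bursts(times, min_spikes=5, max_isi=0.1):
    """Exhaustive scan: maximal runs with every ISI strictly below max_isi."""
    out = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and times[j + 1] - times[j] < max_isi:
            j += 1
        if j - i + 1 >= min_spikes:
            out.append((times[i], times[j], j - i + 1))
        i = j + 1
    return out


class TestDetectBursts:
    def test_five_spike_burst(self, small_geom):
        s = make_spikes(small_geom, 10.0, {0: [0, 0.05, 0.10, 0.15, 0.20]})
        bursts, _ = detect_bursts(s)
        (b,) = bursts
        assert (b.n_spikes, b.start, b.end) == (5, 0.0, 0.20)

    def test_four_spikes_no_burst(self, small_geom):
        s = make_spikes(small_geom, 10.0, {0: [0, 0.05, 0.10, 0.15]})
        assert detect_bursts(s)[0] == []

    def test_isi_boundary_strict(self, small_geom):
        # ISIs [50,50,100,50,50] ms: the 100 ms ISI breaks the run
        t = np.cumsum([0, 0.05, 0.05, 0.1, 0.05, 0.05])
        s = make_spikes(small_geom, 10.0, {0: t})
        assert detect_bursts(s)[0] == []

    def test_matches_oracle_on_poisson_train(self, small_geom):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 600, 600))
        t = np.unique(t)
        s = make_spikes(small_geom, 600.0, {0: t})
        bursts, _ = detect_bursts(s)
        expected = oracle_bursts(list(t))
        assert [(b.start, b.end, b.n_spikes) for b in bursts] == pytest.approx(expected)

    @given(
        st.lists(st.integers(0, 99_999), min_size=1, max_size=500, unique=True)
    )
    @settings(max_examples=100)
    def test_matches_oracle_property(self, grid_times):
        # times on a 10 ms grid exercise the strict-inequality boundary hard
        t = np.sort(np.array(grid_times)) * 0.01
        s = make_spikes(ArrayGeometry(2, 2), 1000.0, {0: t})
        bursts, _ = detect_bursts(s)
        got = [(b.start, b.end, b.n_spikes) for b in bursts]
        assert got == pytest.approx(oracle_bursts(list(t)))

    def test_mbr_units(self, small_geom):
        # one active electrode with 3 bursts in 60 s -> 3 bursts/min
        t = np.concatenate([k * 20 + np.arange(5) * 0.05 for k in range(3)])
        s = make_spikes(small_geom, 60.0, {0: t})  # 15 spikes/60s = 0.25 Hz, active
        _, mbr = detect_bursts(s)
        assert mbr == pytest.approx(3.0)


class TestDetectNetworkBursts:
    def _synchronous_set(self, geom, n_active=100, n_sync=50, duration=60.0):
        rng = np.random.default_rng(1)
        trains = {}
        for e in range(n_active):
            # sparse asynchronous background (~0.2 Hz), kept clear of the
            # event window so peak participation is exactly n_sync
            t = np.sort(rng.uniform(0, duration, 12))
            t = t[np.abs(t - 30.0) > 0.5]
            if e < n_sync:  # event at t=30 s inside one 15 ms bin
                t = np.sort(np.append(t, 30.0 + rng.uniform(0, 0.014)))
            trains[e] = np.unique(t)
        return make_spikes(geom, duration, trains)

    def test_single_planted_event(self):
        geom = ArrayGeometry(10, 10)
        s = self._synchronous_set(geom)
        nbs = detect_network_bursts(s)
        assert len(nbs) == 1
        assert nbs[0].peak_participation == 50
        assert nbs[0].start <= 30.0 <= nbs[0].end

    def test_asynchronous_poisson_yields_none(self):
        # expected per-bin participation ~0.75 electrodes << threshold 15
        geom = ArrayGeometry(10, 10)
        p = NetworkPreset(n_active=100, rate_mu_log10=np.log10(0.5),
                          rate_sigma_log10=0.0, nb_rate_per_min=0.0)
        s, _ = simulate_network(p, 600.0, geom, seed=2)
        assert detect_network_bursts(s) == []

    def test_merge_rule(self):
        geom = ArrayGeometry(10, 10)
        rng = np.random.default_rng(3)
        near, far = 30.0, 40.0

        def build(gap):
            trains = {}
            for e in range(100):
                t = np.sort(rng.uniform(0, 60.0, 12))
                if e < 50:
                    t = np.append(t, [near + rng.uniform(0, 0.01),
                                      near + gap + rng.uniform(0, 0.01)])
                trains[e] = np.unique(np.sort(t))
            return make_spikes(geom, 60.0, trains)

        assert len(detect_network_bursts(build(0.030))) == 1   # 30 ms apart: merged
        assert len(detect_network_bursts(build(0.200))) == 2   # 200 ms apart: two NBs

    def test_threshold_monotonicity(self):
        geom = ArrayGeometry(10, 10)
        p = NetworkPreset(n_active=100, nb_rate_per_min=6.0, nb_participation=0.4)
        s, _ = simulate_network(p, 300.0, geom, seed=4)
        counts = [len(detect_network_bursts(s, threshold_frac=f)) for f in (0.15, 0.3, 0.5)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_permutation_invariance(self):
        geom = ArrayGeometry(10, 10)
        s = self._synchronous_set(geom)
        perm = np.random.default_rng(5).permutation(geom.n_electrodes)
        s2 = SpikeTrainSet(geom, s.duration,
                           {int(perm[e]): s.times[e] for e in s.electrodes},
                           {int(perm[e]): s.amplitudes[e] for e in s.electrodes})
        a = detect_network_bursts(s)
        b = detect_network_bursts(s2)
        assert [(nb.start, nb.end, nb.peak_participation) for nb in a] == [
            (nb.start, nb.end, nb.peak_participation) for nb in b
        ]

    def test_preset_contrast_lgdel_lacks_nbs_at_8div(self):
        presets = load_presets()
        s_lg, _ = simulate_network(presets["Lgdel-8div"], 300.0, seed=6)
        s_wt, _ = simulate_network(presets["WT-8div"], 300.0, seed=6)
        assert len(detect_network_bursts(s_lg)) == 0
        assert len(detect_network_bursts(s_wt)) > 0

    def test_needs_active_electrode(self, small_geom):
        with pytest.raises(ValueError):
            detect_network_bursts(SpikeTrainSet(small_geom, 10.0))


class TestIBIDistribution:
    def test_regular_events_unimodal_at_zero(self):
        d = ibi_distribution([0.0, 1.0, 2.0, 3.0])
        assert np.allclose(d.values_s, 1.0)
        assert abs(d.grid[np.argmax(d.density)]) < 0.02  # peak at log10(1)=0

    def test_alternating_gaps_bimodal(self):
        onsets = np.cumsum([0] + [0.2, 5.0] * 10)
        d = ibi_distribution(onsets)
        # modes near log10(0.2) and log10(5)
        from scipy.signal import argrelextrema

        peaks = d.grid[argrelextrema(d.density, np.greater)[0]]
        assert np.any(np.abs(peaks - np.log10(0.2)) < 0.1)
        assert np.any(np.abs(peaks - np.log10(5.0)) < 0.1)
        # kernel-density oracle: same values, same bandwidth rule
        x = np.log10(np.diff(onsets))
        bw = 0.05 * (x.max() - x.min())
        oracle = np.exp(-0.5 * ((d.grid[:, None] - x[None, :]) / bw) ** 2).sum(axis=1)
        oracle /= np.trapezoid(oracle, d.grid)
        assert np.allclose(d.density, oracle)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(7)
        onsets = np.cumsum(rng.exponential(2.0, 50))
        d = ibi_distribution(onsets)
        assert abs(np.trapezoid(d.density, d.grid) - 1.0) < 1e-6

    def test_accepts_burst_objects(self, small_geom):
        t = np.concatenate([k * 10 + np.arange(5) * 0.05 for k in range(4)])
        s = make_spikes(small_geom, 60.0, {0: t})
        bursts, _ = detect_bursts(s)
        d = ibi_distribution(bursts)
        assert np.allclose(d.values_s, 10.0)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            ibi_distribution([1.0])
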