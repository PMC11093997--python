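"""LFP preprocessing, Morlet TFR baseline, Rayleigh phase stats, modulation."""

import numpy as np
import pytest

from marmonav.config import LfpConfig
from marmonav.events import (LfpSeries, align_firing, classify_modulation,
                             fit_aperiodic, morlet_tfr, preprocess_lfp,
                             rayleigh_over_window, rayleigh_p, rayleigh_z,
                             theta_phase)


class TestPreprocess:
    def test_clean_theta_sinusoid_preserved(self):
        fs_raw = 10_000.0
        t = np.arange(0, 20, 1 / fs_raw)
        raw = np.sin(2 * np.pi * 8.0 * t)
        lfp = preprocess_lfp(raw, fs_raw)
        assert lfp.fs == 1000.0
        assert lfp.artifact_mask.mean() < 0.05
        mid = lfp.samples[2000:-2000]
        assert np.percentile(np.abs(mid), 95) == pytest.approx(1.0, abs=0.05)

    def test_dc_offset_removed(self):
        fs_raw = 10_000.0
        raw = np.full(int(20 * fs_raw), 5.0) + \
            np.sin(2 * np.pi * 8.0 * np.arange(0, 20, 1 / fs_raw))
        lfp = preprocess_lfp(raw, fs_raw)
        assert abs(lfp.samples[2000:-2000].mean()) < 0.01

    def test_high_frequency_burst_masked(self):
        rng = np.random.default_rng(0)
        fs_raw = 10_000.0
        n = int(30 * fs_raw)
        raw = rng.standard_normal(n)
        t = np.arange(n) / fs_raw
        burst = (t > 15.0) & (t < 15.2)
        raw[burst] += 10.0 * np.sin(2 * np.pi * 150.0 * t[burst])
        lfp = preprocess_lfp(raw, fs_raw)
        sec = lfp.artifact_mask[int(15.05 * 1000):int(15.15 * 1000)]
        assert sec.all()
        # and the pad extends at least 100 ms before onset
        assert lfp.artifact_mask[int(14.92 * 1000)]

    def test_raw_rate_below_target_rejected(self):
        with pytest.raises(ValueError):
            preprocess_lfp(np.zeros(100), 500.0)


class TestAperiodic:
    def test_pure_power_law_recovered(self):
        freqs = np.arange(1.0, 31.0)
        psd = 10.0 * freqs ** -1.5
        off, expo = fit_aperiodic(freqs, psd)
        assert expo == pytest.approx(1.5, abs=0.01)
        assert off == pytest.approx(1.0, abs=0.01)

    def test_oscillatory_peak_excluded(self):
        freqs = np.arange(1.0, 31.0)
        psd = 10.0 * freqs ** -1.5
        psd[6:9] *= 30.0  # theta bump
        _, expo = fit_aperiodic(freqs, psd)
        assert expo == pytest.approx(1.5, abs=0.15)


class TestThetaPhase:
    def test_cosine_phase_zero_at_origin(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        lfp = LfpSeries(fs=fs, samples=np.cos(2 * np.pi * 6.0 * t))
        ph = theta_phase(lfp)
        # cos is at phase 0 on every full cycle; check away from filter edges
        assert abs(ph[1000]) < 0.05
        # advances at 6 cycles/s
        cyc = np.unwrap(ph)
        rate = (cyc[-1000] - cyc[1000]) / (t[-1000] - t[1000]) / (2 * np.pi)
        assert rate == pytest.approx(6.0, abs=0.01)

    def test_negated_cosine_offset_by_pi(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        a = theta_phase(LfpSeries(fs=fs, samples=np.cos(2 * np.pi * 6 * t)))
        b = theta_phase(LfpSeries(fs=fs, samples=-np.cos(2 * np.pi * 6 * t)))
        d = np.angle(np.exp(1j * (b - a)))
        assert np.allclose(np.abs(d[500:-500]), np.pi, atol=0.05)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            theta_phase(LfpSeries(fs=1000.0, samples=np.zeros(100)),
                        band=(10.0, 4.0))


class TestRayleigh:
    def test_identical_phases_give_z_equal_n(self):
        phases = np.full((37, 5), 1.3)
        z, r = rayleigh_z(phases, axis=0)
        assert np.allclose(z, 37.0)
        assert np.allclose(r, 1.0)

    def test_uniform_phases_expected_z_one(self):
        rng = np.random.default_rng(1)
        phases = rng.uniform(-np.pi, np.pi, (200, 2000))
        z, _ = rayleigh_z(phases, axis=0)
        assert abs(z.mean() - 1.0) < 0.1
        p = rayleigh_p(z, 200)
        assert abs((p < 0.01).mean() - 0.01) < 0.01

    def test_invariant_to_global_phase_rotation(self):
        rng = np.random.default_rng(2)
        phases = rng.vonmises(0.0, 2.0, (50, 20))
        z1, _ = rayleigh_z(phases)
        z2, _ = rayleigh_z(np.angle(np.exp(1j * (phases + 1.234))))
        assert np.allclose(z1, z2, atol=1e-9)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        phases = rng.vonmises(0.5, 1.0, 40)
        z, _ = rayleigh_z(phases[:, None])
        p = rayleigh_p(z, 40)
        z_ref, p_ref = pingouin.circ_rayleigh(phases)
        assert z[0] == pytest.approx(z_ref, rel=1e-9)
        assert p[0] == pytest.approx(p_ref, rel=1e-6)

    def test_too_few_events_rejected(self):
        lfp = LfpSeries(fs=1000.0, samples=np.random.default_rng(0)
                        .standard_normal(5000))
        with pytest.raises(ValueError, match="at least 10"):
            rayleigh_over_window(lfp, np.array([1.0, 2.0]))


class TestModulation:
    DURATION = 400.0

    def _events(self, rng, n=120):
        return np.sort(rng.uniform(5.0, self.DURATION - 5.0, n))

    def test_stationary_unit_unmodulated(self):
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(0, self.DURATION, 2000))
        res = classify_modulation("u", spikes, self._events(rng),
                                  self.DURATION, rng=rng)
        assert res.label == "unmodulated"

    def test_threefold_gain_is_upmodulated(self):
        rng = np.random.default_rng(5)
        base = np.sort(rng.uniform(0, self.DURATION, 2000))
        events = self._events(rng)
        # x3 rate in the 100 ms after the event peak
        extra = np.concatenate([
            ev + rng.uniform(0.0, 0.1, rng.poisson(1.0))
            for ev in events])
        spikes = np.sort(np.concatenate([base, extra]))
        res = classify_modulation("u", spikes, events, self.DURATION, rng=rng)
        assert res.label == "up"
        assert 0.0 <= res.peak_s <= 0.15

    def test_suppression_is_downmodulated(self):
        rng = np.random.default_rng(6)
        spikes = np.sort(rng.uniform(0, self.DURATION, 4000))
        events = self._events(rng)
        keep = np.ones(spikes.size, bool)
        for ev in events:
            win = (spikes > ev) & (spikes < ev + 0.15)
            keep &= ~(win & (rng.uniform(size=spikes.size) < 0.9))
        res = classify_modulation("u", spikes[keep], events, self.DURATION,
                                  rng=rng)
        assert res.label == "down"

    def test_suppression_then_excitation_is_down_up(self):
        rng = np.random.default_rng(7)
        spikes = np.sort(rng.uniform(0, self.DURATION, 4000))
        events = self._events(rng)
        keep = np.ones(spikes.size, bool)
        for ev in events:
            win = (spikes > ev - 0.15) & (spikes < ev - 0.02)
            keep &= ~(win & (rng.uniform(size=spikes.size) < 0.9))
        extra = np.concatenate([
            ev + rng.uniform(0.02, 0.12, rng.poisson(1.2)) for ev in events])
        spikes = np.sort(np.concatenate([spikes[keep], extra]))
        res = classify_modulation("u", spikes, events, self.DURATION, rng=rng)
        assert res.label == "down_up"

    def test_empty_event_list_rejected(self):
        with pytest.raises(ValueError, match="empty event"):
            classify_modulation("u", np.array([1.0]), np.array([]), 10.0,
                                rng=0)

    def test_align_firing_flat_for_poisson(self):
        rng = np.random.default_rng(8)
        spikes = np.sort(rng.uniform(0, self.DURATION, 3000))
        centers, rate, z = align_firing(spikes, self._events(rng),
                                        self.DURATION)
        assert centers.size == 8
        assert np.all(np.abs(z) < 3.0)


class TestMorletTfr:
    def _lfp(self, rng, duration=120.0, fs=1000.0, freq=None):
        n = int(duration * fs)
        x = rng.standard_normal(n)
        if freq is not None:
            x = 0.2 * x + np.cos(2 * np.pi * freq * np.arange(n) / fs)
        return LfpSeries(fs=fs, samples=x)

    def test_white_noise_map_flat(self):
        rng = np.random.default_rng(9)
        lfp = self._lfp(rng)
        events = np.sort(rng.uniform(5, 115, 60))
        tfr = morlet_tfr(lfp, events, window=1.0)
        assert np.abs(tfr.power_db.mean(axis=1)).max() < 1.0

    def test_pure_oscillation_peaks_at_its_frequency(self):
        rng = np.random.default_rng(10)
        lfp = self._lfp(rng, freq=8.0)
        events = np.sort(rng.uniform(5, 115, 40))
        tfr = morlet_tfr(lfp, events, window=1.0)
        band = tfr.power_db.mean(axis=1)
        assert tfr.freqs[int(np.argmax(band))] == pytest.approx(8.0, abs=1.0)

    def test_events_overlapping_artifacts_dropped(self):
        rng = np.random.default_rng(11)
        lfp = self._lfp(rng)
        lfp.artifact_mask[50_000:52_000] = True
        events = np.concatenate([np.sort(rng.uniform(5, 45, 30)), [50.5]])
        tfr = morlet_tfr(lfp, events, window=1.0)
        assert tfr.n_events_dropped == 1
        assert tfr.n_events_used == 30
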