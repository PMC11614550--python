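"""Phase extraction, Rayleigh test with subsampling, STWA shuffle ratio."""

import numpy as np
import pytest

from betasync import (
    instantaneous_phase,
    make_beta_source,
    phase_locked_summary,
    rayleigh_test,
    spike_phases,
    stwa,
    stwa_shuffle_ratio,
    synthesize_spike_train,
)
from betasync.io import SpikeTrain
from betasync.spikefield import select_target_channel, shuffle_spike_times
from betasync.synth import oscillation_phase

FS = 1000.0
BAND = (25.0, 40.0)


def _tone(freq=30.0, amp=1.0, duration=60.0):
    t = np.arange(int(duration * FS)) / FS
    return amp * np.cos(2 * np.pi * freq * t), t


class TestPhase:
    def test_zero_phase_at_tone_maxima(self):
        sig, t = _tone()
        ph = instantaneous_phase(sig, FS, BAND)
        peaks = np.where((sig[1:-1] > sig[:-2]) & (sig[1:-1] > sig[2:]))[0] + 1
        assert np.degrees(np.abs(ph[peaks[5:-5]])).max() < 5

    def test_phase_velocity_matches_tone_frequency(self):
        sig, _ = _tone()
        ph = np.unwrap(instantaneous_phase(sig, FS, BAND))
        inner = slice(5000, -5000)
        rate = np.mean(np.diff(ph[inner])) * FS
        assert rate == pytest.approx(2 * np.pi * 30, rel=0.01)

    def test_broadband_noise_phases_uniform(self):
        rng = np.random.default_rng(0)
        ph = instantaneous_phase(rng.standard_normal(60000), FS, BAND)
        n_locked = 0
        for _ in range(50):
            sample = rng.choice(ph, 40, replace=False)
            n_locked += rayleigh_test(sample, 40, rng).locked
        assert n_locked / 50 < 0.2

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(1000), FS, (40, 25))


class TestSpikePhases:
    def test_spikes_at_maxima_read_zero_phase(self):
        sig, t = _tone()
        ph = instantaneous_phase(sig, FS, BAND)
        spike_t = np.arange(30, 1740) / 30.0  # tone maxima at multiples of 1/30 s
        angles, skipped = spike_phases(spike_t, ph, FS)
        assert skipped == 0
        assert np.degrees(np.abs(angles)).max() < 15

    def test_empty_train_gives_empty_list(self):
        angles, skipped = spike_phases(np.array([]), np.zeros(1000), FS)
        assert angles.size == 0 and skipped == 0

    def test_out_of_range_spikes_counted(self):
        angles, skipped = spike_phases(np.array([0.1, 2.0]), np.zeros(1000), FS)
        assert angles.size == 1 and skipped == 1

    def test_jittered_spikes_attenuate_vector_strength(self):
        sig, _ = _tone()
        ph = instantaneous_phase(sig, FS, BAND)
        rng = np.random.default_rng(3)
        base = np.arange(1, 1760) / 30.0  # one spike per cycle
        jitter = rng.normal(0, 0.002, base.size)
        angles, _ = spike_phases(np.sort(base + jitter), ph, FS)
        r = np.abs(np.exp(1j * angles).mean())
        # R = exp(-sigma_phi^2/2) for Gaussian phase jitter
        expected = np.exp(-0.5 * (2 * np.pi * 30 * 0.002) ** 2)
        assert r == pytest.approx(expected, abs=0.03)


class TestRayleigh:
    def test_39_spikes_excluded(self, rng):
        res = rayleigh_test(rng.uniform(-np.pi, np.pi, 39), 40, rng)
        assert res.excluded and res.n_spikes_available == 39

    def test_identical_angles_fully_locked(self, rng):
        res = rayleigh_test(np.full(40, 1.3), 40, rng)
        assert res.r == pytest.approx(1.0)
        assert res.z == pytest.approx(40.0)
        assert res.locked
        assert res.preferred_phase == pytest.approx(1.3)

    def test_uniformly_spaced_angles_null(self, rng):
        angles = np.linspace(-np.pi, np.pi, 40, endpoint=False)
        res = rayleigh_test(angles, 40, rng)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0
        assert not res.locked

    def test_z_equals_n_r_squared(self, rng):
        for _ in range(20):
            res = rayleigh_test(rng.uniform(-np.pi, np.pi, 80), 40, rng)
            assert res.z == pytest.approx(res.subsample_n * res.r**2, abs=1e-12)

    def test_subsampling_determinism(self):
        angles = np.random.default_rng(5).uniform(-np.pi, np.pi, 200)
        a = rayleigh_test(angles, 40, seed=17)
        b = rayleigh_test(angles, 40, seed=17)
        assert (a.r, a.z, a.p) == (b.r, b.z, b.p)

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha=.05 on uniform phases (reduced-replicate
        check; the full 10k-replicate calibration runs in acceptance)."""
        rng = np.random.default_rng(11)
        n_locked = sum(
            rayleigh_test(rng.uniform(-np.pi, np.pi, 100), 40, rng).locked
            for _ in range(2000)
        )
        assert 0.03 <= n_locked / 2000 <= 0.07


class TestStwa:
    def test_coherent_averaging_reproduces_tone(self):
        sig, t = _tone(amp=1.5)
        spike_t = np.arange(2, 58) * (3 / 30.0)  # every 3rd cycle, at maxima
        train = SpikeTrain("u", "motor_cortex", spike_t)
        res = stwa(train, sig, FS, BAND)
        assert not res.excluded
        assert res.peak_to_trough == pytest.approx(2 * 1.5, rel=0.05)

    def test_incoherent_spikes_average_out(self):
        rng = np.random.default_rng(4)
        lfp = make_beta_source(60, FS, BAND, rng)
        band_ptt = lfp.max() - lfp.min()
        spike_t = np.sort(rng.uniform(1, 59, 2000))
        res = stwa(SpikeTrain("u", "motor_cortex", spike_t), lfp, FS, BAND)
        assert res.peak_to_trough < 0.2 * band_ptt

    def test_zero_lfp_zero_ptt_and_undefined_ratio(self):
        spike_t = np.sort(np.random.default_rng(0).uniform(1, 59, 100))
        train = SpikeTrain("u", "motor_cortex", spike_t)
        res = stwa(train, np.zeros(60000), FS, BAND)
        assert res.peak_to_trough == 0.0
        with pytest.raises(ZeroDivisionError):
            stwa_shuffle_ratio(train, np.zeros(60000), FS, BAND, seed=0)

    def test_too_few_complete_windows_excluded(self):
        train = SpikeTrain("u", "motor_cortex", np.linspace(1, 59, 30))
        res = stwa(train, np.zeros(60000), FS, BAND)
        assert res.excluded

    def test_twenty_shuffles_recorded(self, rng):
        lfp = make_beta_source(60, FS, BAND, rng)
        spike_t = np.sort(rng.uniform(1, 59, 300))
        res = stwa_shuffle_ratio(SpikeTrain("u", "motor_cortex", spike_t), lfp, FS, BAND, seed=rng)
        assert len(res.shuffle_magnitudes) == 20
        assert res.ratio > 0

    def test_shuffle_preserves_isi_multiset(self, rng):
        t = np.sort(rng.uniform(0, 60, 200))
        s = shuffle_spike_times(t, rng)
        assert s.size == t.size
        np.testing.assert_allclose(np.sort(np.diff(s)), np.sort(np.diff(t)), atol=1e-12)
        assert s[0] == t[0] and s[-1] == pytest.approx(t[-1])

    def test_locked_spikes_inflate_ratio(self):
        rng = np.random.default_rng(8)
        beta = make_beta_source(60, FS, BAND, rng)
        lfp = beta + 0.3 * rng.standard_normal(60000)
        train = synthesize_spike_train(
            oscillation_phase(beta), FS, 5, 4.0, 0.0, 60, rng, unit_id="u"
        )
        res = stwa_shuffle_ratio(train, lfp, FS, BAND, seed=rng)
        assert res.ratio > 2

    def test_ratio_monotone_in_kappa(self):
        means = []
        for kappa in (0.0, 1.0, 2.0, 4.0):
            vals = []
            for s in range(5):
                rng = np.random.default_rng(100 + s)
                beta = make_beta_source(60, FS, BAND, rng)
                lfp = beta + 0.3 * rng.standard_normal(60000)
                train = synthesize_spike_train(
                    oscillation_phase(beta), FS, 5, kappa, 0.0, 60, rng, unit_id="u"
                )
                vals.append(stwa_shuffle_ratio(train, lfp, FS, BAND, seed=rng).ratio)
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestSummaryAndTargets:
    def test_locked_proportion_counting(self, rng):
        locked = [rayleigh_test(np.full(40, 0.2), 40, rng) for _ in range(3)]
        unlocked = [
            rayleigh_test(np.linspace(-np.pi, np.pi, 40, endpoint=False), 40, rng)
            for _ in range(7)
        ]
        excluded = [rayleigh_test(np.ones(10), 40, rng)]
        summary = phase_locked_summary({"g": locked + unlocked + excluded})
        assert summary["g"]["n_tested"] == 10
        assert summary["g"]["proportion"] == pytest.approx(0.3)

    def test_all_excluded_warns_and_empty(self, rng):
        res = [rayleigh_test(np.ones(5), 40, rng)]
        with pytest.warns(UserWarning):
            summary = phase_locked_summary({"g": res})
        assert summary == {}

    def test_target_channel_maximises_band_power(self, rest_segment):
        from betasync import band_power, welch_psd

        segment, _ = rest_segment
        rec = segment.recording
        i = select_target_channel(segment, "motor_cortex", BAND)
        powers = {
            j: band_power(welch_psd(rec.samples[j], rec.fs), BAND)
            for j in rec.region_indices("motor_cortex")
        }
        assert powers[i] == max(powers.values())
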