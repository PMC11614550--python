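"""Simulator contracts: spectral content, coupling, locking, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from betasync import (
    SimulationConfig,
    band_power,
    expected_band_coherence,
    expected_vector_strength,
    make_background,
    make_beta_source,
    mean_band_coherence,
    coherence_spectrum,
    spike_phases,
    synthesize_lfp_pair,
    synthesize_spike_train,
    welch_psd,
)
from betasync.io import MOTOR_CORTEX, STRIATUM
from betasync.synth import (
    CohortConfig,
    UnitSpec,
    iter_cohort_segments,
    oscillation_phase,
    synthesize_cohort,
)
from dataclasses import replace


def _psd_loglog_slope(x, fs, f_lo=1.0, f_hi=100.0):
    psd = welch_psd(x, fs)
    sel = (psd.frequencies >= f_lo) & (psd.frequencies <= f_hi) & (psd.power > 0)
    slope, *_ = sps.linregress(np.log10(psd.frequencies[sel]), np.log10(psd.power[sel]))
    return slope


class TestBackground:
    def test_white_noise_when_alpha_zero(self, rng):
        x = make_background(60, 1000, alpha=0.0, sd=1.0, rng=rng)
        assert x.size == 60000
        assert abs(x.std() - 1.0) < 0.05
        assert abs(_psd_loglog_slope(x, 1000)) < 0.1

    def test_zero_sd_gives_silence(self, rng):
        assert not make_background(10, 1000, 1.0, 0.0, rng).any()

    def test_pink_noise_slope(self):
        # average the fitted slope over Monte-Carlo realizations
        slopes = [
            _psd_loglog_slope(
                make_background(60, 1000, 1.0, 1.0, np.random.default_rng(s)), 1000
            )
            for s in range(20)
        ]
        assert abs(np.mean(slopes) + 1.0) < 0.2

    def test_invalid_args_rejected(self, rng):
        with pytest.raises(ValueError):
            make_background(0, 1000, 1.0, 1.0, rng)
        with pytest.raises(ValueError):
            make_background(10, -5, 1.0, 1.0, rng)


class TestBetaSource:
    def test_power_confined_to_band(self, rng):
        x = make_beta_source(60, 1000, (25, 40), rng)
        assert abs(x.var() - 1.0) < 0.05
        psd = welch_psd(x, 1000)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert band_power(psd, (23, 42)) / total >= 0.95

    def test_alpha_band_source_avoids_beta(self, rng):
        x = make_beta_source(60, 1000, (8, 12), rng)
        psd = welch_psd(x, 1000)
        total = np.trapezoid(psd.power, psd.frequencies)
        assert band_power(psd, (25, 40)) / total < 0.02

    def test_sample_count_and_nyquist_guard(self, rng):
        assert make_beta_source(60, 1000, (25, 40), rng).size == 60000
        with pytest.raises(ValueError):
            make_beta_source(10, 1000, (400, 600), rng)


class TestLfpPair:
    def test_no_shared_signal_means_no_coherence(self):
        cfg = SimulationConfig(shared_gain_cortex=0, shared_gain_striatum=0)
        rec, truth = synthesize_lfp_pair(cfg, "rest", 0)
        assert truth.expected_band_coherence == 0
        coh = coherence_spectrum(rec.samples[0], rec.samples[4], 1000)
        # below three times the 1/K independence bias
        assert mean_band_coherence(coh, (25, 40)) < 3.0 / coh.n_windows

    def test_pure_shared_signal_is_fully_coherent(self):
        cfg = SimulationConfig(
            independent_gain_cortex=0,
            independent_gain_striatum=0,
            background_sd=1e-8,
            shared_gain_cortex=1.0,
            shared_gain_striatum=1.0,
        )
        rec, truth = synthesize_lfp_pair(cfg, "rest", 0)
        assert truth.expected_band_coherence > 0.999
        coh = coherence_spectrum(rec.samples[0], rec.samples[4], 1000)
        sel = (coh.frequencies >= 25) & (coh.frequencies <= 40)
        assert coh.cxy[sel].min() >= 0.99

    def test_closed_form_quarter_coherence(self):
        cfg = SimulationConfig(
            shared_gain_cortex=1,
            shared_gain_striatum=1,
            independent_gain_cortex=1,
            independent_gain_striatum=1,
            background_sd=1e-6,
        )
        assert expected_band_coherence(cfg, "rest") == pytest.approx(0.25, abs=1e-6)
        measured = []
        for seed in range(20):
            rec, _ = synthesize_lfp_pair(cfg, "rest", seed)
            coh = coherence_spectrum(rec.samples[0], rec.samples[4], 1000)
            measured.append(mean_band_coherence(coh, (25, 40)))
        assert np.mean(measured) == pytest.approx(0.25, abs=0.05)

    def test_channel_layout_and_regions(self, default_config):
        rec, _ = synthesize_lfp_pair(default_config, "rest", 3)
        assert rec.samples.shape == (8, 60000)
        assert len(rec.region_indices(MOTOR_CORTEX)) == 4
        assert len(rec.region_indices(STRIATUM)) == 4

    def test_power_additivity(self, default_config):
        """Channel variance = background + gain-weighted source variances."""
        rec, _ = synthesize_lfp_pair(default_config, "rest", 11)
        g = default_config
        expected = (
            g.background_sd**2
            + g.shared_gain_cortex**2
            + g.independent_gain_cortex**2
        )
        assert rec.samples[0].var() == pytest.approx(expected, rel=0.05)

    def test_determinism(self, default_config):
        a, _ = synthesize_lfp_pair(default_config, "rest", 42)
        b, _ = synthesize_lfp_pair(default_config, "rest", 42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_coherence_monotone_in_shared_gain(self):
        prev = -1.0
        for g in (0.1, 0.3, 0.6, 1.0):
            cfg = SimulationConfig(shared_gain_cortex=g, shared_gain_striatum=g)
            rec, _ = synthesize_lfp_pair(cfg, "rest", 5)
            coh = coherence_spectrum(rec.samples[0], rec.samples[4], 1000)
            val = mean_band_coherence(coh, (25, 40))
            assert val > prev
            prev = val

    def test_delay_longer_than_segment_rejected(self):
        cfg = SimulationConfig(duration_s=60, conduction_delay_ms=61_000)
        with pytest.raises(ValueError):
            synthesize_lfp_pair(cfg, "rest", 0)


@pytest.fixture(scope="module")
def beta_phase():
    src = make_beta_source(60, 1000, (25, 40), np.random.default_rng(9))
    return oscillation_phase(src)


class TestSpikeTrain:
    def test_unmodulated_train_has_uniform_phases(self, beta_phase, rng):
        train = synthesize_spike_train(beta_phase, 1000, 10, 0.0, 0.0, 60, rng)
        angles, _ = spike_phases(train.spike_times_s, beta_phase, 1000)
        assert angles.size >= 400
        assert np.abs(np.exp(1j * angles).mean()) < 0.1

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_vector_strength_matches_bessel_ratio(self, beta_phase, kappa):
        train = synthesize_spike_train(
            beta_phase, 1000, 20, kappa, 0.0, 60, np.random.default_rng(int(kappa * 10))
        )
        angles, _ = spike_phases(train.spike_times_s, beta_phase, 1000)
        assert angles.size >= 1000
        r = np.abs(np.exp(1j * angles).mean())
        assert r == pytest.approx(expected_vector_strength(kappa), abs=0.05)

    def test_rate_follows_poisson_count(self, beta_phase):
        counts = [
            synthesize_spike_train(
                beta_phase, 1000, 5, 0.0, 0.0, 60, np.random.default_rng(s)
            ).n_spikes
            for s in range(10)
        ]
        assert np.mean(counts) == pytest.approx(300, abs=3 * np.sqrt(300))

    def test_rate_independent_of_kappa(self, beta_phase):
        """The I0 normalisation keeps mean rate at base_rate for any kappa."""
        counts = [
            np.mean(
                [
                    synthesize_spike_train(
                        beta_phase, 1000, 8, k, 0.0, 60, np.random.default_rng(s)
                    ).n_spikes
                    for s in range(5)
                ]
            )
            for k in (0.0, 2.0, 4.0)
        ]
        for c in counts:
            assert c == pytest.approx(480, rel=0.1)

    def test_trains_respect_refractory_period(self, beta_phase):
        """Simulated sorted units never violate the 1-ms refractory screen."""
        from betasync import refractory_check

        for kappa in (0.0, 4.0):
            train = synthesize_spike_train(
                beta_phase, 1000, 15, kappa, 0.0, 60, np.random.default_rng(2)
            )
            frac, ok = refractory_check(train.spike_times_s)
            assert ok and frac == 0.0

    def test_expected_vector_strength_monotone(self):
        vals = [expected_vector_strength(k) for k in (0, 0.5, 1, 2, 4)]
        assert vals[0] == 0
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0 <= v < 1 for v in vals)


class TestCohort:
    def test_dataset_count_on_disk(self, tmp_path):
        cohort = CohortConfig(weeks=(2, 4), n_subjects_per_group=2)
        paths = synthesize_cohort(cohort, tmp_path, seed=1)
        assert len(paths) == 3 * 2 * 2 * 2
        assert (tmp_path / "cohort_manifest.json").exists()
        for p in paths:
            assert (p / "lfp.h5").exists()
            assert (p / "spikes.csv").exists()
            assert (p / "ground_truth.json").exists()

    def test_cohort_determinism(self):
        cohort = CohortConfig(weeks=(2,), n_subjects_per_group=1, states=("rest",))
        runs = []
        for _ in range(2):
            metas = []
            for meta, seg, truth in iter_cohort_segments(cohort, 99):
                metas.append((meta["subject"], seg.recording.samples.sum(), len(seg.spikes[0].spike_times_s)))
            runs.append(metas)
        assert runs[0] == runs[1]

    def test_effect_table_must_be_complete(self):
        with pytest.raises(ValueError):
            CohortConfig(weeks=(2, 4), effect_table={("sham", 2, "rest"): (1.0, 1.0)})

    def test_lesion_multiplier_raises_truth_coherence(self):
        cohort = CohortConfig(weeks=(2,), n_subjects_per_group=1, subject_cv=0.0)
        truth_by_group = {}
        for meta, seg, truth in iter_cohort_segments(cohort, 3):
            if meta["state"] == "rest":
                truth_by_group[meta["group"]] = truth.expected_band_coherence
        assert truth_by_group["lesion"] > 2 * truth_by_group["sham"]
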