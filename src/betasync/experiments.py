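"""Seeded calibration and parameter-recovery experiments.

These functions exercise the full analysis chain against the simulator's
ground truth: estimator bias of Welch coherence under independence, type-I
calibration of the subsampled Rayleigh test, the STWA shuffle-ratio null
and effect distributions, vector-strength recovery across the von Mises
concentration ladder, and group-level recovery of a lesion-like cohort
contrast.  They are used by the test suite and by reproduction scripts.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .coherence import coherence_spectrum, mean_band_coherence, region_pair_coherence
from .io import Segment
from .spectral import band_power, welch_psd
from .spikefield import rayleigh_test, spike_phases, stwa_shuffle_ratio
from .stats import anova_bonferroni
from .synth import (
    SimulationConfig,
    apply_effect,
    make_beta_source,
    oscillation_phase,
    synthesize_lfp_pair,
    synthesize_spike_train,
)

HIGH_BETA = (25.0, 40.0)


def coherence_null_calibration(
    n_seeds: int = 200, duration_s: float = 60.0, fs: float = 1000.0, seed: int = 0
) -> dict:
    """Band-mean coherence of independent white-noise pairs; the Welch
    estimator's independence bias is ~1/K for K averaged windows."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    means = []
    k = None
    for _ in range(n_seeds):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        coh = coherence_spectrum(x, y, fs)
        k = coh.n_windows
        means.append(mean_band_coherence(coh, HIGH_BETA))
    means = np.asarray(means)
    return {
        "mean_band_coherence": float(means.mean()),
        "p95_band_coherence": float(np.quantile(means, 0.95)),
        "expected_bias": 1.0 / k,
        "n_windows": k,
        "n_seeds": n_seeds,
    }


def rayleigh_type1_calibration(
    n_replicates: int = 10000, n_available: int = 100, subsample_n: int = 40, seed: int = 0
) -> dict:
    """Rejection rate of the subsampled Rayleigh test at alpha = .05 on
    uniform phases (should sit at the nominal level)."""
    rng = np.random.default_rng(seed)
    n_locked = 0
    for _ in range(n_replicates):
        angles = rng.uniform(-np.pi, np.pi, n_available)
        res = rayleigh_test(angles, subsample_n, rng)
        n_locked += res.locked
    return {"rejection_rate": n_locked / n_replicates, "n_replicates": n_replicates}


def stwa_ratio_experiment(
    n_units: int = 100,
    kappa: float = 0.0,
    base_rate_hz: float = 5.0,
    duration_s: float = 60.0,
    fs: float = 1000.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict:
    """STWA shuffle ratios for ``n_units`` simulated units.

    kappa = 0 gives the null (spikes independent of the LFP); kappa > 0
    locks the spikes to the LFP's own beta phase.
    """
    ss = np.random.SeedSequence([seed, int(kappa * 1000)])
    ratios = []
    for child in ss.spawn(n_units):
        rng = np.random.default_rng(child)
        beta = make_beta_source(duration_s, fs, HIGH_BETA, rng)
        lfp = beta + noise_sd * rng.standard_normal(len(beta))
        if kappa > 0:
            phase = oscillation_phase(beta)
        else:
            # spikes driven by an unrelated oscillation: independent of lfp
            phase = oscillation_phase(make_beta_source(duration_s, fs, HIGH_BETA, rng))
        train = synthesize_spike_train(
            phase, fs, base_rate_hz, kappa, 0.0, duration_s, rng, unit_id="u"
        )
        res = stwa_shuffle_ratio(train, lfp, fs, HIGH_BETA, seed=rng)
        if not res.excluded:
            ratios.append(res.ratio)
    ratios = np.asarray(ratios)
    return {
        "mean_ratio": float(ratios.mean()),
        "fraction_above_2": float((ratios > 2).mean()),
        "n_units": int(ratios.size),
    }


def vector_strength_ladder(
    kappas: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0),
    base_rate_hz: float = 20.0,
    duration_s: float = 60.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> dict:
    """Empirical resultant length vs the von Mises prediction I1(k)/I0(k),
    measured on the generating phase with >= 1000 spikes per rung."""
    rng = np.random.default_rng(seed)
    phase = oscillation_phase(make_beta_source(duration_s, fs, HIGH_BETA, rng))
    rows = []
    for kappa in kappas:
        train = synthesize_spike_train(
            phase, fs, base_rate_hz, kappa, 0.0, duration_s, rng, unit_id="u"
        )
        angles, _ = spike_phases(train.spike_times_s, phase, fs)
        r = float(np.abs(np.exp(1j * angles).mean()))
        rows.append(
            {
                "kappa": kappa,
                "empirical_r": r,
                "expected_r": synth.expected_vector_strength(kappa),
                "n_spikes": train.n_spikes,
            }
        )
    return {"ladder": rows}


def _subject_measures(
    config: SimulationConfig, state: str, seed
) -> tuple[float, float]:
    """(mean cortical high-beta power, mean corticostriatal band coherence)
    for one simulated subject segment."""
    rec, _ = synthesize_lfp_pair(config, state, seed)
    seg = Segment(rec, state, 0.0)
    ctx = rec.region_indices("motor_cortex")
    power = float(
        np.mean([band_power(welch_psd(rec.samples[i], rec.fs), HIGH_BETA) for i in ctx])
    )
    coh, _ = region_pair_coherence(seg, HIGH_BETA)
    return power, coh


def cohort_recovery_experiment(
    n_replicates: int = 100,
    n_subjects: int = 8,
    lesion_shared_mult: float = 2.0,
    subject_cv: float = 0.1,
    seed: int = 0,
    null: bool = False,
) -> dict:
    """Rejection rates of the group ANOVA on high-beta power and on band
    coherence, over seeded cohort replicates.

    Effect cohorts give the lesion group a doubled shared beta gain (which
    more than doubles the expected band coherence); null cohorts set every
    multiplier to 1 and should reject at the nominal 5 % rate.
    """
    base = SimulationConfig()
    mult = {
        "sham": 1.0,
        "lesion": 1.0 if null else lesion_shared_mult,
        "lesion_treated": 1.0 if null else (1.0 + lesion_shared_mult) / 2,
    }
    master = np.random.SeedSequence([seed, 1 if null else 2])
    reject_power = 0
    reject_coh = 0
    for rep_seed in master.spawn(n_replicates):
        kids = iter(rep_seed.spawn(len(mult) * n_subjects * 2))
        powers: dict[str, list[float]] = {}
        cohs: dict[str, list[float]] = {}
        for group, m in mult.items():
            powers[group] = []
            cohs[group] = []
            for _ in range(n_subjects):
                jitter = float(np.random.default_rng(next(kids)).lognormal(0.0, subject_cv))
                cfg = apply_effect(base, (m * jitter, jitter))
                p, c = _subject_measures(cfg, "rest", next(kids))
                powers[group].append(p)
                cohs[group].append(c)
        p_power = anova_bonferroni({k: np.asarray(v) for k, v in powers.items()}).p
        p_coh = anova_bonferroni({k: np.asarray(v) for k, v in cohs.items()}).p
        reject_power += p_power < 0.05
        reject_coh += p_coh < 0.05
    return {
        "rejection_rate_power": reject_power / n_replicates,
        "rejection_rate_coherence": reject_coh / n_replicates,
        "n_replicates": n_replicates,
        "n_subjects_per_group": n_subjects,
        "null": null,
    }
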