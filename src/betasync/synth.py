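"""Synthetic two-region LFP + spike cohort generator.

Emulates corticostriatal recordings from a hemi-parkinsonian rat study
design: motor cortex and dorsolateral striatum sampled on >= 4 electrodes
each, 60-s alert-rest and walking segments, a shared narrowband
high-beta/low-gamma (25-40 Hz) component whose gain and inter-region
coupling vary by group (sham / lesion / lesion + treatment) and by week,
and cortical units spiking as inhomogeneous Poisson processes with a
von Mises phase preference to the cortical beta oscillation.

The generator is phenomenological: every channel is

    background_i(t) + g_shared * s(t [- delay]) + g_private * b_region(t)

where s is a beta-band noise source common to both regions, b_region is a
private beta source shared by that region's electrodes, and background_i
is an independent 1/f^alpha process per electrode.  Because the mixing
gains are known, the 25-40 Hz coherence between a cortex and a striatum
channel has a closed form that ships with each dataset as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.signal import hilbert
from scipy.special import i0, i1

from ._filters import raised_cosine_band_mask
from .bands import DEFAULT_BANDS, BandTable
from .io import (
    MOTOR_CORTEX,
    STRIATUM,
    EpochSet,
    Recording,
    Segment,
    SpikeTrain,
    write_dataset,
)

GROUPS = ("sham", "lesion", "lesion_treated")
STATES = ("rest", "walking")

_BACKGROUND_F_MIN = 1.0  # Hz below which the 1/f envelope is held flat


class UnitSpec(NamedTuple):
    """One simulated cortical unit: rate, von Mises locking, identity."""

    base_rate_hz: float
    kappa: float
    mu_rad: float
    locked: bool


def default_unit_specs() -> tuple[UnitSpec, ...]:
    """Eight cortical units, half phase-locked (kappa = 2) and half not."""
    locked = [UnitSpec(r, 2.0, m, True) for r, m in [(5.0, 0.0), (8.0, 0.5), (3.0, -0.5), (6.0, 1.0)]]
    unlocked = [UnitSpec(r, 0.0, 0.0, False) for r in (4.0, 10.0, 2.0, 7.0)]
    return tuple(locked + unlocked)


@dataclass(frozen=True)
class StateParams:
    """Behavioural-state modulation of the beta sources."""

    beta_gain_mult: float = 1.0
    peak_offset_hz: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated (subject, state) segment pair.

    Gains are amplitude multipliers on unit-variance beta sources; the
    background is an independent 1/f^alpha process per electrode with
    standard deviation ``background_sd``.
    """

    fs_lfp: float = 1000.0
    duration_s: float = 60.0
    bands: BandTable = field(default_factory=BandTable)
    background_alpha: float = 1.0
    background_sd: float = 1.0
    beta_band: tuple[float, float] = (25.0, 40.0)
    shared_gain_cortex: float = 0.3
    shared_gain_striatum: float = 0.3
    independent_gain_cortex: float = 0.3
    independent_gain_striatum: float = 0.3
    conduction_delay_ms: float = 5.0
    n_electrodes_per_region: int = 4
    unit_specs: tuple[UnitSpec, ...] = field(default_factory=default_unit_specs)
    state_params: dict = field(
        default_factory=lambda: {
            "rest": StateParams(1.0, 0.0),
            "walking": StateParams(0.8, 2.0),
        }
    )

    def __post_init__(self) -> None:
        for g in (
            self.shared_gain_cortex,
            self.shared_gain_striatum,
            self.independent_gain_cortex,
            self.independent_gain_striatum,
        ):
            if g < 0:
                raise ValueError("gains must be >= 0")
        f_lo, f_hi = self.beta_band
        if not (0 < f_lo < f_hi <= self.fs_lfp / 2):
            raise ValueError("beta_band must lie inside (0, fs/2]")
        if self.n_electrodes_per_region < 4:
            raise ValueError("at least 4 electrodes per region are required")
        for spec in self.unit_specs:
            if spec.kappa < 0 or spec.base_rate_hz <= 0:
                raise ValueError("unit specs need kappa >= 0 and base_rate > 0")


@dataclass
class GroundTruth:
    """What the simulator knows to be true about one generated segment."""

    band_variances: dict  # channel_id -> band name -> variance
    expected_band_coherence: float
    units: list  # dicts: unit_id, kappa, mu, locked, expected_vector_strength
    state: str
    beta_band: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.expected_band_coherence <= 1:
            raise ValueError("expected_band_coherence must lie in [0, 1]")


def expected_vector_strength(kappa: float) -> float:
    """Resultant length of a von Mises sample: R = I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return float(i1(kappa) / i0(kappa))


# ---------------------------------------------------------------------------
# elementary sources


def make_background(
    duration_s: float,
    fs: float,
    alpha: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """1/f^alpha Gaussian background, normalised to sample SD ``sd``.

    The spectral envelope is f^(-alpha/2), held flat below 1 Hz so the
    variance stays finite and desk-scale segments are not dominated by
    drift; the log-log PSD slope over 1-100 Hz is -alpha.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    n = int(round(duration_s * fs))
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    env = _background_envelope(freqs, alpha)
    x = np.fft.irfft(np.fft.rfft(white) * env, n=n)
    return x * (sd / x.std())


def _background_envelope(freqs: np.ndarray, alpha: float) -> np.ndarray:
    env = np.zeros_like(freqs)
    nz = freqs > 0
    env[nz] = np.maximum(freqs[nz], _BACKGROUND_F_MIN) ** (-alpha / 2.0)
    return env


def make_beta_source(
    duration_s: float,
    fs: float,
    band: tuple[float, float],
    rng: np.random.Generator,
    transition_hz: float = 2.0,
) -> np.ndarray:
    """Unit-variance narrowband Gaussian noise confined to ``band``.

    Band-limited by a zero-phase raised-cosine spectral mask with a 2-Hz
    roll-off, so all power lies inside [f_lo - 2, f_hi + 2] Hz.
    """
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, fs/2)")
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = raised_cosine_band_mask(freqs, f_lo, f_hi, transition_hz)
    x = np.fft.irfft(np.fft.rfft(white) * mask, n=n)
    return x / x.std()


# ---------------------------------------------------------------------------
# closed-form expected coherence


def _densities(
    config: SimulationConfig, band: tuple[float, float], freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Expected one-sided PSD shapes (unit variance) of the beta source and
    the background on grid ``freqs``."""
    mask2 = raised_cosine_band_mask(freqs, band[0], band[1], 2.0) ** 2
    s_density = mask2 / np.trapezoid(mask2, freqs)
    env2 = _background_envelope(freqs, config.background_alpha) ** 2
    b_density = env2 / np.trapezoid(env2, freqs)
    return s_density, b_density


def expected_band_coherence(config: SimulationConfig, state: str = "rest") -> float:
    """Closed-form mean 25-40 Hz coherence between a cortex and a striatum
    channel of :func:`synthesize_lfp_pair`.

    Per frequency, with source density S(f), background density B(f) and
    state-scaled gains g:

        C(f) = (g_c g_s S)^2 /
               ((g_c^2 S + g_cI^2 S + sd^2 B) (g_s^2 S + g_sI^2 S + sd^2 B))

    averaged over the bins of the (state-shifted) beta band.  The delay
    only rotates the cross-spectrum phase and does not change |Cxy|.
    """
    sp = config.state_params.get(state, StateParams())
    band = (
        config.beta_band[0] + sp.peak_offset_hz,
        config.beta_band[1] + sp.peak_offset_hz,
    )
    n = int(round(config.duration_s * config.fs_lfp))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs_lfp)
    s_d, b_d = _densities(config, band, freqs)
    m = sp.beta_gain_mult
    gc2 = (config.shared_gain_cortex * m) ** 2
    gs2 = (config.shared_gain_striatum * m) ** 2
    gci2 = (config.independent_gain_cortex * m) ** 2
    gsi2 = (config.independent_gain_striatum * m) ** 2
    sd2 = config.background_sd**2
    num = gc2 * gs2 * s_d**2
    den = (gc2 * s_d + gci2 * s_d + sd2 * b_d) * (gs2 * s_d + gsi2 * s_d + sd2 * b_d)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cxy = np.where(den > 0, num / den, 0.0)
    return float(cxy[in_band].mean())


def _expected_band_variances(
    config: SimulationConfig, state: str, region: str
) -> dict[str, float]:
    """Expected per-band variance of one channel of ``region``."""
    sp = config.state_params.get(state, StateParams())
    band = (
        config.beta_band[0] + sp.peak_offset_hz,
        config.beta_band[1] + sp.peak_offset_hz,
    )
    n = int(round(config.duration_s * config.fs_lfp))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs_lfp)
    s_d, b_d = _densities(config, band, freqs)
    m = sp.beta_gain_mult
    if region == MOTOR_CORTEX:
        g2 = (config.shared_gain_cortex * m) ** 2 + (config.independent_gain_cortex * m) ** 2
    else:
        g2 = (config.shared_gain_striatum * m) ** 2 + (config.independent_gain_striatum * m) ** 2
    density = g2 * s_d + config.background_sd**2 * b_d
    out = {}
    for name, (lo, hi) in config.bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        out[name] = float(np.trapezoid(density[sel], freqs[sel]))
    return out


# ---------------------------------------------------------------------------
# LFP pair and spikes


def synthesize_lfp_pair(
    config: SimulationConfig,
    state: str,
    seed: int | np.random.SeedSequence,
) -> tuple[Recording, GroundTruth]:
    """One two-region recording: shared + private beta sources over
    independent 1/f backgrounds, with the striatal shared copy delayed."""
    if state not in config.state_params:
        raise ValueError(f"unknown state {state!r}; have {sorted(config.state_params)}")
    if config.conduction_delay_ms / 1000.0 >= config.duration_s:
        raise ValueError("conduction delay must be shorter than the segment")
    sp = config.state_params[state]
    band = (
        config.beta_band[0] + sp.peak_offset_hz,
        config.beta_band[1] + sp.peak_offset_hz,
    )
    rng = np.random.default_rng(seed)
    fs = config.fs_lfp
    shared = make_beta_source(config.duration_s, fs, band, rng)
    priv_ctx = make_beta_source(config.duration_s, fs, band, rng)
    priv_str = make_beta_source(config.duration_s, fs, band, rng)
    delay_samples = int(round(config.conduction_delay_ms / 1000.0 * fs))
    shared_delayed = np.roll(shared, delay_samples)

    m = sp.beta_gain_mult
    n_per = config.n_electrodes_per_region
    channels: list[tuple[str, str]] = []
    rows = []
    for i in range(n_per):
        bg = make_background(config.duration_s, fs, config.background_alpha, config.background_sd, rng)
        rows.append(bg + m * (config.shared_gain_cortex * shared + config.independent_gain_cortex * priv_ctx))
        channels.append((f"ctx{i:02d}", MOTOR_CORTEX))
    for i in range(n_per):
        bg = make_background(config.duration_s, fs, config.background_alpha, config.background_sd, rng)
        rows.append(bg + m * (config.shared_gain_striatum * shared_delayed + config.independent_gain_striatum * priv_str))
        channels.append((f"str{i:02d}", STRIATUM))
    recording = Recording(samples=np.vstack(rows), fs=fs, channels=channels)

    truth = GroundTruth(
        band_variances={
            cid: _expected_band_variances(config, state, region)
            for cid, region in channels
        },
        expected_band_coherence=expected_band_coherence(config, state),
        units=[
            {
                "unit_id": f"unit{i:02d}",
                "kappa": spec.kappa,
                "mu": spec.mu_rad,
                "locked": spec.locked,
                "expected_vector_strength": expected_vector_strength(spec.kappa),
            }
            for i, spec in enumerate(config.unit_specs)
        ],
        state=state,
        beta_band=band,
    )
    return recording, truth


def synthesize_spike_train(
    phase_signal: np.ndarray,
    fs: float,
    base_rate_hz: float,
    kappa: float,
    mu: float,
    duration_s: float,
    rng: np.random.Generator,
    unit_id: str = "unit",
    region: str = MOTOR_CORTEX,
    waveform_template: np.ndarray | None = None,
    refractory_ms: float = 1.5,
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes with von Mises phase modulation.

    Intensity lambda(t) = base_rate * exp(kappa * cos(phi(t) - mu)) / I0(kappa),
    realised by thinning a homogeneous process at the envelope rate
    base_rate * exp(kappa) / I0(kappa).  The I0 normalisation keeps the
    time-averaged rate at base_rate regardless of kappa (the band-passed
    phase is uniform on the circle over a long segment).  An absolute
    refractory period (default 1.5 ms) then removes spikes following too
    closely, as a sorted single unit requires; at the rates simulated this
    trims well under 1 % of spikes.
    """
    if base_rate_hz <= 0:
        raise ValueError("base_rate_hz must be positive")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    n_needed = int(round(duration_s * fs))
    if len(phase_signal) < n_needed:
        raise ValueError("phase signal does not cover the requested duration")
    norm = float(i0(kappa))
    lam_max = base_rate_hz * np.exp(kappa) / norm
    n_hom = rng.poisson(lam_max * duration_s)
    t_cand = np.sort(rng.uniform(0.0, duration_s, size=n_hom))
    idx = np.minimum((t_cand * fs).astype(int), n_needed - 1)
    lam = base_rate_hz * np.exp(kappa * np.cos(phase_signal[idx] - mu)) / norm
    if np.any(lam > lam_max * (1 + 1e-12)):
        raise RuntimeError("thinning envelope violated")  # defensive; cannot occur
    keep = rng.uniform(0.0, 1.0, size=n_hom) < lam / lam_max
    times = np.unique(t_cand[keep])
    if refractory_ms > 0 and times.size:
        dead = refractory_ms / 1000.0
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= dead:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain(
        unit_id=unit_id,
        region=region,
        spike_times_s=times,
        waveform_template=waveform_template,
    )


def make_waveform_template(
    trough_to_peak_ms: float,
    fs: float = 30000.0,
    amplitude: float = 100.0,
    length_ms: float = 2.0,
) -> np.ndarray:
    """Synthetic biphasic extracellular spike template: a sharp negative
    trough followed by a slower positive after-wave at the requested
    trough-to-peak separation."""
    n = int(round(length_ms / 1000.0 * fs))
    t = np.arange(n) / fs * 1000.0  # ms
    t_trough = 0.4
    t_peak = t_trough + trough_to_peak_ms
    trough = -amplitude * np.exp(-0.5 * ((t - t_trough) / 0.08) ** 2)
    peak = 0.45 * amplitude * np.exp(-0.5 * ((t - t_peak) / (0.1 + 0.25 * trough_to_peak_ms)) ** 2)
    return trough + peak


def oscillation_phase(component: np.ndarray) -> np.ndarray:
    """Instantaneous phase of an already narrowband signal (analytic
    signal angle; 0 at oscillation peaks)."""
    return np.angle(hilbert(component))


def synthesize_segment(
    config: SimulationConfig,
    state: str,
    seed: int | np.random.SeedSequence,
    subject: str = "",
    week: int | None = None,
) -> tuple[Segment, GroundTruth]:
    """A ready-to-analyse 60-s Segment with spike trains attached.

    Spikes lock to the phase of the summed cortical beta component
    (shared + private), which is what a cortical unit would feel.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    lfp_seed, spk_seed = ss.spawn(2)
    recording, truth = synthesize_lfp_pair(config, state, lfp_seed)
    sp = config.state_params[state]
    band = truth.beta_band
    # rebuild the cortical oscillatory component from the same stream
    rng = np.random.default_rng(lfp_seed)
    shared = make_beta_source(config.duration_s, config.fs_lfp, band, rng)
    priv_ctx = make_beta_source(config.duration_s, config.fs_lfp, band, rng)
    m = sp.beta_gain_mult
    component = m * (config.shared_gain_cortex * shared + config.independent_gain_cortex * priv_ctx)
    if np.allclose(component, 0):
        phase = np.zeros_like(component)
    else:
        phase = oscillation_phase(component)

    spk_rng = np.random.default_rng(spk_seed)
    spikes = []
    for i, spec in enumerate(config.unit_specs):
        ttp = 0.45 if spec.kappa > 0 else 0.2  # locked units modelled as broad pyramidal
        spikes.append(
            synthesize_spike_train(
                phase,
                config.fs_lfp,
                spec.base_rate_hz,
                spec.kappa,
                spec.mu_rad,
                config.duration_s,
                spk_rng,
                unit_id=f"unit{i:02d}",
                region=MOTOR_CORTEX,
                waveform_template=make_waveform_template(ttp),
            )
        )
    segment = Segment(
        recording=recording,
        state=state,
        start_s=0.0,
        subject=subject,
        week=week,
        spikes=spikes,
    )
    return segment, truth


# ---------------------------------------------------------------------------
# cohort layout


@dataclass(frozen=True)
class CohortConfig:
    """Group x week x state cohort design.

    ``effect_table`` maps (group, week, state) to multipliers applied to the
    base config's shared and independent beta gains; it must cover every
    combination.  ``subject_cv`` adds per-subject lognormal gain variability
    (coefficient of variation) so groups are populations, not clones.
    """

    groups: tuple[str, ...] = GROUPS
    weeks: tuple[int, ...] = (2, 4)
    n_subjects_per_group: int = 2
    effect_table: dict = field(default_factory=dict)
    base: SimulationConfig = field(default_factory=SimulationConfig)
    states: tuple[str, ...] = STATES
    subject_cv: float = 0.1

    def __post_init__(self) -> None:
        table = self.effect_table or default_effect_table(self.groups, self.weeks, self.states)
        object.__setattr__(self, "effect_table", table)
        for g in self.groups:
            for w in self.weeks:
                for s in self.states:
                    key = (g, w, s)
                    if key not in self.effect_table:
                        raise ValueError(f"effect_table missing entry for {key}")
                    sh, ind = self.effect_table[key]
                    if sh < 0 or ind < 0:
                        raise ValueError("effect multipliers must be >= 0")


def default_effect_table(
    groups: tuple[str, ...] = GROUPS,
    weeks: tuple[int, ...] = (2, 4),
    states: tuple[str, ...] = STATES,
    lesion_shared: float = 2.0,
    treatment_recovery: float = 0.6,
) -> dict:
    """(group, week, state) -> (shared multiplier, independent multiplier).

    Sham stays at 1; the lesion group carries an elevated shared beta gain;
    the treated group relaxes toward sham at later weeks, mimicking a
    time-dependent therapeutic effect.
    """
    table = {}
    wk_sorted = sorted(weeks)
    for g in groups:
        for i, w in enumerate(wk_sorted):
            for s in states:
                if g == "sham":
                    mult = 1.0
                elif g == "lesion":
                    mult = lesion_shared
                else:  # lesion_treated: geometric relaxation toward sham
                    frac = i / max(len(wk_sorted) - 1, 1)
                    mult = lesion_shared * (treatment_recovery / 1.0) ** frac
                table[(g, w, s)] = (mult, 1.0)
    return table


def apply_effect(base: SimulationConfig, multipliers: tuple[float, float]) -> SimulationConfig:
    sh, ind = multipliers
    return replace(
        base,
        shared_gain_cortex=base.shared_gain_cortex * sh,
        shared_gain_striatum=base.shared_gain_striatum * sh,
        independent_gain_cortex=base.independent_gain_cortex * ind,
        independent_gain_striatum=base.independent_gain_striatum * ind,
    )


def iter_cohort_segments(cohort: CohortConfig, seed: int | np.random.SeedSequence):
    """Yield (meta dict, Segment, GroundTruth) for every cohort cell.

    One master seed spawns one child per (group, subject, week, state) in a
    fixed nested loop order, so any cell is reproducible independently of
    how many others are generated.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_cells = (
        len(cohort.groups) * cohort.n_subjects_per_group * len(cohort.weeks) * len(cohort.states)
    )
    n_subj_draws = len(cohort.groups) * cohort.n_subjects_per_group
    children = ss.spawn(n_cells + n_subj_draws)
    cell = iter(children[:n_cells])
    subj_seed = iter(children[n_cells:])
    for group in cohort.groups:
        for s_idx in range(cohort.n_subjects_per_group):
            subject = f"{group}_s{s_idx:02d}"
            subj_rng = np.random.default_rng(next(subj_seed))
            jitter = (
                float(subj_rng.lognormal(mean=0.0, sigma=cohort.subject_cv))
                if cohort.subject_cv > 0
                else 1.0
            )
            for week in cohort.weeks:
                for state in cohort.states:
                    mult = cohort.effect_table[(group, week, state)]
                    cfg = apply_effect(cohort.base, (mult[0] * jitter, mult[1] * jitter))
                    segment, truth = synthesize_segment(
                        cfg, state, next(cell), subject=subject, week=week
                    )
                    meta = {
                        "group": group,
                        "subject": subject,
                        "week": week,
                        "state": state,
                        "shared_multiplier": mult[0],
                        "independent_multiplier": mult[1],
                        "subject_gain_jitter": jitter,
                    }
                    yield meta, segment, truth


def synthesize_cohort(
    cohort: CohortConfig, out_dir: str | Path, seed: int | np.random.SeedSequence
) -> list[Path]:
    """Write the full cohort to disk: one dataset directory per
    (subject, week, state), plus a cohort-level ground-truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = []
    for meta, segment, truth in iter_cohort_segments(cohort, seed):
        name = f"{meta['subject']}_w{meta['week']:02d}_{meta['state']}"
        epochs = EpochSet([(meta["state"], 0.0, segment.recording.duration_s)])
        gt = asdict(truth)
        gt.update(meta)
        path = write_dataset(
            out_dir / name,
            segment.recording,
            spikes=segment.spikes,
            epochs=epochs,
            ground_truth=gt,
            manifest={"subject": meta["subject"], "week": meta["week"], "state": meta["state"], "group": meta["group"]},
        )
        paths.append(path)
        manifest.append({"path": name, **meta, "expected_band_coherence": truth.expected_band_coherence})
    (out_dir / "cohort_manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths
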