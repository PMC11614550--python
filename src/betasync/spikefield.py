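"""Spike-LFP phase locking and the spike-triggered waveform average (STWA).

Two complementary measures of how tightly cortical spiking rides the
25-40 Hz oscillation:

* Rayleigh test on spike phases.  Phases are read off the band-passed
  analytic signal at each spike time; exactly 40 spikes are drawn per unit
  (units with fewer than 40 spikes are excluded) and the Rayleigh statistic
  Z = n R^2 is converted to a p value with the standard small-sample series
  approximation.  A unit is "locked" when p < .05.

* STWA shuffle ratio.  The band-filtered LFP is averaged in +/-100 ms
  windows around spikes; the peak-to-trough magnitude of that average is
  divided by the mean magnitude over 20 surrogate trains built by permuting
  inter-spike intervals.  Under independence the ratio sits near 1; locked
  units push it well above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from ._filters import bandpass_zero_phase
from .bands import HIGH_BETA
from .io import Segment, SpikeTrain
from .spectral import welch_psd, band_power

MIN_SPIKES = 40
DEFAULT_SUBSAMPLE = 40
DEFAULT_N_SHUFFLE = 20
DEFAULT_WINDOW_MS = 100.0
ALPHA = 0.05


@dataclass
class PhaseLockResult:
    """Rayleigh-test outcome for one unit against one LFP target."""

    unit_id: str
    target_region: str
    n_spikes_available: int
    subsample_n: int = DEFAULT_SUBSAMPLE
    r: float = float("nan")
    z: float = float("nan")
    p: float = float("nan")
    preferred_phase: float = float("nan")
    locked: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not self.excluded:
            if not np.isclose(self.z, self.subsample_n * self.r**2, atol=1e-9):
                raise ValueError("Rayleigh identity Z = n R^2 violated")
            if not 0 < self.p <= 1:
                raise ValueError("p must lie in (0, 1]")


@dataclass
class StwaResult:
    """Spike-triggered waveform average and its shuffle-null ratio."""

    unit_id: str
    target_region: str
    window_ms: float
    stwa_waveform: np.ndarray | None
    peak_to_trough: float
    shuffle_magnitudes: list[float] = field(default_factory=list)
    ratio: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not self.excluded and self.peak_to_trough < 0:
            raise ValueError("peak_to_trough must be >= 0")


def instantaneous_phase(
    lfp: np.ndarray, fs: float, band: tuple[float, float] = HIGH_BETA
) -> np.ndarray:
    """Phase (radians) of the band-passed analytic signal.

    Zero-phase filtering, so there is no systematic lag; phase 0 falls at
    oscillation peaks and advances through (-pi, pi] each cycle.
    """
    filtered = bandpass_zero_phase(lfp, fs, band)
    return np.angle(hilbert(filtered))


def spike_phases(
    spike_times_s: np.ndarray, phase_signal: np.ndarray, fs: float
) -> tuple[np.ndarray, int]:
    """Phase at the nearest sample to each spike; returns (angles,
    n_skipped) where skipped spikes fell outside the signal."""
    t = np.asarray(spike_times_s, dtype=float)
    idx = np.round(t * fs).astype(int)
    valid = (idx >= 0) & (idx < len(phase_signal))
    return phase_signal[idx[valid]], int((~valid).sum())


def rayleigh_p(z: float, n: int) -> float:
    """Small-sample series approximation to the Rayleigh test p value."""
    p = np.exp(-z) * (
        1
        + (2 * z - z**2) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def rayleigh_test(
    angles: np.ndarray,
    subsample_n: int = DEFAULT_SUBSAMPLE,
    seed: int | np.random.Generator = 0,
    unit_id: str = "",
    target_region: str = "",
) -> PhaseLockResult:
    """Rayleigh uniformity test on a seeded subsample of ``subsample_n``
    spike phases; units offering fewer phases are excluded outright."""
    angles = np.asarray(angles, dtype=float)
    n_avail = angles.size
    if n_avail < subsample_n:
        return PhaseLockResult(
            unit_id=unit_id,
            target_region=target_region,
            n_spikes_available=n_avail,
            subsample_n=subsample_n,
            excluded=True,
            exclusion_reason=f"fewer than {subsample_n} spikes",
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(n_avail, size=subsample_n, replace=False)
    sub = angles[chosen]
    vec = np.exp(1j * sub).mean()
    r = float(np.abs(vec))
    z = subsample_n * r**2
    p = rayleigh_p(z, subsample_n)
    return PhaseLockResult(
        unit_id=unit_id,
        target_region=target_region,
        n_spikes_available=n_avail,
        subsample_n=subsample_n,
        r=r,
        z=z,
        p=p,
        preferred_phase=float(np.angle(vec)),
        locked=p < ALPHA,
    )


def _snippet_average(
    filtered: np.ndarray, spike_idx: np.ndarray, half_window: int
) -> np.ndarray | None:
    ok = (spike_idx >= half_window) & (spike_idx < len(filtered) - half_window)
    idx = spike_idx[ok]
    if idx.size == 0:
        return None
    offsets = np.arange(-half_window, half_window + 1)
    return filtered[idx[:, None] + offsets[None, :]].mean(axis=0), idx.size


def stwa(
    spikes: SpikeTrain,
    lfp: np.ndarray,
    fs: float,
    band: tuple[float, float] = HIGH_BETA,
    window_ms: float = DEFAULT_WINDOW_MS,
    target_region: str = "",
    _prefiltered: np.ndarray | None = None,
) -> StwaResult:
    """Band-filtered spike-triggered average over +/-window_ms; the
    summary statistic is its peak-to-trough magnitude."""
    filtered = _prefiltered if _prefiltered is not None else bandpass_zero_phase(lfp, fs, band)
    half = int(round(window_ms / 1000.0 * fs))
    idx = np.round(spikes.spike_times_s * fs).astype(int)
    out = _snippet_average(filtered, idx, half)
    n_complete = 0 if out is None else out[1]
    if out is None or n_complete < MIN_SPIKES:
        return StwaResult(
            unit_id=spikes.unit_id,
            target_region=target_region,
            window_ms=window_ms,
            stwa_waveform=None,
            peak_to_trough=float("nan"),
            excluded=True,
            exclusion_reason=f"only {n_complete} complete windows (< {MIN_SPIKES})",
        )
    avg = out[0]
    return StwaResult(
        unit_id=spikes.unit_id,
        target_region=target_region,
        window_ms=window_ms,
        stwa_waveform=avg,
        peak_to_trough=float(avg.max() - avg.min()),
    )


def shuffle_spike_times(
    spike_times_s: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Surrogate train with the same spike count and inter-spike-interval
    multiset: the ISIs are randomly permuted, anchored at the first spike."""
    t = np.asarray(spike_times_s, dtype=float)
    if t.size < 2:
        return t.copy()
    isis = np.diff(t)
    return t[0] + np.concatenate(([0.0], np.cumsum(rng.permutation(isis))))


def stwa_shuffle_ratio(
    spikes: SpikeTrain,
    lfp: np.ndarray,
    fs: float,
    band: tuple[float, float] = HIGH_BETA,
    window_ms: float = DEFAULT_WINDOW_MS,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
    seed: int | np.random.Generator = 0,
    target_region: str = "",
) -> StwaResult:
    """Unshuffled STWA peak-to-trough divided by the mean magnitude of
    ``n_shuffle`` ISI-permuted surrogate trains (all magnitudes retained)."""
    filtered = bandpass_zero_phase(lfp, fs, band)
    base = stwa(
        spikes, lfp, fs, band, window_ms, target_region=target_region, _prefiltered=filtered
    )
    if base.excluded:
        return base
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mags = []
    for _ in range(n_shuffle):
        surrogate = SpikeTrain(
            unit_id=spikes.unit_id,
            region=spikes.region,
            spike_times_s=np.unique(shuffle_spike_times(spikes.spike_times_s, rng)),
        )
        s = stwa(
            surrogate, lfp, fs, band, window_ms, target_region=target_region, _prefiltered=filtered
        )
        mags.append(float(s.peak_to_trough) if not s.excluded else float("nan"))
    mean_mag = float(np.nanmean(mags))
    if not np.isfinite(mean_mag) or mean_mag == 0.0:
        raise ZeroDivisionError("mean shuffled peak-to-trough is zero; ratio undefined")
    base.shuffle_magnitudes = mags
    base.ratio = base.peak_to_trough / mean_mag
    return base


def select_target_channel(
    segment: Segment, region: str, band: tuple[float, float] = HIGH_BETA
) -> int:
    """The analysis LFP for a region: the electrode with the highest band
    power (deterministic, power-maximising choice)."""
    rec = segment.recording
    idx = rec.region_indices(region)
    if not idx:
        raise ValueError(f"segment has no {region} channels")
    powers = [band_power(welch_psd(rec.samples[i], rec.fs), band) for i in idx]
    return idx[int(np.argmax(powers))]


def phase_locked_summary(results: dict[str, list[PhaseLockResult]]) -> dict[str, dict]:
    """Per-group counts and proportion of significantly locked units;
    excluded units never enter the denominator."""
    summary = {}
    for group, res in results.items():
        tested = [r for r in res if not r.excluded]
        if not tested:
            continue
        n_locked = sum(r.locked for r in tested)
        summary[group] = {
            "n_locked": n_locked,
            "n_tested": len(tested),
            "proportion": n_locked / len(tested),
        }
    if not summary:
        import warnings

        warnings.warn("all units excluded; no phase-locking summary", stacklevel=2)
    return summary
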